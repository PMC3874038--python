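"""Readers and writers for the external formats the pipeline touches.

Supported formats: plain TSV expression matrices (genes in rows, first column
``gene_id``), GCT v1.2 (read-only convenience), GMT gene-set files with paired
``NAME_UP`` / ``NAME_DOWN`` lines, two-column ortholog TSVs, and a JSON run
manifest. Group annotation lives in a two-column sidecar TSV (sample_id, arm)
rather than being encoded in sample names.

All writers emit plain text; TSV expression round-trips are bit-identical
because floats are written with ``repr`` precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    ExpressionStudy,
    FormatError,
    GeneSignature,
    OrthologMap,
    ParseError,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_groups",
    "write_groups",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "write_ortholog_map",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# expression matrices


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, arm) sidecar TSV; header optional."""
    groups: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {i + 1}: expected 2 fields, got {len(fields)}")
        if i == 0 and fields[0].lower() in {"sample", "sample_id"}:
            continue
        groups[fields[0]] = fields[1]
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tarm\n")
        for s, a in groups.items():
            fh.write(f"{s}\t{a}\n")


def _parse_matrix_body(
    rows: list[list[str]], sample_ids: list[str], path: str | Path
) -> pd.DataFrame:
    gene_ids: list[str] = []
    data: list[list[float]] = []
    for r, fields in enumerate(rows):
        gene_ids.append(fields[0])
        vals = []
        for c, cell in enumerate(fields[1:]):
            try:
                vals.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at data row {r + 1}, "
                    f"column {sample_ids[c]!r}"
                ) from None
        if len(vals) != len(sample_ids):
            raise FormatError(
                f"{path}: data row {r + 1} has {len(vals)} values for "
                f"{len(sample_ids)} samples"
            )
        data.append(vals)
    df = pd.DataFrame(data, index=gene_ids, columns=sample_ids, dtype=float)
    df.index.name = "gene_id"
    return df


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: malformed header (need gene_id + >=1 sample)")
    sample_ids = header[1:]
    rows = [ln.split("\t") for ln in lines[1:]]
    return _parse_matrix_body(rows, sample_ids, path)


def _read_gct_matrix(path: str | Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        raise FormatError(f"{path}: GCT v1.2 requires a '#1.2' first line")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed GCT dimensions line") from None
    header = lines[2].split("\t")
    if len(header) < 3 or header[0].lower() not in {"name", "gene_id"}:
        raise FormatError(f"{path}: malformed GCT header row")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: header lists {len(sample_ids)} samples, dims line says {n_samples}"
        )
    body = [ln.split("\t") for ln in lines[3:] if ln.strip()]
    if len(body) != n_genes:
        raise FormatError(f"{path}: {len(body)} data rows, dims line says {n_genes}")
    # drop the Description column
    rows = [[f[0]] + f[2:] for f in body]
    return _parse_matrix_body(rows, sample_ids, path)


def read_expression_table(
    path: str | Path,
    groups: str | Path | Mapping[str, str],
    dialect: str = "tsv",
    species: str = "",
) -> ExpressionStudy:
    """Read an expression matrix plus its group annotation.

    Parameters
    ----------
    path
        Matrix file; TSV (first column ``gene_id``) or GCT v1.2.
    groups
        Either a sidecar TSV path or an in-memory sample->arm mapping.
    dialect
        ``"tsv"`` or ``"gct"``.
    """
    if dialect == "tsv":
        df = _read_tsv_matrix(path)
    elif dialect == "gct":
        df = _read_gct_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not isinstance(groups, Mapping):
        groups = read_groups(groups)
    return ExpressionStudy(df, dict(groups), species=species)


def write_expression_table(
    study: ExpressionStudy,
    path: str | Path,
    groups_path: str | Path | None = None,
) -> None:
    """Write a study as plain TSV; floats use repr so round-trips are exact."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(study.sample_ids) + "\n")
        for gid, row in zip(study.gene_ids, study.values.to_numpy()):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    if groups_path is not None:
        write_groups(study.groups, groups_path)


# ---------------------------------------------------------------------------
# GMT gene sets

_UP_SUFFIX = "_UP"
_DOWN_SUFFIX = "_DOWN"


def read_gmt(path: str | Path, species: str = "") -> list[GeneSignature]:
    """Read GMT; ``NAME_UP``/``NAME_DOWN`` line pairs merge into one signature.

    Unpaired lines become a signature with an empty down (or up) set; a line
    without either suffix is treated as an up set under its own name.
    """
    halves: dict[str, dict[str, set[str]]] = {}
    order: list[str] = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {i + 1}: GMT needs name, description and >=1 gene"
            )
        name, genes = fields[0], fields[2:]
        if name.endswith(_UP_SUFFIX):
            base, side = name[: -len(_UP_SUFFIX)], "up"
        elif name.endswith(_DOWN_SUFFIX):
            base, side = name[: -len(_DOWN_SUFFIX)], "down"
        else:
            base, side = name, "up"
        if base not in halves:
            halves[base] = {"up": set(), "down": set()}
            order.append(base)
        halves[base][side].update(genes)
    out = []
    for base in order:
        h = halves[base]
        overlap = h["up"] & h["down"]
        if overlap:
            raise ValidationError(
                f"{path}: signature {base!r} has gene(s) in both up and down: "
                f"{sorted(overlap)[:5]}"
            )
        out.append(GeneSignature(base, frozenset(h["up"]), frozenset(h["down"]), species))
    return out


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.up:
                fh.write("\t".join([sig.name + _UP_SUFFIX, "na", *sorted(sig.up)]) + "\n")
            if sig.down:
                fh.write("\t".join([sig.name + _DOWN_SUFFIX, "na", *sorted(sig.down)]) + "\n")


# ---------------------------------------------------------------------------
# ortholog maps


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (source id, target id); header optional."""
    pairs: list[tuple[str, str]] = []
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: line {i + 1}: expected 2 fields, got {len(fields)}")
        if i == 0 and fields[0].lower() in {"source", "source_id", "mouse", "from"}:
            continue
        pairs.append((fields[0], fields[1]))
    omap = OrthologMap(pairs)
    if not omap.pairs:
        log.warning("%s: empty ortholog map", path)
    else:
        log.info("%s: ortholog map %s", path, omap.mapping_counts())
    return omap


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\n")
        for s, t in omap.pairs:
            fh.write(f"{s}\t{t}\n")


# ---------------------------------------------------------------------------
# run manifest


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    inputs: Iterable[str | Path],
    params: Mapping[str, object],
    seed: int | None,
) -> None:
    """Record input checksums, parameters, seed and package version as JSON."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "params": dict(params),
        # keyed by file name so manifests are identical across output dirs
        "inputs": {Path(p).name: _sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
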