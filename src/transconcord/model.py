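"""Core domain types shared across the pipeline.

The central containers are :class:`ExpressionStudy` (a log2 expression matrix
with a sample-to-arm grouping), :class:`GeneSignature` (a named pair of up/down
gene-id sets, i.e. a "transcriptome used as a gene set") and
:class:`OrthologMap` (a possibly many-to-many correspondence between the gene
identifiers of two species).

Gene identifiers are opaque, case-sensitive strings throughout: silent case
folding would corrupt ortholog joins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TransconcordError",
    "FormatError",
    "ParseError",
    "ValidationError",
    "InferenceError",
    "ExpressionStudy",
    "GeneSignature",
    "OrthologMap",
]


class TransconcordError(Exception):
    """Base class for errors raised by this package."""


class FormatError(TransconcordError):
    """A file does not have the structure its format requires."""


class ParseError(TransconcordError):
    """A cell or field could not be parsed; the message reports where."""


class ValidationError(TransconcordError):
    """An object violates a domain invariant."""


class InferenceError(TransconcordError):
    """A statistical procedure cannot be run on the given inputs."""


@dataclass
class ExpressionStudy:
    """A genes x samples matrix of log2 intensities with arm labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id, holding
        log2-scale expression. All entries must be finite.
    groups
        Mapping from sample id to arm label (free strings such as ``"naive"``,
        ``"disease"``). Every sample must have exactly one label.
    species
        Free species label, e.g. ``"mouse"`` or ``"human"``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    species: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene id(s): {dup[:5]}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample id(s): {dup[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValidationError(f"{n_bad} missing or non-finite expression value(s)")
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValidationError(f"sample(s) without a group label: {missing}")
        # keep only labels for samples actually present, in column order
        self.groups = {s: str(self.groups[s]) for s in cols}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def arms(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.groups.values():
            seen.setdefault(a, None)
        return list(seen)

    def samples_in_arm(self, arm: str) -> list[str]:
        return [s for s, a in self.groups.items() if a == arm]

    def arm_values(self, arm: str) -> pd.DataFrame:
        """Sub-matrix of the samples belonging to one arm."""
        cols = self.samples_in_arm(arm)
        if not cols:
            raise ValidationError(f"no samples in arm {arm!r}")
        return self.values[cols]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionStudy":
        keep = [g for g in gene_ids]
        return ExpressionStudy(self.values.loc[keep], dict(self.groups), self.species)


@dataclass(frozen=True)
class GeneSignature:
    """Named up/down gene-id sets for one species."""

    name: str
    up: frozenset[str] = frozenset()
    down: frozenset[str] = frozenset()
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: gene(s) in both up and down: "
                f"{sorted(overlap)[:5]}"
            )

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class OrthologMap:
    """Deduplicated (source id, target id) pairs; may be many-to-many."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        for s, t in self.pairs:
            seen.setdefault((str(s), str(t)), None)
        self.pairs = list(seen)

    def __len__(self) -> int:
        return len(self.pairs)

    def forward(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return out

    def backward(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(t, set()).add(s)
        return out

    def reversed(self) -> "OrthologMap":
        return OrthologMap([(t, s) for s, t in self.pairs])

    def mapping_counts(self) -> dict[str, int]:
        """Counts of one-to-one vs many-to-many sources/targets."""
        fwd, bwd = self.forward(), self.backward()
        multi_src = sum(1 for v in fwd.values() if len(v) > 1)
        multi_tgt = sum(1 for v in bwd.values() if len(v) > 1)
        return {
            "n_pairs": len(self.pairs),
            "n_sources": len(fwd),
            "n_targets": len(bwd),
            "many_to_many_sources": multi_src,
            "many_to_many_targets": multi_tgt,
        }
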