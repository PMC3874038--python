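"""Ortholog translation, Venn concordance, and top-k ranked-list overlap
with a Monte-Carlo null band.

The ranked-overlap analysis asks: of the k most strongly regulated genes in
one study, how many belong to a reference gene set (for instance the
translated DEGs of another species)? The observed curve O(k) is compared with
its distribution under random ordering, estimated by drawing uniform
permutations of the measured gene universe. The universe is the set of
measured (filtered, gene-level) genes, not the whole genome: an observed
ranking can only select from genes that were measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GeneSignature, OrthologMap, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "OverlapCurve",
    "VennResult",
    "translate_signature",
    "venn_fraction",
    "ranked_top_lists",
    "overlap_curve",
    "simulate_null_overlap",
    "concordance_curve",
]


@dataclass(frozen=True)
class RankedList:
    """Gene ids ordered by a descending ranking statistic.

    For a ``down`` list the statistic is the negated signed value, so that
    ``stats`` is monotone non-increasing for both directions.
    """

    gene_ids: tuple[str, ...]
    stats: tuple[float, ...]
    direction: str
    universe_size: int

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("ranked list contains duplicate gene ids")
        if len(self.gene_ids) != len(self.stats):
            raise ValidationError("gene_ids and stats lengths differ")
        if len(self.gene_ids) > self.universe_size:
            raise ValidationError("ranked list longer than its universe")
        arr = np.asarray(self.stats, dtype=float)
        if arr.size > 1 and np.any(np.diff(arr) > 1e-12):
            raise ValidationError("ranking statistic must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class OverlapCurve:
    """Observed top-k overlap counts and the Monte-Carlo null band."""

    k_grid: np.ndarray
    observed: np.ndarray
    null_mean: np.ndarray
    null_lo: np.ndarray
    null_hi: np.ndarray
    n_reps: int
    seed: int
    target_size: int
    universe_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_grid,
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_lo": self.null_lo,
                "null_hi": self.null_hi,
            }
        )


@dataclass(frozen=True)
class VennResult:
    """Fraction of DEG genes present in a reference signature."""

    fraction: float
    n_deg: int
    n_ref: int
    n_intersection: int


# ---------------------------------------------------------------------------
# ortholog translation


def translate_signature(
    sig: GeneSignature,
    omap: OrthologMap,
    policy: str = "all_targets",
    target_species: str = "",
) -> GeneSignature:
    """Map a signature's gene ids through an ortholog map.

    ``policy="all_targets"`` expands many-to-many orthologs to every target;
    ``policy="one_to_one"`` keeps only sources with a unique target. Genes
    without orthologs are dropped and counted; a target reachable from both
    the up and the down set is dropped from both (conflict), preserving
    disjointness.
    """
    fwd = omap.forward()
    if policy == "one_to_one":
        fwd = {s: t for s, t in fwd.items() if len(t) == 1}
    elif policy != "all_targets":
        raise ValueError(f"unknown policy {policy!r}")

    def _translate(ids: frozenset[str]) -> tuple[set[str], int]:
        out: set[str] = set()
        unmapped = 0
        for g in ids:
            targets = fwd.get(g)
            if targets:
                out |= targets
            else:
                unmapped += 1
        return out, unmapped

    up, up_unmapped = _translate(sig.up)
    down, down_unmapped = _translate(sig.down)
    conflicts = up & down
    if conflicts:
        log.warning(
            "translate_signature(%s): %d target(s) reachable from both up and "
            "down sources dropped: %s",
            sig.name,
            len(conflicts),
            sorted(conflicts)[:5],
        )
        up -= conflicts
        down -= conflicts
    if up_unmapped or down_unmapped:
        log.info(
            "translate_signature(%s): %d up / %d down source gene(s) without orthologs",
            sig.name,
            up_unmapped,
            down_unmapped,
        )
    if not up and not down:
        log.warning("translate_signature(%s): no mappable genes", sig.name)
    return GeneSignature(sig.name, frozenset(up), frozenset(down), target_species)


# ---------------------------------------------------------------------------
# Venn concordance


def venn_fraction(deg, ref: GeneSignature) -> VennResult:
    """Fraction of DEG genes (up and down pooled) present in a reference
    signature (up and down pooled). NaN with a warning when the DEG set is
    empty."""
    deg_genes = set(deg.all_genes)
    ref_genes = set(ref.all_genes)
    inter = deg_genes & ref_genes
    if not deg_genes:
        log.warning("venn_fraction: empty DEG set, fraction undefined")
        return VennResult(float("nan"), 0, len(ref_genes), 0)
    return VennResult(
        fraction=len(inter) / len(deg_genes),
        n_deg=len(deg_genes),
        n_ref=len(ref_genes),
        n_intersection=len(inter),
    )


# ---------------------------------------------------------------------------
# ranked lists and overlap curves


def ranked_top_lists(
    table: pd.DataFrame, K: int = 5000, stat: str = "log2fch"
) -> tuple[RankedList, RankedList]:
    """Top-K most up- and most down-regulated genes of a differential table.

    The up list ranks by descending signed statistic, the down list by
    ascending; ties break lexicographically by gene id. K is truncated (with
    a warning) when the table is smaller.
    """
    if table.empty:
        raise ValidationError("differential table is empty")
    if K > len(table):
        log.warning("K=%d exceeds the %d available genes; truncating", K, len(table))
        K = len(table)
    s = table[stat]
    order_up = sorted(table.index, key=lambda g: (-s[g], g))
    order_dn = sorted(table.index, key=lambda g: (s[g], g))
    n = len(table)
    up = RankedList(
        tuple(order_up[:K]),
        tuple(float(s[g]) for g in order_up[:K]),
        "up",
        n,
    )
    down = RankedList(
        tuple(order_dn[:K]),
        tuple(-float(s[g]) for g in order_dn[:K]),
        "down",
        n,
    )
    return up, down


def overlap_curve(
    ranked: RankedList, target: set[str], universe: set[str], K: int | None = None
) -> np.ndarray:
    """Observed cumulative overlap O(k) = |top_k of ranked  ∩ target|."""
    if not target <= universe:
        raise ValidationError("target gene set is not a subset of the universe")
    missing = [g for g in ranked.gene_ids if g not in universe]
    if missing:
        raise ValidationError(f"ranked gene(s) outside the universe: {missing[:5]}")
    if K is None:
        K = len(ranked)
    member = np.fromiter((g in target for g in ranked.gene_ids[:K]), dtype=bool, count=min(K, len(ranked)))
    return np.cumsum(member).astype(int)


def simulate_null_overlap(
    universe: set[str],
    target: set[str],
    K: int,
    n_reps: int = 5000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo null band for the top-k overlap under random ordering.

    Each replicate draws one uniform permutation of the universe and reads the
    cumulative overlap at every k in a single pass — marginally identical to
    sampling k genes without replacement independently per k, at O(G) per
    replicate. Returns (mean, lower, upper) per k for the central ``level``
    band (empirical percentiles).
    """
    if not target <= universe:
        raise ValidationError("target gene set is not a subset of the universe")
    G, M = len(universe), len(target)
    if G < K:
        raise ValidationError(f"universe of {G} genes is smaller than K={K}")
    rng = np.random.default_rng(seed)
    base = np.zeros(G, dtype=np.int8)
    base[:M] = 1  # permuting an indicator vector = permuting labelled genes
    curves = np.empty((n_reps, K), dtype=np.int32)
    for r in range(n_reps):
        curves[r] = np.cumsum(rng.permutation(base)[:K])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(curves, [100 * alpha, 100 * (1 - alpha)], axis=0)
    return curves.mean(axis=0), lo, hi


def concordance_curve(
    ranked: RankedList,
    target: set[str],
    universe: set[str],
    K: int | None = None,
    n_reps: int = 5000,
    seed: int = 0,
    level: float = 0.95,
) -> OverlapCurve:
    """Observed overlap curve plus its Monte-Carlo null band."""
    if K is None:
        K = len(ranked)
    K = min(K, len(ranked))
    observed = overlap_curve(ranked, target, universe, K)
    mean, lo, hi = simulate_null_overlap(universe, target, K, n_reps, seed, level)
    return OverlapCurve(
        k_grid=np.arange(1, K + 1),
        observed=observed,
        null_mean=mean,
        null_lo=lo,
        null_hi=hi,
        n_reps=n_reps,
        seed=seed,
        target_size=len(target),
        universe_size=len(universe),
    )
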