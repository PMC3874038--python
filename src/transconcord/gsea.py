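"""Weighted Kolmogorov-Smirnov gene-set enrichment with connectivity scores.

A gene set S is scored against a ranked gene list by the running sum
``P_hit(i) - P_miss(i)``, where hits accumulate weight ``|r_j|^p`` (p = 1 by
default) and misses accumulate uniformly. The enrichment score ES is the
signed extremum of that running sum; the normalized score NES divides ES by
the mean |ES| of sign-matched random gene sets of the same size, and the
permutation p-value and Subramanian-style FDR come from the same null.

When a transcriptome's up and down halves are both scored against one ranked
list, the paired summary is the connectivity score CS = (ES_up - ES_down)/2:
+1 means perfect concordance (up genes at the top, down genes at the bottom),
-1 perfect anti-concordance.

Gene-set permutation (random sets of matched size) is used rather than
phenotype permutation: with five samples per arm there are only 126 distinct
relabelings, too few for a stable NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_species import RankedList
from .model import GeneSignature, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ConnectivityScore",
    "rank_all_genes",
    "enrichment_score",
    "null_es",
    "normalize_es",
    "gsea_fdr",
    "connectivity_score",
    "run_gsea",
]


@dataclass
class EnrichmentResult:
    """ES/NES/p/q for one gene-set half against one ranked list."""

    set_name: str
    set_size: int
    es: float
    nes: float
    p_perm: float
    q_fdr: float
    peak_index: int


@dataclass(frozen=True)
class ConnectivityScore:
    """Paired up/down summary: cs = (es_up - es_down) / 2."""

    name: str
    es_up: float
    es_down: float

    @property
    def cs(self) -> float:
        return connectivity_score(self.es_up, self.es_down)


def rank_all_genes(
    table: pd.DataFrame, metric: str = "signed_log2fch"
) -> RankedList:
    """Full descending ordering of a gene-level differential table.

    ``metric`` is ``"signed_log2fch"`` (default, fold-change ranking) or
    ``"t_mod"``. Ties break lexicographically by gene id, so the output is
    independent of input row order.
    """
    if table.empty:
        raise ValidationError("differential table is empty")
    col = {"signed_log2fch": "log2fch", "t_mod": "t_mod"}.get(metric)
    if col is None:
        raise ValueError(f"unknown ranking metric {metric!r}")
    s = table[col]
    order = sorted(table.index, key=lambda g: (-s[g], g))
    return RankedList(
        tuple(order),
        tuple(float(s[g]) for g in order),
        "all",
        len(table),
    )


def _es_from_membership(
    stats: np.ndarray, member: np.ndarray, weight_p: float
) -> tuple[float, int, np.ndarray]:
    """Running-sum ES for a boolean membership vector over a ranked list."""
    n = stats.size
    n_h = int(member.sum())
    w = np.where(member, np.abs(stats) ** weight_p, 0.0)
    total_w = w.sum()
    if total_w == 0:
        # all member weights zero (e.g. ranking stats are 0); fall back to
        # unweighted steps so the score remains defined
        w = member.astype(float)
        total_w = w.sum()
    p_hit = np.cumsum(w) / total_w
    p_miss = np.cumsum(~member) / (n - n_h)
    running = p_hit - p_miss
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def enrichment_score(
    ranked: RankedList, gene_set: set[str], weight_p: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """Weighted-KS enrichment score of ``gene_set`` along ``ranked``.

    Returns ``(es, peak_index, running_sum)`` where ``es`` is the running-sum
    value of maximal absolute magnitude (signed) and ``peak_index`` its
    0-based position. Genes of the set absent from the list are ignored; a
    set covering the whole list is rejected (the complement is empty).
    """
    ids = ranked.gene_ids
    member = np.fromiter((g in gene_set for g in ids), dtype=bool, count=len(ids))
    n_h = int(member.sum())
    if n_h == 0:
        log.warning("enrichment_score: no gene of the set appears in the ranked list")
        return float("nan"), -1, np.zeros(len(ids))
    if n_h == len(ids):
        raise ValidationError("gene set covers the entire ranked list")
    stats = np.asarray(ranked.stats, dtype=float)
    return _es_from_membership(stats, member, weight_p)


def null_es(
    ranked: RankedList,
    set_size: int,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> np.ndarray:
    """Permutation null: ES of uniform random gene sets of ``set_size``."""
    n = len(ranked)
    if not (0 < set_size < n):
        raise ValidationError(f"set_size must be in (0, {n}), got {set_size}")
    stats = np.asarray(ranked.stats, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for k in range(n_perm):
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=set_size, replace=False)] = True
        out[k], _, _ = _es_from_membership(stats, member, weight_p)
    return out


def normalize_es(es: float, null: np.ndarray) -> tuple[float, float]:
    """NES and permutation p-value from a sign-matched null.

    ``nes = es / mean(|null_k|)`` over null values of the same sign as
    ``es``; ``p_perm`` is the add-one-smoothed fraction of sign-matched null
    values at least as extreme. NaN (flagged) when no null value matches the
    sign.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    if es == 0:
        return 0.0, 1.0
    matched = null[np.sign(null) == np.sign(es)]
    if matched.size == 0:
        log.warning("normalize_es: no sign-matched permutation; NES undefined")
        return float("nan"), 1.0 / (null.size + 1.0)
    nes = es / np.abs(matched).mean()
    p = (1.0 + (np.abs(matched) >= abs(es)).sum()) / (matched.size + 1.0)
    return float(nes), float(p)


def gsea_fdr(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Subramanian-style FDR q per observed NES from the pooled null NES.

    For each observed NES*, q is the ratio of the sign-matched tail fractions
    of the null and the observed NES distributions at |NES*|, clipped to 1
    and floored at 1/(n_null + 1).
    """
    observed_nes = np.asarray(observed_nes, dtype=float)
    null_nes = np.asarray(null_nes, dtype=float)
    null_nes = null_nes[np.isfinite(null_nes)]
    q = np.empty_like(observed_nes)
    for i, nes in enumerate(observed_nes):
        if not np.isfinite(nes):
            q[i] = float("nan")
            continue
        sgn = np.sign(nes) if nes != 0 else 1.0
        null_m = null_nes[np.sign(null_nes) == sgn]
        obs_m = observed_nes[np.sign(observed_nes) == sgn]
        if null_m.size == 0 or obs_m.size == 0:
            q[i] = float("nan")
            continue
        frac_null = (np.abs(null_m) >= abs(nes)).mean()
        frac_obs = (np.abs(obs_m) >= abs(nes)).mean()
        raw = frac_null / frac_obs if frac_obs > 0 else 1.0
        q[i] = min(1.0, max(raw, 1.0 / (null_m.size + 1.0)))
    return q


def connectivity_score(es_up: float, es_down: float) -> float:
    """Connectivity score cs = (es_up - es_down) / 2 of a paired signature."""
    for name, v in (("es_up", es_up), ("es_down", es_down)):
        if not -1.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [-1, 1]")
    return (es_up - es_down) / 2.0


def run_gsea(
    table: pd.DataFrame,
    signatures: list[GeneSignature],
    metric: str = "signed_log2fch",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every signature half against a ranked differential table.

    Returns ``(results, cs_table)``: one row per non-empty signature half
    with ES, NES, permutation p and FDR q, and one row per signature with the
    paired connectivity score.
    """
    ranked = rank_all_genes(table, metric=metric)
    halves: list[tuple[str, str, set[str]]] = []
    for sig in signatures:
        if sig.up:
            halves.append((sig.name, "up", set(sig.up)))
        if sig.down:
            halves.append((sig.name, "down", set(sig.down)))

    rows = []
    all_null_nes: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for name, side, genes in halves:
        detected = genes & set(ranked.gene_ids)
        if not detected:
            log.warning("run_gsea: %s_%s has no detected genes; skipped", name, side)
            continue
        es, peak, _ = enrichment_score(ranked, detected, weight_p)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        null = null_es(ranked, len(detected), n_perm, sub_seed, weight_p)
        nes, p = normalize_es(es, null)
        pos, neg = null[null > 0], null[null < 0]
        null_nes = np.concatenate(
            [
                pos / pos.mean() if pos.size else pos,
                neg / np.abs(neg).mean() if neg.size else neg,
            ]
        )
        all_null_nes.append(null_nes)
        rows.append(
            {
                "set": name,
                "side": side,
                "size": len(detected),
                "es": es,
                "nes": nes,
                "p_perm": p,
                "peak_index": peak,
            }
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        pooled = np.concatenate(all_null_nes) if all_null_nes else np.array([])
        results["q_fdr"] = gsea_fdr(results["nes"].to_numpy(), pooled)

    cs_rows = []
    for sig in signatures:
        r_up = results[(results["set"] == sig.name) & (results["side"] == "up")]
        r_dn = results[(results["set"] == sig.name) & (results["side"] == "down")]
        if len(r_up) == 1 and len(r_dn) == 1:
            es_u = float(r_up["es"].iloc[0])
            es_d = float(r_dn["es"].iloc[0])
            cs_rows.append(
                {
                    "set": sig.name,
                    "es_up": es_u,
                    "es_down": es_d,
                    "cs": connectivity_score(es_u, es_d),
                }
            )
    return results, pd.DataFrame(cs_rows)
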