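"""Treatment-response normalization metrics.

For each gene altered in disease, a treatment arm's effect is summarized by
three quantities, all defined on arm means of the log2 expression matrix:

* percent improvement toward recovery —
  ``100 * (mean_disease - mean_treated) / (mean_disease - mean_naive)``:
  0% means the treated arm sits at the disease level, 100% at the naive
  level; the sign cancellation makes the same formula work for up- and
  down-regulated genes. Genes whose disease effect is below ``eps`` (default
  0.1 log2 units) are excluded from summaries and counted; values are
  clipped to [-200, 300] for summary robustness.
* fold change toward recovery — ``2**|mean_disease - mean_treated|``, signed
  positive when the treated mean moved toward naive and negative when it
  moved away (1.0 when it did not move).
* modulated fraction — the fraction of disease DEGs that are also DEGs in
  the treated-vs-disease contrast at the same cut-offs, by default requiring
  the treatment direction to oppose the disease direction.

Summaries are reported over all disease DEGs and stratified into genes
shared with a human signature versus species-unique genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DEGSet, call_degs
from .model import ExpressionStudy, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ResponseSummary",
    "modulated_fraction",
    "improvement_pct",
    "fch_toward_recovery",
    "summarize_response",
]

CLIP_LO, CLIP_HI = -200.0, 300.0


@dataclass
class ResponseSummary:
    """Aggregate treatment-response statistics for one treatment arm."""

    arm: str
    n_disease_genes: int
    n_excluded: int
    modulated_fraction: float
    mean_improvement_pct: float
    pct_genes_improved_over_50: float
    mean_fch_toward_recovery: float
    strata: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n_disease_genes": self.n_disease_genes,
            "n_excluded": self.n_excluded,
            "modulated_fraction": self.modulated_fraction,
            "mean_improvement_pct": self.mean_improvement_pct,
            "pct_genes_improved_over_50": self.pct_genes_improved_over_50,
            "mean_fch_toward_recovery": self.mean_fch_toward_recovery,
            "strata": self.strata,
        }


def modulated_fraction(
    disease_degs: DEGSet,
    treated_vs_disease: pd.DataFrame,
    fch_cut: float = 2.0,
    fdr_cut: float = 0.05,
    require_opposite: bool = True,
) -> float:
    """Fraction of disease DEGs that a treatment significantly modulates.

    A disease DEG counts as modulated when it is a DEG of the
    treated-vs-disease contrast at the same cut-offs and, if
    ``require_opposite``, its treatment direction opposes its disease
    direction (a drug pushing a disease gene further from naive is not
    modulation).
    """
    if len(disease_degs) == 0:
        raise ValidationError("disease DEG set is empty; modulated fraction undefined")
    trt = call_degs(treated_vs_disease, fch_cut=fch_cut, fdr_cut=fdr_cut)
    if require_opposite:
        # treated_vs_disease is treated minus disease: recovery of an
        # up-in-disease gene appears as down in this contrast
        modulated = (disease_degs.up & trt.down) | (disease_degs.down & trt.up)
    else:
        modulated = disease_degs.all_genes & trt.all_genes
    return len(modulated) / len(disease_degs)


def improvement_pct(
    mean_naive: np.ndarray,
    mean_disease: np.ndarray,
    mean_treated: np.ndarray,
    eps: float = 0.1,
    clip: bool = True,
) -> np.ndarray:
    """Percent improvement toward recovery per gene; NaN where the disease
    effect is below ``eps`` (those genes are excluded from summaries)."""
    mean_naive = np.asarray(mean_naive, dtype=float)
    mean_disease = np.asarray(mean_disease, dtype=float)
    mean_treated = np.asarray(mean_treated, dtype=float)
    denom = mean_disease - mean_naive
    small = np.abs(denom) <= eps
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mean_disease - mean_treated) / denom
    pct = np.where(small, np.nan, pct)
    if clip:
        n_clip = int(np.nansum((pct < CLIP_LO) | (pct > CLIP_HI)))
        if n_clip:
            log.info("improvement_pct: clipped %d value(s) to [%.0f, %.0f]",
                     n_clip, CLIP_LO, CLIP_HI)
        pct = np.clip(pct, CLIP_LO, CLIP_HI)
    return pct


def fch_toward_recovery(
    mean_naive: np.ndarray,
    mean_disease: np.ndarray,
    mean_treated: np.ndarray,
) -> np.ndarray:
    """Linear fold change of the treated-vs-disease shift, oriented toward
    naive: ``sign * 2**|mean_disease - mean_treated|`` with positive sign
    when the movement reduces the distance to the naive mean. No movement
    gives +1.0."""
    mean_naive = np.asarray(mean_naive, dtype=float)
    mean_disease = np.asarray(mean_disease, dtype=float)
    mean_treated = np.asarray(mean_treated, dtype=float)
    shift = mean_disease - mean_treated
    disease_dir = mean_disease - mean_naive
    toward = np.sign(shift) * np.sign(disease_dir)
    sign = np.where(toward < 0, -1.0, 1.0)  # no movement -> +1
    return sign * np.exp2(np.abs(shift))


def _stratum_stats(pct: np.ndarray, fch: np.ndarray) -> dict[str, float]:
    ok = ~np.isnan(pct)
    n = int(ok.sum())
    if n == 0:
        return {"n": 0}
    return {
        "n": n,
        "mean_improvement_pct": float(pct[ok].mean()),
        "mean_fch_toward_recovery": float(fch[ok].mean()),
    }


def summarize_response(
    study: ExpressionStudy,
    disease_degs: DEGSet,
    treatment_tables: dict[str, pd.DataFrame],
    shared_set: set[str] | None = None,
    naive_arm: str = "naive",
    disease_arm: str = "disease",
    fch_cut: float = 2.0,
    fdr_cut: float = 0.05,
    require_opposite: bool = True,
    eps: float = 0.1,
) -> dict[str, ResponseSummary]:
    """Per-treatment-arm response summary over the disease DEGs.

    ``treatment_tables`` maps each treatment arm label to its
    treated-vs-disease differential table (used for the modulated fraction).
    ``shared_set`` holds the disease DEGs shared with a human signature
    (already translated to this study's species); the remainder form the
    species-unique stratum.
    """
    genes = sorted(disease_degs.all_genes)
    if not genes:
        raise ValidationError("disease DEG set is empty")
    missing = [g for g in genes if g not in study.values.index]
    if missing:
        raise ValidationError(f"disease DEG(s) absent from the study: {missing[:5]}")
    m_naive = study.arm_values(naive_arm).loc[genes].mean(axis=1).to_numpy()
    m_dis = study.arm_values(disease_arm).loc[genes].mean(axis=1).to_numpy()
    shared_mask = np.array([g in (shared_set or set()) for g in genes])

    out: dict[str, ResponseSummary] = {}
    for arm, table in treatment_tables.items():
        m_trt = study.arm_values(arm).loc[genes].mean(axis=1).to_numpy()
        pct = improvement_pct(m_naive, m_dis, m_trt, eps=eps)
        fch = fch_toward_recovery(m_naive, m_dis, m_trt)
        ok = ~np.isnan(pct)
        n_excl = int((~ok).sum())
        if n_excl:
            log.info("summarize_response(%s): excluded %d gene(s) with disease "
                     "effect below %.2f log2 units", arm, n_excl, eps)
        strata = {
            "shared_with_human": _stratum_stats(pct[shared_mask], fch[shared_mask]),
            "mouse_only": _stratum_stats(pct[~shared_mask], fch[~shared_mask]),
        }
        out[arm] = ResponseSummary(
            arm=arm,
            n_disease_genes=len(genes),
            n_excluded=n_excl,
            modulated_fraction=modulated_fraction(
                disease_degs, table, fch_cut, fdr_cut, require_opposite
            ),
            mean_improvement_pct=float(pct[ok].mean()) if ok.any() else float("nan"),
            pct_genes_improved_over_50=float((pct[ok] > 50).mean()) if ok.any() else float("nan"),
            mean_fch_toward_recovery=float(fch[ok].mean()) if ok.any() else float("nan"),
            strata=strata,
        )
    return out
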