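"""Expression filtering and empirical-Bayes moderated-t differential expression.

The workflow mirrors the standard microarray pipeline: filter a normalized
log2 matrix to expressed, variable genes; compute two-group sufficient
statistics per gene; shrink per-gene variances toward an inverse-chi-square
prior whose hyperparameters (d0, s0^2) are estimated from the ensemble by
moment matching on log variances; form the moderated t with d0 extra degrees
of freedom; adjust p-values by Benjamini-Hochberg; and call differentially
expressed genes at FDR < 0.05 and |fold change| >= 2.

Fold changes are reported on the signed linear scale, ``sign * 2**|dlog2|``
(negative for down-regulation), the convention used in microarray tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionStudy, InferenceError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EBayesPrior",
    "DEGSet",
    "filter_expressed",
    "fit_contrast",
    "estimate_eb_prior",
    "moderated_t",
    "adjust_bh",
    "fit_differential",
    "call_degs",
    "collapse_to_genes",
    "signed_fold_change",
]


@dataclass(frozen=True)
class EBayesPrior:
    """Hyperparameters of the scaled inverse-chi-square variance prior.

    ``d0`` is the prior degrees of freedom (may be ``math.inf`` when the
    observed variances show no excess spread beyond sampling noise) and
    ``s0_sq`` the prior variance, in squared log2-intensity units.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValidationError(f"prior d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValidationError(f"prior s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed gene calls for one contrast."""

    contrast: str
    up: frozenset[str]
    down: frozenset[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValidationError("DEG up and down sets overlap")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


# ---------------------------------------------------------------------------
# filtering


def filter_expressed(
    study: ExpressionStudy,
    min_level: float = 2.0,
    min_samples: int = 3,
    min_sd: float = 0.1,
) -> ExpressionStudy:
    """Keep genes expressed above ``min_level`` (log2) in at least
    ``min_samples`` samples and with row SD >= ``min_sd``.

    The SD cut is a minimum-variability filter (sample SD, ddof=1): flat genes
    carry no contrast information. Gene order is preserved.
    """
    if min_samples > len(study.sample_ids):
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {len(study.sample_ids)} samples"
        )
    arr = study.values.to_numpy()
    n_high = (arr > min_level).sum(axis=1)
    sd = arr.std(axis=1, ddof=1)
    keep = (n_high >= min_samples) & (sd >= min_sd)
    if not keep.any():
        log.warning("expression filter removed every gene")
    kept = study.values.loc[keep]
    return ExpressionStudy(kept, dict(study.groups), study.species)


# ---------------------------------------------------------------------------
# two-group sufficient statistics


def fit_contrast(study: ExpressionStudy, arm_a: str, arm_b: str) -> pd.DataFrame:
    """Per-gene two-group sufficient statistics for the contrast a - b.

    Returns a DataFrame indexed by gene id with columns ``mean_a``, ``mean_b``,
    ``delta`` (mean_a - mean_b), ``s2`` (pooled residual variance) and ``df``
    (n_a + n_b - 2).
    """
    xa = study.arm_values(arm_a).to_numpy()
    xb = study.arm_values(arm_b).to_numpy()
    n_a, n_b = xa.shape[1], xb.shape[1]
    if n_a < 2 or n_b < 2:
        raise InferenceError(
            f"arms {arm_a!r} (n={n_a}) and {arm_b!r} (n={n_b}) need >=2 samples each"
        )
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    ss_a = ((xa - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = n_a + n_b - 2
    s2 = (ss_a + ss_b) / df
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta": mean_a - mean_b,
            "s2": s2,
            "df": float(df),
        },
        index=study.values.index,
    )
    out.attrs["n_a"], out.attrs["n_b"] = n_a, n_b
    out.attrs["arm_a"], out.attrs["arm_b"] = arm_a, arm_b
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        return math.inf
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x approximation
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        tetra = special.polygamma(2, x)
        # Newton step on 1/trigamma, which is nearly linear in x
        delta = tri * (1.0 - tri / y) / tetra
        x += delta
        if x <= 0:
            x = 1e-8
        if abs(delta) < tol * x:
            break
    return float(x)


def estimate_eb_prior(s2: np.ndarray, df: np.ndarray | float) -> EBayesPrior:
    """Estimate (d0, s0^2) by moment matching on log variances.

    With ``s2_g ~ s0^2 * chi2_df / df`` scaled by a gene effect, the quantity
    ``e_g = log s2_g - digamma(df_g/2) + log(df_g/2)`` is an unbiased-in-mean
    transform whose excess variance over ``trigamma(df_g/2)`` identifies d0:
    ``trigamma(d0/2) = var(e) - mean(trigamma(df_g/2))``, solved by monotone
    Newton iteration; s0^2 follows from ``mean(e)`` and d0. When the excess is
    non-positive, d0 = +inf and ``s0^2 = exp(mean(e))``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    pos = s2 > 0
    if not pos.any():
        raise InferenceError("all residual variances are zero; cannot fit a prior")
    if pos.sum() < 2:
        raise InferenceError("need >=2 genes with positive variance to fit a prior")
    if not pos.all():
        log.info("prior fit excludes %d gene(s) with zero variance", int((~pos).sum()))
    s2, df = s2[pos], df[pos]
    half = df / 2.0
    e = np.log(s2) - special.digamma(half) + np.log(half)
    e_mean = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, half).mean())
    if excess <= 0:
        return EBayesPrior(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t


def moderated_t(
    delta: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray | float,
    prior: EBayesPrior,
    n_a: int,
    n_b: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t statistic, total df and two-sided p-value per gene.

    The posterior variance ``s_tilde^2 = (d0*s0^2 + df*s2) / (d0 + df)``
    shrinks each gene's variance toward the prior; the t statistic gains
    ``d0`` degrees of freedom. With d0 = +inf the variance is s0^2 exactly and
    p-values come from the normal limit. A zero posterior variance yields a
    signed-infinite t with p = 0 (flagged in the log).
    """
    delta = np.asarray(delta, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), delta.shape).astype(float)
    c = 1.0 / n_a + 1.0 / n_b
    if math.isinf(prior.d0):
        s_tilde_sq = np.full_like(delta, prior.s0_sq)
        df_total = np.full_like(delta, math.inf)
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s_tilde_sq * c)
    zero_var = s_tilde_sq == 0
    if zero_var.any():
        log.warning("%d gene(s) with zero posterior variance: t set to +/-inf", int(zero_var.sum()))
        t = np.where(zero_var, np.sign(delta) * np.inf, t)
        t = np.where(zero_var & (delta == 0), 0.0, t)
    if math.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(zero_var & np.isinf(t), 0.0, p)
    return t, df_total, p


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fch: np.ndarray) -> np.ndarray:
    """Signed linear fold change ``sign * 2**|dlog2|``; 0 maps to +1."""
    log2fch = np.asarray(log2fch, dtype=float)
    sign = np.where(log2fch < 0, -1.0, 1.0)
    return sign * np.exp2(np.abs(log2fch))


# ---------------------------------------------------------------------------
# the full differential table


def fit_differential(
    study: ExpressionStudy,
    arm_a: str,
    arm_b: str,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Full per-gene differential table for the contrast arm_a vs arm_b.

    Columns: ``mean_<arm_a>``, ``mean_<arm_b>``, ``log2fch`` (a - b),
    ``fch_signed``, ``s2``, ``df_residual``, ``t_mod``, ``df_total``, ``p``,
    ``q``. The prior is estimated from all genes of the contrast unless one is
    supplied (shrinkage must be estimated on the ensemble, not on hits).
    """
    suff = fit_contrast(study, arm_a, arm_b)
    if prior is None:
        prior = estimate_eb_prior(suff["s2"].to_numpy(), suff["df"].to_numpy())
    t, df_total, p = moderated_t(
        suff["delta"].to_numpy(),
        suff["s2"].to_numpy(),
        suff["df"].to_numpy(),
        prior,
        suff.attrs["n_a"],
        suff.attrs["n_b"],
    )
    q = adjust_bh(p)
    table = pd.DataFrame(
        {
            f"mean_{arm_a}": suff["mean_a"],
            f"mean_{arm_b}": suff["mean_b"],
            "log2fch": suff["delta"],
            "fch_signed": signed_fold_change(suff["delta"].to_numpy()),
            "s2": suff["s2"],
            "df_residual": suff["df"],
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "q": q,
        },
        index=suff.index,
    )
    table.attrs.update(suff.attrs)
    table.attrs["contrast"] = f"{arm_a}_vs_{arm_b}"
    table.attrs["prior"] = prior
    return table


def call_degs(
    table: pd.DataFrame, fch_cut: float = 2.0, fdr_cut: float = 0.05
) -> DEGSet:
    """Call DEGs at FDR < ``fdr_cut`` and |fold change| >= ``fch_cut``.

    The fold-change boundary is inclusive and the FDR boundary exclusive, so
    reported counts are reproducible to the digit.
    """
    sig = table["q"] < fdr_cut
    up = table.index[sig & (table["fch_signed"] >= fch_cut)]
    down = table.index[sig & (table["fch_signed"] <= -fch_cut)]
    return DEGSet(
        contrast=table.attrs.get("contrast", ""),
        up=frozenset(up),
        down=frozenset(down),
        thresholds={"fch_cut": fch_cut, "fdr_cut": fdr_cut},
    )


def collapse_to_genes(
    table: pd.DataFrame, probe_to_gene: dict[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level table to gene level, keeping the probe with
    maximal |t_mod| per gene (ties broken by lexicographically smaller probe
    id). Probes absent from the map are dropped and counted in the log."""
    mapped = table.index.map(probe_to_gene.get)
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        log.info("collapse_to_genes: dropped %d unmapped probe(s)", n_unmapped)
    sub = table.loc[~mapped.isna()].copy()
    sub["_gene"] = mapped[~mapped.isna()]
    sub["_abs_t"] = sub["t_mod"].abs()
    sub = sub.sort_values(
        by=["_gene", "_abs_t"], ascending=[True, False], kind="mergesort"
    )
    # mergesort is stable, so sorting by probe id first fixes the tie-break
    sub = sub.sort_index(kind="mergesort").sort_values(
        by=["_gene", "_abs_t"], ascending=[True, False], kind="mergesort"
    )
    keep = ~sub["_gene"].duplicated(keep="first")
    out = sub.loc[keep].copy()
    out["probe_id"] = out.index
    out = out.set_index("_gene").drop(columns=["_abs_t"])
    out.index.name = "gene_id"
    out.attrs.update(table.attrs)
    return out
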