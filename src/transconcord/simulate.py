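"""Synthetic two-species expression studies with full ground truth.

The generator emulates the design every other module assumes: a four-arm
mouse study (naive, disease, and two treatment arms, five animals per arm)
and a human lesional-vs-non-lesional study linked to it through an ortholog
map.

Per gene g the mouse model is

    x_gs = mu_g + beta_g * I[s in disease-derived arms] * (1 - rho_{g,arm})
           + eps_gs,      eps_gs ~ Normal(0, sigma_g^2)

with baseline mu_g ~ Normal(6, 1.5^2) log2 units, gene variances drawn from
a scaled inverse-chi-square prior sigma_g^2 ~ d0*s0^2 / chi2_{d0}, a fraction
``frac_de`` of genes disease-altered with signed log2 effect beta_g
(magnitude = minimum + Gamma draw, so |fold change| >= 2 is attainable by
construction; sign up-biased by ``up_bias``), and a per-gene, per-arm
recovery fraction rho in [0,1] (0 = untreated; the disease arm has rho = 0
by definition). The human study shares a configurable fraction of mouse DE
genes as sign-concordant DE orthologs and adds human-only DE genes, under
the same noise model.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ExpressionStudy, OrthologMap, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_mouse_study",
    "generate_human_study",
    "generate_ortholog_map",
    "generate_all",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-species experiment.

    Defaults correspond to the emulated study design: 5000 genes, four mouse
    arms of five animals, 20% disease-altered genes with log2 effects of
    magnitude >= 1 (so fold change >= 2), variance prior (d0, s0^2) =
    (4, 0.04), recovery fractions rho ~ Beta(2, 2) per treatment arm, a
    ten-vs-ten human study sharing 40% of mouse DE genes, and 90% ortholog
    coverage with 5% many-to-many sources.
    """

    n_genes: int = 5000
    n_per_arm: int = 5
    treatment_arms: tuple[str, ...] = ("trtA", "trtB")
    naive_arm: str = "naive"
    disease_arm: str = "disease"
    # disease effect
    frac_de: float = 0.2
    effect_min: float = 1.0
    effect_gamma_shape: float = 2.0
    effect_gamma_scale: float = 0.5
    up_bias: float = 0.5
    # noise
    d0: float = 4.0
    s0_sq: float = 0.04
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    # recovery: per-arm Beta(a, b) for rho, or a fixed value overriding it
    recovery_beta: tuple[float, float] = (2.0, 2.0)
    recovery_fixed: dict[str, float] = field(default_factory=dict)
    # human study
    n_ls: int = 10
    n_nl: int = 10
    frac_shared: float = 0.4
    frac_human_only: float = 0.1
    # ortholog map
    ortholog_coverage: float = 0.9
    many_to_many_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("frac_de", "up_bias", "frac_shared", "frac_human_only",
                     "ortholog_coverage", "many_to_many_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        if self.n_per_arm < 2 or self.n_ls < 2 or self.n_nl < 2:
            raise ValidationError("every arm needs n >= 2")
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("variance prior requires d0 > 0 and s0_sq > 0")
        for arm, rho in self.recovery_fixed.items():
            if not 0.0 <= rho <= 1.0:
                raise ValidationError(f"recovery_fixed[{arm!r}]={rho} outside [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-gene generating parameters, the oracle for recovery tests."""

    genes: pd.DataFrame  # is_de, sign, beta, sigma_sq, rho_<arm>... per mouse gene
    human_genes: pd.DataFrame | None = None  # is_de, sign, beta, shared_from
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.genes.index[self.genes["is_de"]])


def _mouse_ids(n: int) -> list[str]:
    return [f"mg{i:05d}" for i in range(n)]


def _draw_effects(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mag = cfg.effect_min + rng.gamma(cfg.effect_gamma_shape, cfg.effect_gamma_scale, size=n)
    sign = np.where(rng.random(n) < cfg.up_bias, 1.0, -1.0)
    return mag * sign, sign


def _draw_sigma_sq(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return cfg.d0 * cfg.s0_sq / rng.chisquare(cfg.d0, size=n)


def generate_mouse_study(
    config: SimulationConfig, seed: int
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the four-arm mouse study and its ground truth."""
    rng = np.random.default_rng(seed)
    g = config.n_genes
    gene_ids = _mouse_ids(g)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    sigma_sq = _draw_sigma_sq(config, g, rng)
    is_de = rng.random(g) < config.frac_de
    beta = np.zeros(g)
    sign = np.zeros(g)
    n_de = int(is_de.sum())
    if n_de:
        beta[is_de], sign[is_de] = _draw_effects(config, n_de, rng)

    a, b = config.recovery_beta
    rho: dict[str, np.ndarray] = {}
    for arm in config.treatment_arms:
        r = np.zeros(g)
        if arm in config.recovery_fixed:
            r[is_de] = config.recovery_fixed[arm]
        elif n_de:
            r[is_de] = rng.beta(a, b, size=n_de)
        rho[arm] = r

    arms = [config.naive_arm, config.disease_arm, *config.treatment_arms]
    sample_ids, groups, cols = [], {}, []
    for arm in arms:
        if arm == config.naive_arm:
            effect = np.zeros(g)
        elif arm == config.disease_arm:
            effect = beta  # rho = 0: the disease+vehicle arm is untreated
        else:
            effect = beta * (1.0 - rho[arm])
        for i in range(config.n_per_arm):
            sid = f"{arm}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = arm
            cols.append(mu + effect + rng.normal(0.0, np.sqrt(sigma_sq)))
    values = pd.DataFrame(
        np.column_stack(cols), index=gene_ids, columns=sample_ids, dtype=float
    )
    values.index.name = "gene_id"
    study = ExpressionStudy(values, groups, species="mouse")

    truth_cols = {
        "is_de": is_de,
        "sign": sign,
        "beta": beta,
        "sigma_sq": sigma_sq,
        "mu": mu,
    }
    for arm in config.treatment_arms:
        truth_cols[f"rho_{arm}"] = rho[arm]
    truth = GroundTruth(pd.DataFrame(truth_cols, index=gene_ids))
    truth.genes.index.name = "gene_id"
    return study, truth


def generate_ortholog_map(
    config: SimulationConfig, seed: int
) -> OrthologMap:
    """Mouse-to-human ortholog pairs: each mouse gene is covered with
    probability ``ortholog_coverage``; covered genes gain a second human
    target at the ``many_to_many_rate``."""
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for i, mg in enumerate(_mouse_ids(config.n_genes)):
        if rng.random() < config.ortholog_coverage:
            pairs.append((mg, f"hs{i:05d}"))
            if rng.random() < config.many_to_many_rate:
                pairs.append((mg, f"hs{i:05d}b"))
    return OrthologMap(pairs)


def generate_human_study(
    config: SimulationConfig,
    seed: int,
    mouse_truth: GroundTruth,
    omap: OrthologMap,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate the human lesional (LS) vs non-lesional (NL) study.

    A fraction ``frac_shared`` of ortholog-covered mouse DE genes get
    sign-concordant human DE orthologs (fresh effect magnitudes); a fraction
    ``frac_human_only`` of the remaining human genes are DE independently of
    the mouse. Noise model identical to the mouse study.
    """
    rng = np.random.default_rng(seed)
    fwd = omap.forward()
    human_ids = sorted({t for ts in fwd.values() for t in ts})
    # unmapped human genes so the human universe is not exactly the map image
    n_extra = max(1, int(0.1 * config.n_genes))
    human_ids += [f"hu{i:05d}" for i in range(n_extra)]
    h = len(human_ids)
    pos = {g: i for i, g in enumerate(human_ids)}

    is_de = np.zeros(h, dtype=bool)
    sign = np.zeros(h)
    beta = np.zeros(h)
    shared_from = np.array([""] * h, dtype=object)

    mouse_de = [g for g in mouse_truth.genes.index[mouse_truth.genes["is_de"]] if g in fwd]
    n_shared = int(round(config.frac_shared * len(mouse_de)))
    shared_sources = list(rng.choice(mouse_de, size=n_shared, replace=False)) if n_shared else []
    for mg in shared_sources:
        hg = sorted(fwd[mg])[0]  # one concordant ortholog per shared gene
        i = pos[hg]
        if is_de[i]:
            continue
        is_de[i] = True
        sign[i] = mouse_truth.genes.at[mg, "sign"]
        mag, _ = _draw_effects(config, 1, rng)
        beta[i] = abs(mag[0]) * sign[i]
        shared_from[i] = mg

    candidates = np.flatnonzero(~is_de)
    n_only = int(round(config.frac_human_only * candidates.size))
    if n_only:
        chosen = rng.choice(candidates, size=n_only, replace=False)
        is_de[chosen] = True
        eff, sgn = _draw_effects(config, n_only, rng)
        beta[chosen], sign[chosen] = eff, sgn

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=h)
    sigma_sq = _draw_sigma_sq(config, h, rng)
    sample_ids, groups, cols = [], {}, []
    for arm, n in (("LS", config.n_ls), ("NL", config.n_nl)):
        effect = beta if arm == "LS" else np.zeros(h)
        for i in range(n):
            sid = f"{arm}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = arm
            cols.append(mu + effect + rng.normal(0.0, np.sqrt(sigma_sq)))
    values = pd.DataFrame(
        np.column_stack(cols), index=human_ids, columns=sample_ids, dtype=float
    )
    values.index.name = "gene_id"
    study = ExpressionStudy(values, groups, species="human")

    human_genes = pd.DataFrame(
        {
            "is_de": is_de,
            "sign": sign,
            "beta": beta,
            "sigma_sq": sigma_sq,
            "shared_from": shared_from,
        },
        index=human_ids,
    )
    human_genes.index.name = "gene_id"
    truth = GroundTruth(
        genes=mouse_truth.genes, human_genes=human_genes, pairs=list(omap.pairs)
    )
    return study, truth


def generate_all(
    config: SimulationConfig, seed: int
) -> dict:
    """Mouse study, ortholog map and human study from one master seed.

    Sub-seeds are spawned deterministically, so the whole bundle is a pure
    function of (config, seed).
    """
    ss = np.random.SeedSequence(seed)
    s_mouse, s_map, s_human = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    mouse_study, mouse_truth = generate_mouse_study(config, s_mouse)
    omap = generate_ortholog_map(config, s_map)
    human_study, truth = generate_human_study(config, s_human, mouse_truth, omap)
    return {
        "mouse_study": mouse_study,
        "human_study": human_study,
        "ortholog_map": omap,
        "truth": truth,
    }
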