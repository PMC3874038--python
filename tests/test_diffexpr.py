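import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import transconcord as tc
from tests.conftest import two_arm_study


def make_study(rows: dict[str, list[float]], arms: list[str]) -> tc.ExpressionStudy:
    ids = [f"s{i}" for i in range(len(arms))]
    df = pd.DataFrame(rows, index=ids).T
    return tc.ExpressionStudy(df, dict(zip(ids, arms)))


# ---------------------------------------------------------------------------
# expression filter


@pytest.mark.parametrize(
    "values,kept",
    [
        ([2.5, 2.5, 2.5, 2.5], False),  # passes the level cut but SD = 0
        ([3.0, 3.4, 2.8, 1.0], True),   # 3 samples above 2, SD > 0.1
        ([1.9, 1.8, 1.5, 1.2], False),  # never above the level cut
    ],
)
def test_filter_expressed_rule(values, kept):
    study = make_study({"g": values, "anchor": [5.0, 6.0, 5.5, 6.5]},
                       ["a", "a", "b", "b"])
    out = tc.filter_expressed(study)
    assert ("g" in out.gene_ids) is kept


def test_filter_preserves_order_and_warns_when_empty(caplog):
    study = make_study({"g1": [1, 1, 1, 1], "g2": [0, 0, 0, 0]}, ["a"] * 4)
    with caplog.at_level("WARNING"):
        out = tc.filter_expressed(study)
    assert out.gene_ids == [] and "removed every gene" in caplog.text


def test_filter_min_samples_exceeding_study_is_rejected(tiny_study):
    with pytest.raises(tc.ValidationError):
        tc.filter_expressed(tiny_study, min_samples=99)


# ---------------------------------------------------------------------------
# two-group sufficient statistics


def test_fit_contrast_exact_small_cases():
    study = make_study({"g": [5, 5, 3, 3]}, ["a", "a", "b", "b"])
    out = tc.fit_contrast(study, "a", "b")
    assert out.loc["g", "delta"] == 2 and out.loc["g", "s2"] == 0
    assert out.loc["g", "df"] == 2

    study = make_study({"g": [1, 2, 3, 1, 2, 3]}, ["a", "a", "a", "b", "b", "b"])
    out = tc.fit_contrast(study, "a", "b")
    assert out.loc["g", "delta"] == 0 and out.loc["g", "df"] == 4


def test_fit_contrast_matches_hand_pooled_variance():
    rng = np.random.default_rng(3)
    xa, xb = rng.normal(size=5), rng.normal(size=5)
    study = make_study({"g": list(xa) + list(xb)}, ["a"] * 5 + ["b"] * 5)
    out = tc.fit_contrast(study, "a", "b")
    pooled = (np.sum((xa - xa.mean()) ** 2) + np.sum((xb - xb.mean()) ** 2)) / 8
    assert out.loc["g", "s2"] == pytest.approx(pooled)


def test_fit_contrast_rejects_single_sample_arm():
    study = make_study({"g": [1, 2, 3]}, ["a", "a", "b"])
    with pytest.raises(tc.InferenceError):
        tc.fit_contrast(study, "a", "b")


# ---------------------------------------------------------------------------
# empirical-Bayes prior


def test_prior_identical_variances_give_infinite_d0():
    prior = tc.estimate_eb_prior(np.full(50, 0.04), 8.0)
    assert math.isinf(prior.d0)
    # s0^2 = exp(mean(e)); for constant s2 this is s2 times the df correction
    from scipy.special import digamma

    expected = 0.04 * math.exp(math.log(4.0) - digamma(4.0))
    assert prior.s0_sq == pytest.approx(expected, rel=1e-9)


def test_prior_excess_spread_gives_finite_d0():
    prior = tc.estimate_eb_prior(np.array([0.01, 1.0]), 8.0)
    assert 0 < prior.d0 < math.inf


def test_prior_all_zero_variances_rejected():
    with pytest.raises(tc.InferenceError):
        tc.estimate_eb_prior(np.zeros(10), 8.0)


@pytest.mark.parametrize("seed", range(5))
def test_prior_recovers_simulation_hyperparameters(seed):
    """s2 ~ scaled-inv-chi2(d0=4, s0^2=0.04) at G=5000, df=8: d0 within 20%."""
    rng = np.random.default_rng(seed)
    d0, s0_sq, df = 4.0, 0.04, 8.0
    s2_true = d0 * s0_sq / rng.chisquare(d0, 5000)
    s2 = s2_true * rng.chisquare(df, 5000) / df
    prior = tc.estimate_eb_prior(s2, df)
    assert prior.d0 == pytest.approx(d0, rel=0.2)
    assert prior.s0_sq == pytest.approx(s0_sq, rel=0.2)


# ---------------------------------------------------------------------------
# moderated t


def test_moderated_t_closed_form_fixture():
    # s_tilde^2 = (4*0.04 + 8*0.25) / 12 = 0.18; t = 1/sqrt(0.18 * 0.4)
    prior = tc.EBayesPrior(4.0, 0.04)
    t, df_total, p = tc.moderated_t(np.array([1.0]), np.array([0.25]), 8.0, prior, 5, 5)
    assert t[0] == pytest.approx(1.0 / math.sqrt(0.18 * 0.4))
    assert df_total[0] == 12.0
    assert p[0] == pytest.approx(2 * stats.t.sf(t[0], 12))


def test_moderated_t_zero_delta_gives_p_one():
    prior = tc.EBayesPrior(4.0, 0.04)
    t, _, p = tc.moderated_t(np.array([0.0]), np.array([0.25]), 8.0, prior, 5, 5)
    assert t[0] == 0.0 and p[0] == 1.0


def test_moderated_t_small_d0_limit_is_ordinary_t():
    rng = np.random.default_rng(7)
    delta = rng.normal(size=100)
    s2 = rng.chisquare(8, 100) / 8 * 0.05
    prior = tc.EBayesPrior(1e-12, 0.04)
    t_mod, _, _ = tc.moderated_t(delta, s2, 8.0, prior, 5, 5)
    t_ord = delta / np.sqrt(s2 * (1 / 5 + 1 / 5))
    np.testing.assert_allclose(t_mod, t_ord, rtol=1e-6)


def test_moderated_t_infinite_d0_uses_normal_limit():
    prior = tc.EBayesPrior(math.inf, 0.04)
    t, df_total, p = tc.moderated_t(np.array([0.4]), np.array([9.0]), 8.0, prior, 5, 5)
    # the huge observed variance is ignored entirely
    assert t[0] == pytest.approx(0.4 / math.sqrt(0.04 * 0.4))
    assert math.isinf(df_total[0])
    assert p[0] == pytest.approx(2 * stats.norm.sf(t[0]))


def test_moderated_t_zero_posterior_variance_flagged():
    prior = tc.EBayesPrior(1e-300, 1e-300)
    t, _, p = tc.moderated_t(np.array([1.0, -1.0]), np.array([0.0, 0.0]), 8.0, prior, 5, 5)
    assert t[0] == math.inf and t[1] == -math.inf and (p == 0).all()


@given(
    s2=st.floats(1e-6, 10.0),
    d0=st.floats(0.1, 50.0),
    s0=st.floats(1e-4, 5.0),
    df=st.floats(2.0, 20.0),
)
@settings(deadline=None, derandomize=True, max_examples=200)
def test_posterior_variance_between_prior_and_observed(s2, d0, s0, df):
    prior = tc.EBayesPrior(d0, s0)
    s_tilde_sq = (d0 * s0 + df * s2) / (d0 + df)
    assert min(s2, s0) - 1e-12 <= s_tilde_sq <= max(s2, s0) + 1e-12


# ---------------------------------------------------------------------------
# BH adjustment


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Step-up definition: q_i = min over p_(j) >= p_(i) of p_(j)*m/rank(j)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15]
        q[i] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize("seed", range(10))
def test_bh_matches_bruteforce_on_random_vectors(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 40))
    np.testing.assert_allclose(tc.adjust_bh(p), bh_bruteforce(p), atol=1e-12)


def test_bh_known_small_cases():
    np.testing.assert_allclose(tc.adjust_bh(np.ones(3)), np.ones(3))
    np.testing.assert_allclose(
        tc.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(tc.adjust_bh(np.array([0.2])), [0.2])


def test_bh_is_monotone_and_dominates_p():
    rng = np.random.default_rng(0)
    p = rng.random(200)
    q = tc.adjust_bh(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(tc.ValidationError):
        tc.adjust_bh(np.array([0.5, 1.5]))


# ---------------------------------------------------------------------------
# DEG calling and probe collapse


def _table(rows):
    df = pd.DataFrame(rows).set_index("gene_id")
    df.attrs["contrast"] = "test"
    return df


def test_call_degs_boundaries():
    table = _table(
        [
            {"gene_id": "g1", "fch_signed": 2.0, "q": 0.049},
            {"gene_id": "g2", "fch_signed": 5.0, "q": 0.2},
            {"gene_id": "g3", "fch_signed": -2.0, "q": 0.01},
            {"gene_id": "g4", "fch_signed": 2.0, "q": 0.05},
        ]
    )
    degs = tc.call_degs(table)
    assert degs.up == {"g1"} and degs.down == {"g3"}


def test_call_degs_recall_on_strong_synthetic_effects():
    """True effects of |log2fch| = 2 at sigma 0.2, n = 5/arm: recall >= 0.9."""
    study, de = two_arm_study(np.random.default_rng(21), g=500)
    table = tc.fit_differential(study, "disease", "naive")
    degs = tc.call_degs(table)
    truth = set(np.array(study.gene_ids)[de])
    recall = len(degs.all_genes & truth) / len(truth)
    precision = len(degs.all_genes & truth) / max(len(degs.all_genes), 1)
    assert recall >= 0.9 and precision >= 0.9


def test_signed_fold_change_convention():
    np.testing.assert_allclose(
        tc.signed_fold_change(np.array([1.0, -1.0, 0.0, 2.5])),
        [2.0, -2.0, 1.0, 2 ** 2.5],
    )


def test_collapse_to_genes_keeps_max_abs_t_and_breaks_ties_lexicographically():
    table = _table(
        [
            {"gene_id": "p1", "t_mod": 3.1},
            {"gene_id": "p2", "t_mod": -2.2},
            {"gene_id": "p3", "t_mod": 1.5},
            {"gene_id": "p4", "t_mod": -1.5},
            {"gene_id": "p5", "t_mod": 9.0},
        ]
    )
    out = tc.collapse_to_genes(
        table, {"p1": "X", "p2": "X", "p3": "Y", "p4": "Y"}
    )  # p5 unmapped
    assert out.loc["X", "probe_id"] == "p1"
    assert out.loc["Y", "probe_id"] == "p3"  # |t| tie -> smaller probe id
    assert len(out) == 2


# ---------------------------------------------------------------------------
# FDR control under the global null


def test_fdr_control_under_global_null_quick():
    fracs = []
    for seed in range(5):
        study, _ = two_arm_study(np.random.default_rng(100 + seed), g=2000, frac_de=0.0)
        table = tc.fit_differential(study, "disease", "naive")
        fracs.append((table["q"] < 0.05).mean())
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert np.mean(fracs) <= 0.05 + 3 * max(se, 1e-4)


# ---------------------------------------------------------------------------
# independent oracle: limma


def test_moderated_t_matches_limma(tmp_path):
    """The full eBayes path (prior fit + moderated t + p) cross-checked
    against limma on a 300-gene fixture."""
    assert shutil.which("Rscript"), "Rscript expected on PATH"
    # heteroscedastic genes (variances from the inverse-chi-square prior) so
    # the finite-d0 shrinkage branch is the one exercised
    rng = np.random.default_rng(42)
    g, n = 300, 5
    sigma2 = 4 * 0.04 / rng.chisquare(4, g)
    mu = rng.normal(6, 1.5, g)
    beta = np.where(rng.random(g) < 0.2, rng.normal(0, 1.5, g), 0.0)
    x = np.hstack(
        [mu[:, None] + beta[:, None] + rng.normal(0, np.sqrt(sigma2)[:, None], (g, n)),
         mu[:, None] + rng.normal(0, np.sqrt(sigma2)[:, None], (g, n))]
    )
    ids = [f"g{i:04d}" for i in range(g)]
    cols = [f"A_{i}" for i in range(n)] + [f"B_{i}" for i in range(n)]
    study = tc.ExpressionStudy(
        pd.DataFrame(x, index=ids, columns=cols),
        {c: c.split("_")[0] for c in cols},
    )
    mat = tmp_path / "x.csv"
    study.values.to_csv(mat)
    table = tc.fit_differential(study, "A", "B")
    prior = table.attrs["prior"]
    out = tmp_path / "limma.csv"
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.csv("{mat}", row.names=1))
    design <- cbind(Intercept=1, A=c(rep(1,5), rep(0,5)))
    fit <- eBayes(lmFit(x, design))
    write.csv(data.frame(t=fit$t[,"A"], p=fit$p.value[,"A"],
                         d0=fit$df.prior, s0sq=fit$s2.prior), "{out}")
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = pd.read_csv(out, index_col=0)
    assert math.isfinite(prior.d0)
    assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
    assert prior.s0_sq == pytest.approx(ref["s0sq"].iloc[0], rel=1e-5)
    np.testing.assert_allclose(table["t_mod"], ref["t"], rtol=1e-8)
    np.testing.assert_allclose(table["p"], ref["p"], rtol=1e-8, atol=1e-12)
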