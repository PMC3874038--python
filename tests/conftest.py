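import numpy as np
import pandas as pd
import pytest

import transconcord as tc


@pytest.fixture
def tiny_study() -> tc.ExpressionStudy:
    """3 genes x 4 samples, two arms of two."""
    values = pd.DataFrame(
        [[5.0, 5.2, 3.0, 3.1], [2.0, 2.1, 2.2, 2.0], [7.5, 7.4, 7.6, 7.8]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = {"s1": "disease", "s2": "disease", "s3": "naive", "s4": "naive"}
    return tc.ExpressionStudy(values, groups, species="mouse")


def two_arm_study(rng: np.random.Generator, g: int = 200, n: int = 5,
                  frac_de: float = 0.2, effect: float = 2.0, sd: float = 0.2,
                  arm_a: str = "disease", arm_b: str = "naive") -> tuple:
    """Small two-arm study with known truth; returns (study, de_mask)."""
    mu = rng.normal(6, 1.0, g)
    de = rng.random(g) < frac_de
    beta = np.where(de, effect * np.where(rng.random(g) < 0.5, 1, -1), 0.0)
    ids = [f"g{i:04d}" for i in range(g)]
    cols, groups, names = [], {}, []
    for arm, shift in ((arm_a, beta), (arm_b, 0.0)):
        for i in range(n):
            sid = f"{arm}_{i}"
            names.append(sid)
            groups[sid] = arm
            cols.append(mu + shift + rng.normal(0, sd, g))
    study = tc.ExpressionStudy(
        pd.DataFrame(np.column_stack(cols), index=ids, columns=names), groups
    )
    return study, de


@pytest.fixture
def small_bundle():
    """A small but complete synthetic two-species bundle."""
    cfg = tc.SimulationConfig(n_genes=600)
    return cfg, tc.generate_all(cfg, seed=11)
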