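import numpy as np
import pandas as pd
import pytest

from phenoadapt import Covariate, SyntheticConfig, TrialDataset, generate_trial


def make_dataset(
    n=20,
    seed=0,
    schema=(Covariate("age", "continuous"), Covariate("smoker", "binary")),
    n_safety_tiers=0,
):
    """Small hand-rollable dataset with reproducible covariates/outcomes."""
    rng = np.random.default_rng(seed)
    t = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "arm": np.where(rng.random(n) < 0.5, "intervention", "control"),
            "accrual_time": rng.uniform(0, 100, n),
            "primary_time": rng.exponential(300, n) + 1e-3,
            "primary_event": (rng.random(n) < 0.5).astype(int),
        }
    )
    # ensure both arms present
    t.loc[0, "arm"] = "intervention"
    t.loc[1, "arm"] = "control"
    for k in range(n_safety_tiers):
        t[f"safety_{k}_time"] = rng.exponential(400, n) + 1e-3
        t[f"safety_{k}_event"] = (rng.random(n) < 0.4).astype(int)
    for c in schema:
        if c.kind == "continuous":
            t[c.name] = rng.normal(50, 10, n)
        elif c.kind == "binary":
            t[c.name] = (rng.random(n) < 0.4).astype(float)
        else:
            t[c.name] = rng.choice(list(c.levels), n)
    return TrialDataset(t, schema, n_safety_tiers)


@pytest.fixture
def toy_dataset():
    return make_dataset(n=20, seed=0)


@pytest.fixture(scope="session")
def hte_trial():
    """Mid-size trial with a planted binary interaction, shared across tests."""
    cfg = SyntheticConfig(
        n_total=1200,
        n_continuous=4,
        n_binary=3,
        n_categorical=1,
        hte_features=("b0",),
        hte_coeffs=(-0.8,),
        binary_prevalence=(0.4, 0.3, 0.35),
        seed=7,
    )
    return cfg, generate_trial(cfg)
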