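import numpy as np
import pandas as pd
import pytest

import layerprot as lp


@pytest.fixture(scope="session")
def default_design():
    return lp.generate_design()


@pytest.fixture(scope="session")
def small_design():
    """6 cases + 4 controls, one 16-sample set per layer."""
    return lp.generate_design(6, 4, 1, 16)


@pytest.fixture(scope="session")
def null_dataset(default_design):
    """All-null two-platform simulation at default noise (SM layer)."""
    truth = lp.generate_truth(300, fractions={}, seed=11, frac_single_set=0.0)
    noise = lp.NoiseConfig(seed=13)
    tmt = lp.simulate_tmt(default_design, truth, noise)
    lf = lp.simulate_labelfree(default_design, truth, noise)
    return default_design, truth, noise, tmt, lf


def paired_values(design, effect=0.0, sigma_b=0.5, sigma_e=0.2, rng=None):
    """Log2 values for the paired STR/NSTR samples of one layer."""
    rng = rng or np.random.default_rng(0)
    samp = design.samples(layer="SM")
    samp = samp[samp["group"].isin(["STR", "NSTR"])]
    b = {ind: rng.normal(0, sigma_b) for ind in samp["individual_id"].unique()}
    vals = {}
    for _, r in samp.iterrows():
        shift = effect if r["group"] == "STR" else 0.0
        vals[r["sample_id"]] = 10.0 + shift + b[r["individual_id"]] + rng.normal(0, sigma_e)
    return pd.Series(vals)
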