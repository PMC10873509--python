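import numpy as np
import pytest

import mpramix as mx


@pytest.fixture(scope="session")
def small_design():
    """300 candidates + 40 positives + 60 shuffled negatives."""
    return mx.make_synthetic_library(300, 40, 60, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_design):
    """A full simulated experiment (counts → QC → activity → fit → calls)."""
    return mx.run_experiment(small_design, seed=21)


@pytest.fixture(scope="session")
def mixture_sample():
    """n=5000 draws from 0.5·N(0, 0.35) + 0.5·N(0.65, 0.35), fixed seed."""
    rng = np.random.default_rng(7)
    n = 5000
    comp = rng.random(n) < 0.5
    vals = np.where(comp, rng.normal(0.65, 0.35, n), rng.normal(0.0, 0.35, n))
    truth = {"w_bg": 0.5, "mu_bg": 0.0, "sd_bg": 0.35,
             "w_sig": 0.5, "mu_sig": 0.65, "sd_sig": 0.35}
    return vals, truth
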