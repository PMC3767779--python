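import numpy as np
import pytest

from trpquant import synthetic as syn


@pytest.fixture
def design_9x9():
    """One enzyme, 3 biological x 3 technical replicates: 9 runs/condition."""
    return syn.make_run_design()


@pytest.fixture
def clean_cfg():
    """Noise-free, dropout-free generator config with one +2 variant per site."""
    return syn.SimConfig(
        n_background_features=20,
        background_change_fraction=0.0,
        noise_cv=0.0,
        detect_prob=1.0,
        seed=0,
        n_variants_per_site=1,
        multi_phospho_prob=0.0,
        ambiguous_prob=0.0,
        charge_weights={2: 1.0},
    )


@pytest.fixture
def one_site_truth():
    return [syn.TrueSiteState("T849", {"light": 1.0, "dark": 0.25})]


def lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))
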