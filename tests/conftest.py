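import numpy as np
import pytest

import admixgwas as ag


@pytest.fixture(scope="session")
def default_panel():
    """The default desk-scale frequency panel (5000 variants, 10 chromosomes)."""
    return ag.simulate_panel(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_panel):
    """Featureless default cohort: n=500, Beta(mean 0.8, sd 0.1) admixture."""
    return ag.simulate_cohort(default_panel, ag.SimConfig(n=500, seed=11))


@pytest.fixture(scope="session")
def feature_cohort(default_panel):
    """Cohort with the packaged cross-chromosome LD feature injected."""
    return ag.simulate_cohort(
        default_panel,
        ag.SimConfig(n=1000, seed=11, features=(ag.sim.demo_multiregion_feature(),)),
    )


@pytest.fixture()
def small_panel():
    """A tiny two-chromosome panel for unit tests."""
    return ag.AncestralFrequencyPanel(
        chrom=np.array(["1"] * 10 + ["2"] * 10),
        pos_bp=np.concatenate([np.arange(1, 11) * 100_000] * 2),
        p0=np.linspace(0.1, 0.8, 20),
        p1=np.linspace(0.85, 0.15, 20),
    )
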