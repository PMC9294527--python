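import pytest

from musselid.synthetic import SimConfig, simulate_dataset, simulate_paperlike

#: canonical seed for study-shaped fixtures (fixed once for the whole suite)
SEED = 2020


@pytest.fixture(scope="session")
def paperlike():
    """Study-shaped dataset: 7 + 42 pure individuals, 12 F1 hybrids, HRM-like labels."""
    return simulate_paperlike(seed=SEED)


@pytest.fixture(scope="session")
def clean_sim():
    """Two well-separated species, small reference panels, no hybrids.

    Small panels (8 per species) keep the 95th-percentile distance threshold
    adaptive to the most divergent reference, the regime in which the
    threshold-based classifiers are designed to be error-free.
    """
    cfg = SimConfig(
        n_A=8, n_B=8, n_hybrids=0,
        intraspecific_theta=0.002, interspecific_divergence=0.02,
        seed=SEED,
    )
    return simulate_dataset(cfg)
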