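import pytest

from seqstop.simulate import SequentialConfig, first_crossing_distribution

# The canonical null-hypothesis batch: 10,000 sequential strategies from
# n=2 to n=150 per group at alpha=0.05, both groups standard normal.
H0_CONFIG = SequentialConfig(
    n_start=2, n_max=150, alpha=0.05, delta=0.0, sigma=1.0, reps=10_000, seed=20_260_925
)


@pytest.fixture(scope="session")
def h0_result():
    """Shared 10k-replicate null simulation (expensive; run once)."""
    return first_crossing_distribution(H0_CONFIG)
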