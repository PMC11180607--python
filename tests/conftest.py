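import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from celltagmulti.allowlist import Allowlist
from celltagmulti.sim import SyntheticExperimentSpec, simulate_experiment


@pytest.fixture(scope="session")
def toy_allowlist() -> Allowlist:
    """Ten 8-mers, pairwise Hamming distance >= 3 except one close pair."""
    barcodes = [
        "AAAAAAAA",
        "CCCCCCCC",
        "GGGGGGGG",
        "TTTTTTTT",
        "AACCGGTT",
        "TTGGCCAA",
        "ACGTACGT",
        "TGCATGCA",
        "AAAATTTT",
        "CCCCGGGG",
    ]
    return Allowlist(barcodes=barcodes, abundance=np.arange(1.0, 11.0))


@pytest.fixture(scope="session")
def small_experiment():
    """A 40-clone noiseless experiment reused across pipeline tests."""
    spec = SyntheticExperimentSpec(
        n_clones=40,
        clone_size_mean=4.0,
        library_size=2000,
        moi=8.0,
        tag_range=(5, 15),
        dropout_rate=0.0,
        error_rate=0.0,
        n_features=12,
        seed=11,
    )
    return simulate_experiment(spec)
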