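import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tlscan.synthetic_data import design_library, make_reference

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    """Default 31-codon trigger-loop reference (residues 1076-1106)."""
    return make_reference()


@pytest.fixture(scope="session")
def evs(ref):
    """Default programmed library with the five spike-ins."""
    return design_library(ref)


@pytest.fixture(scope="session")
def small_ref():
    """Five-codon toy reference for exhaustive alignment checks."""
    return make_reference(
        coding_sequence="ATGGCTAAAGGTTAC",
        upstream_flank="ACGTACGTACGTACGT",
        downstream_flank="TGCATGCATGCATGCA",
        first_residue_number=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
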