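import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mepflux.synthetic_data import REFERENCE_STUDY

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_rows():
    """The 12 genotype x condition parameter rows (m, A, B, C, J)."""
    return REFERENCE_STUDY.to_dict("records")


@pytest.fixture(scope="session")
def ev_high():
    """Empty-vector control at 1000 PPFD / 30 degC."""
    ref = REFERENCE_STUDY
    return ref[(ref.genotype == "EV") & (ref.ppfd == 1000) & (ref.temp_c == 30)].iloc[0]


@pytest.fixture
def grid():
    """Default labeling grid: 0-50 min at 0.5-min steps."""
    return np.arange(0.0, 50.0 + 1e-9, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240410)
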