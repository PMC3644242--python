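import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def result():
    """Full pipeline run on the default cohort (seed 1), shared session-wide."""
    from ap2erf.pipeline import analyze_cohort

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_cohort(seed=1)


@pytest.fixture(scope="session")
def truth_by_id(result):
    return {t.gene_id: t for t in result.truths}


@pytest.fixture(scope="session")
def panel():
    from ap2erf.synthetic_data import build_reference_panel

    return build_reference_panel(seed=0)


@pytest.fixture(scope="session")
def ap2_model():
    from ap2erf.domain_scan import default_ap2_model

    return default_ap2_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
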