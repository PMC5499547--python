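import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cotshape.folding import fluoride_riboswitch_pathway
from cotshape.sequences import SYNTHETIC_TARGET
from cotshape.templates import TemplateSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20170408)


@pytest.fixture(scope="session")
def native():
    return SYNTHETIC_TARGET


@pytest.fixture(scope="session")
def pathway():
    return fluoride_riboswitch_pathway()


@pytest.fixture()
def template_spec(native):
    return TemplateSpec(
        nontemplate_sequence=native, txn_start=1, target_length=len(native)
    )
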