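import hypothesis
import pytest

from sui_cua.costs import PriceConfig, default_policies
from sui_cua.questionnaires import LUTSQOL_ITEM_NAMES, QuestionnaireResponse

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def prices():
    return PriceConfig()


@pytest.fixture
def policies():
    return default_policies()


def make_response(levels, participant_id="p1", timepoint="baseline", uisf=None):
    """Response from a 19-element level sequence."""
    return QuestionnaireResponse(
        participant_id=participant_id,
        timepoint=timepoint,
        lutsqol_items=dict(zip(LUTSQOL_ITEM_NAMES, levels)),
        uisf_items=uisf,
    )
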