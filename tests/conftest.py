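import pytest

from distilseq import CommunityProfile, Parameters

# the ensemble-analysis defaults: M_u=5, M_l=0.3, tau=0.2, safety 2
DEFAULTS = Parameters()

# the four published 40-cell study communities (counts scaled by 5)
TABLE_PROFILES = {
    "3_2_3": CommunityProfile((15, 10, 15), (4e6, 12e6, 2e6)),
    "1_1_1_5": CommunityProfile((5, 5, 5, 25), (4e6, 12e6, 2e6, 1e6)),
    "1_1_2_4": CommunityProfile((5, 5, 10, 20), (4e6, 12e6, 2e6, 1e6)),
    "1_2_3_2": CommunityProfile((5, 10, 15, 10), (4e6, 12e6, 2e6, 1e6)),
}


@pytest.fixture
def params():
    return DEFAULTS


@pytest.fixture
def profile_323():
    return TABLE_PROFILES["3_2_3"]
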