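import numpy as np
import pytest

from oxakin import reference as ref
from oxakin.profiles import ReactionProfile


@pytest.fixture
def full_profile():
    """Factory: the tabulated two-step profile under a chosen protocol."""

    def make(protocol: str = "G_TPSS") -> ReactionProfile:
        return ReactionProfile.from_values(
            ref.PROFILE_LABELS, ref.PROFILE_ROLES,
            ref.COMPOSITE_PROFILES[protocol],
        )

    return make


@pytest.fixture
def step_profiles():
    """Factory: (step-1, step-2) local profiles for one protocol.

    Step 1 is referenced to MC_S1 (as tabulated); step 2 is re-referenced so
    the water-bound global-minimum complex MC_S2gm sits at zero, ready for
    stitching through the water-binding free energy.
    """

    def make(protocol: str = "G_TPSS"):
        col = ref.COMPOSITE_PROFILES[protocol]
        p1 = ReactionProfile.from_values(
            ref.PROFILE_LABELS[:5], ref.PROFILE_ROLES[:5], col[:5]
        )
        vals2 = np.asarray(col[5:]) - col[5]
        p2 = ReactionProfile.from_values(
            ref.PROFILE_LABELS[5:], ref.PROFILE_ROLES[5:], vals2
        )
        return p1, p2

    return make
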