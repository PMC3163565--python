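import numpy as np
import pytest
from hypothesis import settings

from txem import (
    LengthDistribution,
    ModelParams,
    ProfileErrorModel,
    Rspd,
    Transcript,
    TranscriptSet,
)

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def tiny_ts():
    """Two short transcripts in one gene plus a singleton gene."""
    return TranscriptSet(
        [
            Transcript("t1", "g1", "ACGTACGTACGTACGTACGT"),
            Transcript("t2", "g1", "ACGTACGTTTTTACGTACGT"),
            Transcript("t3", "g2", "GGGGCCCCGGGGCCCCGGGG"),
        ]
    )


@pytest.fixture
def flat_profile_params():
    """Parameters with a flat profile error model and simple distributions,
    convenient for hand-computable weights."""

    def make(ts, read_len=4, frag=None, error_rate=0.0, strand_specific=False):
        err = ProfileErrorModel.flat(read_len, error_rate) if error_rate else _exact_profile(read_len)
        return ModelParams(
            theta=np.full(len(ts) + 1, 1.0 / (len(ts) + 1)),
            lambda_f=frag or LengthDistribution.point(read_len),
            lambda_r=LengthDistribution.point(read_len),
            rspd=Rspd.uniform(),
            error=err,
            strand_specific=strand_specific,
        )

    return make


def _exact_profile(read_len):
    t = np.zeros((read_len, 4, 4))
    for c in range(4):
        t[:, c, c] = 1.0
    return ProfileErrorModel(t)


@pytest.fixture
def exact_profile():
    return _exact_profile
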