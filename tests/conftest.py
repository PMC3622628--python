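import numpy as np
import pytest

from demixem.alignment import ReadAlignmentGroup
from demixem.model import (
    AbundanceProfile,
    EffectiveLengths,
    FragmentModel,
    TranscriptCatalog,
)


def make_group(read_id, candidates, sample_tag="pure"):
    """candidates: list of (transcript_index, start, reverse)."""
    t, p, r = zip(*candidates)
    return ReadAlignmentGroup(
        read_id=read_id,
        transcripts=np.array(t, dtype=np.int64),
        starts=np.array(p, dtype=np.int64),
        reverse=np.array(r, dtype=bool),
        sample_tag=sample_tag,
    )


@pytest.fixture
def two_transcript_catalog():
    return TranscriptCatalog(
        ids=("t1", "t2"),
        lengths=np.array([100, 300]),
        sequences=("ACGT" * 25, "ACGT" * 75),
    )


@pytest.fixture
def unit_lengths():
    return EffectiveLengths(np.array([1.0, 1.0]))


@pytest.fixture
def frag_default():
    return FragmentModel(mu=200.0, sigma=80.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_profile(rng, n):
    return AbundanceProfile(rng.dirichlet(np.ones(n)))
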