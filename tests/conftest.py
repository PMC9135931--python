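import numpy as np
import pytest

from brainfa.fa_model import (
    PANEL_NAMES,
    CompositionProfile,
    SubjectMeta,
)
from brainfa.synthetic import reference_profile


@pytest.fixture(scope="session")
def olive_middle():
    """Reference mean composition of the olive, middle-aged group."""
    return reference_profile("olive", "middle_aged")


@pytest.fixture
def make_profile():
    """Factory for profiles over the study panel from a name->mol% mapping."""

    def _make(values, subject_id="s1", region="olive", age=50.0):
        meta = SubjectMeta(subject_id=subject_id, region=region, age=age)
        return CompositionProfile(meta, dict(values))

    return _make


@pytest.fixture
def random_closed_profile(make_profile):
    """Factory for seeded random compositions closed to 100 mol%."""

    def _make(seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.01, 1.0, size=len(PANEL_NAMES))
        x *= 100.0 / x.sum()
        return make_profile(dict(zip(PANEL_NAMES, x)))

    return _make
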