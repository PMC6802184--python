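"""Shared end-to-end validation studies.

Session-scoped so each synthetic session and its embedding/clustering are
computed once and reused across the validation tests.  Sizes are the study
conditions the generators emulate (see innerstate.studies).
"""

import pytest

from innerstate.studies import HDStudy, TrackStudy


@pytest.fixture(scope="session")
def ca1_study():
    return TrackStudy("ca1", seed=1)


@pytest.fixture(scope="session")
def ca1_study_b():
    """Independent session: same track statistics, disjoint neuron identities."""
    return TrackStudy("ca1", seed=42)


@pytest.fixture(scope="session")
def acc_study():
    return TrackStudy("acc", seed=1)


@pytest.fixture(scope="session")
def hd_rem_study():
    return HDStudy(seed=2, rem_fraction=0.25)
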