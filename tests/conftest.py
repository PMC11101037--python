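import numpy as np
import pytest

from crmkit import io
from crmkit.simulate import FACE_TEMPLATE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(coords, subject_id="s0", fps=20.0):
    coords = np.asarray(coords, dtype=float)
    return io.SubjectRecording(
        subject_id, coords, np.arange(coords.shape[0]), fps=fps
    )


@pytest.fixture
def template_face():
    """Canonical symmetric, level 66-point face."""
    return FACE_TEMPLATE.copy()


@pytest.fixture
def static_recording(template_face):
    """Three identical frames of the template face."""
    return make_recording(np.repeat(template_face[None], 3, axis=0))


@pytest.fixture
def static_cohort(template_face):
    recs = [
        make_recording(np.repeat(template_face[None], 4, axis=0), f"s{i}")
        for i in range(3)
    ]
    return io.CohortDataset(recs)
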