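import numpy as np
import pytest

from gradstab.types import MotionTrace, SessionSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_session(rng):
    """20-ROI, 120-volume random band-ish session (TR 2 s)."""
    t = np.arange(120)[:, None] * 2.0
    freqs = rng.uniform(0.03, 0.08, size=20)[None, :]
    phases = rng.uniform(0, 2 * np.pi, size=20)[None, :]
    data = np.cos(2 * np.pi * freqs * t + phases) + 0.3 * rng.standard_normal((120, 20))
    return SessionSeries(
        data=data,
        tr_s=2.0,
        subject_id="sub-001",
        session_label="pre",
        roi_labels=[f"ROI_{k}" for k in range(1, 21)],
    )


@pytest.fixture
def still_motion():
    return MotionTrace(params=np.zeros((50, 6)))
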