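import numpy as np
import pytest

from ergocardia import BeatSeries, generate_rri_series


@pytest.fixture
def tiny_beats() -> BeatSeries:
    """Hand-built 6-beat tachogram with one ventricular ectopic."""
    rr = np.array([800.0, 790.0, 400.0, 810.0, 820.0, 805.0])
    labels = np.array(["N", "N", "V", "N", "N", "N"])
    return BeatSeries(
        time_s=np.cumsum(rr) / 1000.0, rr_ms=rr, label=labels, subject_id="tiny"
    )


@pytest.fixture(scope="session")
def cascade_rri() -> BeatSeries:
    """One cascade-modulated RR series at demo scale (shared, read-only)."""
    return generate_rri_series(cascade_p=0.75, hurst=0.75, length=2**13, seed=7)
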