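import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from gpecg import SynthSpec, generate_clean, segment_beats
from gpecg.synthetic import DEFAULT_WAVES, LEAD_I_WAVES, generate_clean_multilead


@pytest.fixture(scope="session")
def clean_record():
    """Default 30 s synthetic record with analytic ground truth."""
    spec = SynthSpec(duration=30.0, seed=101)
    return generate_clean(spec)


@pytest.fixture(scope="session")
def clean_seg(clean_record):
    rec, truth = clean_record
    return segment_beats(truth.r_peaks, rec.n_samples)


@pytest.fixture(scope="session")
def two_lead_record():
    """60 s two-lead record sharing one rhythm, two morphologies."""
    spec = SynthSpec(duration=60.0, seed=202)
    return generate_clean_multilead(spec, {"II": DEFAULT_WAVES, "I": LEAD_I_WAVES})


@pytest.fixture()
def periodic_signal():
    """Strictly periodic signal with identical beats and exact segmentation."""
    period, n_beats = 100, 8
    t = np.arange(period)
    beat = np.exp(-0.5 * ((t - 50) / 4.0) ** 2) + 0.3 * np.exp(
        -0.5 * ((t - 75) / 8.0) ** 2
    )
    x = np.tile(beat, n_beats)
    r_peaks = 50 + period * np.arange(n_beats)
    seg = segment_beats(r_peaks, x.size)
    return x, seg
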