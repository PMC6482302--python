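import numpy as np
import pytest

from pcg_emotion.preprocess import PcgRecording, lowpass, shannon_envelope
from pcg_emotion.synth import (DEFAULT_PROFILES, render_pcg,
                               sample_interval_series)

RATE = 2000.0


@pytest.fixture(scope="session")
def relaxed_profile():
    return DEFAULT_PROFILES["relaxed"].with_beats(61)


@pytest.fixture(scope="session")
def clean_pcg(relaxed_profile):
    """Noise-free 60-cycle rendering with its ground truth."""
    rr, ds = sample_interval_series(relaxed_profile, seed=11)
    wave, truth = render_pcg(rr, ds, rate=RATE, snr_db=np.inf, seed=11)
    return wave, truth


@pytest.fixture(scope="session")
def noisy_pcg(relaxed_profile):
    """SNR 20 dB 60-cycle rendering with its ground truth."""
    rr, ds = sample_interval_series(relaxed_profile, seed=11)
    wave, truth = render_pcg(rr, ds, rate=RATE, snr_db=20.0, seed=11)
    return wave, truth


def prepare(wave, rate=RATE):
    """Raw waveform -> (filtered recording, envelope) as the pipeline does."""
    rec = PcgRecording(samples=wave, rate=rate)
    filt = lowpass(rec)
    return filt, shannon_envelope(filt)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A tiny on-disk corpus: 4 relaxed + 4 happy short segments."""
    from pcg_emotion.synth import make_dataset
    out = tmp_path_factory.mktemp("corpus")
    profiles = [DEFAULT_PROFILES["relaxed"], DEFAULT_PROFILES["happy"]]
    manifest = make_dataset(profiles, [4, 4], out, segment_seconds=40.0, seed=5)
    return out, manifest
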