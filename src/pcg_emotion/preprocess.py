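"""Signal conditioning: low-pass filtering, Shannon-energy envelope, and the
quality preselection gate applied before segmentation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from .errors import SignalError

DEFAULT_CUTOFF_HZ = 200.0
DEFAULT_ORDER = 4
DEFAULT_ENVELOPE_WINDOW_S = 0.02

#: preselect thresholds (config-overridable)
PRESELECT_DEFAULTS = {
    "min_periodicity": 0.2,       # envelope autocorr peak in [0.3, 1.5] s lags
    "period_lo_s": 0.3,
    "period_hi_s": 1.5,
    "max_noise_fraction": 0.25,   # spectral power above noise_band_hz / total
    "noise_band_hz": 400.0,
    "max_clip_fraction": 1e-3,    # samples at >= 99.9% full scale
}


@dataclass
class PcgRecording:
    """A mono PCG (or ECG) trace with its sampling rate."""

    samples: np.ndarray
    rate: float
    channel: str = "pcg"
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise SignalError("samples must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.samples)):
            raise SignalError("samples must be finite")
        if not self.rate > 0:
            raise SignalError("rate must be positive")
        if self.channel not in ("pcg", "ecg"):
            raise SignalError(f"unknown channel {self.channel!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Envelope:
    """Non-negative amplitude envelope aligned with its source recording."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise SignalError("envelope values must be non-negative")
        self.values = np.maximum(self.values, 0.0)


def read_wav(path: str | Path, channel: str = "pcg") -> PcgRecording:
    """Read a mono WAV file into a float recording scaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return PcgRecording(samples=samples, rate=float(rate), channel=channel,
                        id=Path(path).stem)


def lowpass(rec: PcgRecording, cutoff: float = DEFAULT_CUTOFF_HZ,
            order: int = DEFAULT_ORDER) -> PcgRecording:
    """Zero-phase Butterworth low-pass; output length equals input length."""
    nyquist = rec.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise SignalError(f"cutoff {cutoff} Hz must lie in (0, {nyquist}) Hz")
    if order < 1:
        raise SignalError("order must be >= 1")
    sos = signal.butter(order, cutoff, btype="low", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def shannon_envelope(rec: PcgRecording,
                     window: float = DEFAULT_ENVELOPE_WINDOW_S) -> Envelope:
    """Normalized Shannon energy envelope, smoothed by a moving average.

    The samples are scaled to unit peak so the envelope is invariant under
    amplitude rescaling; an all-zero input yields an all-zero envelope.
    """
    if window <= 0:
        raise SignalError("window must be positive")
    x = rec.samples
    peak = float(np.max(np.abs(x)))
    if peak == 0.0:
        return Envelope(values=np.zeros_like(x), rate=rec.rate)
    # scale to half peak: keeps x^2 below 1/e, where -x^2 log x^2 is still
    # monotone, so the loudest samples do not collapse to zero energy
    x = 0.5 * x / peak
    x2 = x * x
    energy = np.zeros_like(x2)
    nz = x2 > 0
    energy[nz] = -x2[nz] * np.log(x2[nz])
    n_win = max(1, int(round(window * rec.rate)))
    smoothed = uniform_filter1d(energy, size=n_win, mode="constant")
    return Envelope(values=smoothed, rate=rec.rate)


@dataclass
class PreselectReport:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)


def preselect(rec: PcgRecording, env: Envelope,
              config: dict | None = None) -> PreselectReport:
    """Quality gate: reject aperiodic, broadband-noisy or clipped recordings.

    Checks (all thresholds from ``config``, defaulting to
    :data:`PRESELECT_DEFAULTS`):

    - the envelope autocorrelation must show a dominant periodicity at a lag
      in the physiologic beat range [0.3, 1.5] s;
    - the fraction of raw spectral power above 400 Hz must stay small;
    - clipping (samples pinned at full scale) must be negligible.
    """
    cfg = dict(PRESELECT_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise SignalError(f"unknown preselect keys: {sorted(unknown)}")
        cfg.update(config)

    reasons: list[str] = []
    metrics: dict = {}

    # (a) dominant periodicity of the envelope autocorrelation
    v = env.values - np.mean(env.values)
    denom = float(np.dot(v, v))
    lag_lo = int(round(cfg["period_lo_s"] * env.rate))
    lag_hi = min(int(round(cfg["period_hi_s"] * env.rate)), len(v) - 1)
    if denom <= 0 or lag_hi <= lag_lo:
        peak_corr = 0.0
    else:
        ac = signal.correlate(v, v, mode="full")[len(v) - 1:]
        ac = ac / denom
        peak_corr = float(np.max(ac[lag_lo:lag_hi + 1]))
    metrics["periodicity"] = peak_corr
    if peak_corr < cfg["min_periodicity"]:
        reasons.append("aperiodic: no dominant beat-range periodicity in envelope")

    # (b) broadband noise fraction (power above the noise band cutoff)
    nyquist = rec.rate / 2.0
    if nyquist > cfg["noise_band_hz"]:
        nper = min(len(rec.samples), 4096)
        freqs, psd = signal.welch(rec.samples, fs=rec.rate, nperseg=nper)
        total = float(np.trapezoid(psd, freqs))
        high = float(np.trapezoid(psd[freqs >= cfg["noise_band_hz"]],
                                  freqs[freqs >= cfg["noise_band_hz"]]))
        frac = high / total if total > 0 else 0.0
    else:
        frac = 0.0
    metrics["noise_fraction"] = frac
    if frac > cfg["max_noise_fraction"]:
        reasons.append("broadband noise: excessive power above "
                       f"{cfg['noise_band_hz']:.0f} Hz")

    # (c) clipping against nominal full scale
    full_scale = max(1.0, float(np.max(np.abs(rec.samples))))
    clip_frac = float(np.mean(np.abs(rec.samples) >= 0.999 * full_scale))
    metrics["clip_fraction"] = clip_frac
    if clip_frac > cfg["max_clip_fraction"]:
        reasons.append("clipping: samples pinned at full scale")

    return PreselectReport(passed=not reasons, reasons=reasons, metrics=metrics)
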