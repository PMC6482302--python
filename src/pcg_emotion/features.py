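"""Feature extraction from interval series.

Each series yields a fixed, named feature block:

- RR-kind block (79 features): 7 time-domain + 6 frequency-domain +
  sd1/sd2/sd12 for lags M = 1..22;
- DS-kind block (75 features): 6 time-domain (no pnn50) + 3
  frequency-domain + the same 66 lagged-Poincare features.

Concatenating the two heart-sound blocks with block prefixes gives the
154-feature combined block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import median_abs_deviation

from .errors import SignalError
from .indicators import IntervalSeries

DEFAULT_M_MAX = 22
MIN_SERIES_LEN = 32  # frequency features need a minimally resolvable spectrum

#: spectral bands, Hz for RR series (beat-time axis), cycles/beat for DS
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

BLOCKS = ("hs_hrv", "hs_dsv", "ecg_hrv", "hs_hd")
BLOCK_SIZES = {"hs_hrv": 79, "hs_dsv": 75, "ecg_hrv": 79, "hs_hd": 154}


@dataclass
class LppSummary:
    """Lagged-Poincare ellipse axes at lag M.

    sd1 is the dispersion across the identity line (short half-axis), sd2
    along it; sd12 = sd1/sd2, recorded as NaN when sd2 = 0.
    """

    M: int
    sd1: float
    sd2: float
    sd12: float
    area: float

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("sd1 and sd2 must be non-negative")


def lpp(series: IntervalSeries | np.ndarray, M: int) -> LppSummary:
    """Lagged-Poincare summary at lag ``M``.

    sd1 = sqrt( (1/(N-M)) * sum_i (x_i - x_{i+M})^2 / 2 )
    sd2 = sqrt( (1/(N-M)) * sum_i (x_i + x_{i+M} - 2*mean)^2 / 2 )

    with the mean taken over the full series and a plain 1/(N-M)
    normalization (no N-M-1 correction).
    """
    x = series.values if isinstance(series, IntervalSeries) else np.asarray(series, float)
    n = len(x)
    if M < 1:
        raise ValueError("M must be >= 1")
    if M >= n:
        raise ValueError(f"lag M={M} must be smaller than series length {n}")
    xbar = float(np.mean(x))
    a = x[: n - M]
    b = x[M:]
    sd1 = float(np.sqrt(np.sum((a - b) ** 2 / 2.0) / (n - M)))
    sd2 = float(np.sqrt(np.sum((a + b - 2.0 * xbar) ** 2 / 2.0) / (n - M)))
    sd12 = sd1 / sd2 if sd2 > 0 else float("nan")
    return LppSummary(M=M, sd1=sd1, sd2=sd2, sd12=sd12, area=float(np.pi * sd1 * sd2))


def time_domain(series: IntervalSeries) -> dict[str, float]:
    """Standard interval-series statistics.

    pnn50 (fraction of successive differences exceeding 50 ms) is emitted
    only for RR-kind series, where the values are durations in seconds.
    """
    x = series.values
    if len(x) < 3:
        raise SignalError("need at least 3 values for time-domain features")
    mean = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    out = {
        "mean": mean,
        "sdnn": sdnn,
        "rmssd": rmssd,
        "cv": sdnn / mean if mean != 0 else float("nan"),
        "median": float(np.median(x)),
        "mad": float(median_abs_deviation(x)),
    }
    if series.is_rr:
        out["pnn50"] = float(np.mean(np.abs(diffs) > 0.050))
    return out


def _band_power(t: np.ndarray, y: np.ndarray, band: tuple[float, float],
                n_freqs: int = 128) -> float:
    """Lomb-Scargle power integrated over a frequency band."""
    y = y - np.mean(y)
    if np.allclose(y, 0.0):
        return 0.0
    freqs = np.linspace(band[0], band[1], n_freqs)
    pgram = signal.lombscargle(t, y, 2.0 * np.pi * freqs)
    return float(np.trapezoid(pgram, freqs))


def frequency_domain(series: IntervalSeries) -> dict[str, float]:
    """Band powers from the Lomb-Scargle periodogram of the series.

    RR series use cumulative beat time as the sampling axis and the
    standard VLF/LF/HF bands in Hz; DS series use the cycle index axis
    with LF/HF bands in cycles per beat.
    """
    x = series.values
    if len(x) < MIN_SERIES_LEN:
        raise SignalError(f"need at least {MIN_SERIES_LEN} values for spectral features")
    if series.is_rr:
        t = np.cumsum(x)
        vlf = _band_power(t, x, VLF_BAND)
        lf = _band_power(t, x, LF_BAND)
        hf = _band_power(t, x, HF_BAND)
        out = {"vlf": vlf, "lf": lf, "hf": hf,
               "lf_hf": lf / hf if hf > 0 else float("nan")}
        total = lf + hf
        out["lf_nu"] = lf / total if total > 0 else float("nan")
        out["hf_nu"] = hf / total if total > 0 else float("nan")
        return out
    t = np.arange(len(x), dtype=float)
    lf = _band_power(t, x, LF_BAND)
    hf = _band_power(t, x, HF_BAND)
    return {"lf": lf, "hf": hf, "lf_hf": lf / hf if hf > 0 else float("nan")}


@dataclass
class FeatureVector:
    """Ordered named feature values belonging to one block."""

    names: list[str]
    values: np.ndarray
    block: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must be aligned")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def feature_block(series: IntervalSeries, m_max: int = DEFAULT_M_MAX,
                  block: str | None = None) -> FeatureVector:
    """The full named feature block for one interval series.

    RR-kind series produce 79 features, DS-kind 75 (for the default
    ``m_max`` of 22).  Feature order is deterministic: time-domain,
    frequency-domain, then sd1/sd2/sd12 per lag.
    """
    n = len(series)
    min_len = max(m_max + 1, MIN_SERIES_LEN)
    if n < min_len:
        raise SignalError(
            f"series of length {n} too short for feature block (need >= {min_len})")
    if block is None:
        block = {"hs_rr": "hs_hrv", "hs_ds": "hs_dsv", "ecg_rr": "ecg_hrv"}[series.kind]

    td = time_domain(series)
    td_order = (["mean", "sdnn", "rmssd", "pnn50", "cv", "median", "mad"]
                if series.is_rr else
                ["mean", "sdnn", "rmssd", "cv", "median", "mad"])
    fd = frequency_domain(series)
    fd_order = (["vlf", "lf", "hf", "lf_hf", "lf_nu", "hf_nu"]
                if series.is_rr else ["lf", "hf", "lf_hf"])

    names = list(td_order) + list(fd_order)
    values = [td[k] for k in td_order] + [fd[k] for k in fd_order]
    for m in range(1, m_max + 1):
        s = lpp(series, m)
        names += [f"sd1_m{m:02d}", f"sd2_m{m:02d}", f"sd12_m{m:02d}"]
        values += [s.sd1, s.sd2, s.sd12]
    return FeatureVector(names=names, values=np.asarray(values), block=block)


def combine_blocks(rr_block: FeatureVector, ds_block: FeatureVector) -> FeatureVector:
    """Concatenate the two heart-sound blocks into the combined block.

    Names are prefixed per source block so the combined names stay unique.
    """
    if rr_block.block != "hs_hrv" or ds_block.block != "hs_dsv":
        raise ValueError("combined block requires an hs_hrv and an hs_dsv block")
    names = ([f"hrv.{n}" for n in rr_block.names]
             + [f"dsv.{n}" for n in ds_block.names])
    values = np.concatenate([rr_block.values, ds_block.values])
    return FeatureVector(names=names, values=values, block="hs_hd")


@dataclass
class FeatureMatrix:
    """Segments x features matrix with median-imputed missing values."""

    data: pd.DataFrame
    block: str
    imputed: pd.DataFrame = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def build_matrix(vectors: list[FeatureVector],
                 ids: list[str] | None = None) -> FeatureMatrix:
    """Stack per-segment feature vectors into a matrix.

    All vectors must share block and name order.  NaNs (e.g. sd12 at zero
    sd2) are imputed with the column median; the imputation mask is kept.
    """
    if not vectors:
        raise ValueError("empty corpus")
    block = vectors[0].block
    names = vectors[0].names
    for v in vectors[1:]:
        if v.block != block or v.names != names:
            raise ValueError("inconsistent feature blocks in corpus")
    mat = np.vstack([v.values for v in vectors])
    df = pd.DataFrame(mat, columns=names,
                      index=ids if ids is not None else range(len(vectors)))
    mask = df.isna()
    if mask.to_numpy().any():
        med = df.median(axis=0, skipna=True).fillna(0.0)
        df = df.fillna(med)
    return FeatureMatrix(data=df, block=block, imputed=mask)
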