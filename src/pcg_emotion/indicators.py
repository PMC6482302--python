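"""Interval-series indicators derived from a segmentation.

Two heart-sound indicators are computed from the thb/tha boundary arrays:

- the RR series of successive S1-midpoint differences (heart-sound HRV);
- the per-cycle diastole/systole duration-ratio series (heart-sound DSV),
  where systole runs S1-onset to S2-onset and diastole S2-onset to the
  next S1-onset.

An ECG RR series from R-peak annotations is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientCyclesError, SignalError
from .segment import Segmentation

KINDS = ("hs_rr", "hs_ds", "ecg_rr")


@dataclass
class IntervalSeries:
    """An ordered positive-valued interval (or ratio) series."""

    values: np.ndarray
    kind: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise SignalError(f"unknown series kind {self.kind!r}")
        if self.values.ndim != 1 or len(self.values) == 0:
            raise SignalError("values must be a non-empty 1-d array")
        if np.any(self.values <= 0):
            raise SignalError("interval series values must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_rr(self) -> bool:
        return self.kind in ("hs_rr", "ecg_rr")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(1, len(self) + 1),
                             "value": self.values})

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} source={self.source_id}\n")
            self.to_frame().to_csv(fh, index=False)


def s1_midpoints(seg: Segmentation) -> np.ndarray:
    """Midpoint of each cycle's S1 event: thb(2i-1) + (tha(2i-1) - thb(2i-1))/2."""
    mid = seg.s1_onsets + (seg.s1_offsets - seg.s1_onsets) / 2.0
    if np.any(np.diff(mid) <= 0):
        raise SignalError("S1 midpoints must be strictly increasing")
    return mid


def hs_hrv(seg: Segmentation, source_id: str = "") -> IntervalSeries:
    """Heart-sound RR series: differences of successive S1 midpoints.

    Length N-1 for N cycles.
    """
    if seg.n_cycles < 2:
        raise InsufficientCyclesError("need at least 2 cycles for an RR interval")
    rr = np.diff(s1_midpoints(seg))
    return IntervalSeries(values=rr, kind="hs_rr", source_id=source_id)


def hs_dsv(seg: Segmentation, source_id: str = "") -> IntervalSeries:
    """Heart-sound DS series: per-cycle diastole/systole duration ratio.

    For 1-based cycle i, systole_i = thb(2i) - thb(2i-1) and diastole_i =
    thb(2i+1) - thb(2i), so the series has length N-1: the diastolic
    interval of cycle i runs from the S2 onset to the next cycle's S1 onset.
    """
    if seg.n_cycles < 2:
        raise InsufficientCyclesError("need at least 2 cycles for a DS ratio")
    s1_on = seg.s1_onsets
    s2_on = seg.s2_onsets
    systole = s2_on[:-1] - s1_on[:-1]
    diastole = s1_on[1:] - s2_on[:-1]
    if np.any(systole <= 0):
        raise SignalError("degenerate cycle: zero or negative systolic interval")
    return IntervalSeries(values=diastole / systole, kind="hs_ds",
                          source_id=source_id)


def ecg_rr(rpeaks: np.ndarray, source_id: str = "") -> IntervalSeries:
    """ECG RR series: successive differences of strictly increasing R-peak times."""
    rpeaks = np.asarray(rpeaks, dtype=float)
    if rpeaks.ndim != 1 or len(rpeaks) < 2:
        raise SignalError("need at least 2 R-peak times")
    if np.any(np.diff(rpeaks) <= 0):
        raise SignalError("R-peak times must be strictly increasing")
    return IntervalSeries(values=np.diff(rpeaks), kind="ecg_rr",
                          source_id=source_id)


def median_filter_clean(series: IntervalSeries, kernel: int = 5,
                        max_dev: float = 0.2) -> IntervalSeries:
    """Optional ectopic-interval cleaner (off by default in the pipeline).

    Replaces values deviating from a running median by more than ``max_dev``
    (fractional) with that median.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError("kernel must be odd and >= 3")
    v = series.values.copy()
    half = kernel // 2
    med = np.array([np.median(v[max(0, i - half): i + half + 1])
                    for i in range(len(v))])
    bad = np.abs(v - med) > max_dev * med
    v[bad] = med[bad]
    return IntervalSeries(values=v, kind=series.kind, source_id=series.source_id)
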