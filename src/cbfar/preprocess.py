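"""Beat detection, windowed trends, and the REG integral chain.

The analyses downstream work on two reductions of the raw 200-Hz waveforms:

* beat-level series — per-cycle systolic/diastolic values and pulse
  amplitudes obtained by peak picking;
* windowed trends — block or sliding means (e.g. the 10-s averages feeding
  the reactivity indices), and the REG integral: the rectified first
  derivative of the cranial impedance waveform summed over a trailing 60-s
  window, which suppresses both the baseline and the respiratory
  oscillation while tracking pulsatility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class TrendSeries:
    """A windowed trend: values attached to window-end timestamps."""

    timestamps: np.ndarray
    values: np.ndarray
    window_length: float
    step: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have the same shape")
        if self.timestamps.size >= 2 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.size

    def restrict(self, t0: float, t1: float) -> "TrendSeries":
        """Values with window-end timestamps inside [t0, t1]."""
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return TrendSeries(self.timestamps[m], self.values[m],
                           self.window_length, self.step)


@dataclass
class BeatSeries:
    """Per-beat landmarks: peak times, systolic/diastolic values, amplitude."""

    beat_times: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    foot_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        if self.foot_times is None:
            self.foot_times = np.full_like(self.beat_times, np.nan)
        else:
            self.foot_times = np.asarray(self.foot_times, dtype=float)
        n = self.beat_times.size
        for arr in (self.systolic, self.diastolic, self.foot_times):
            if arr.size != n:
                raise ValueError("beat arrays must share one length")
        if n >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def amplitude(self) -> np.ndarray:
        return self.systolic - self.diastolic

    def __len__(self) -> int:
        return self.beat_times.size


def _condition(waveform: np.ndarray, rate: float, cutoff_hz: float = 15.0) -> np.ndarray:
    """Zero-phase low-pass used only to stabilise peak picking."""
    nyq = rate / 2.0
    wn = min(cutoff_hz, 0.8 * nyq) / nyq
    b, a = sps.butter(2, wn)
    return sps.filtfilt(b, a, waveform)


def detect_beats(
    waveform: np.ndarray,
    rate: float,
    min_hr: float = 40.0,
    max_hr: float = 250.0,
    prominence_frac: float = 0.3,
    t0: float = 0.0,
) -> BeatSeries:
    """Detect one peak per cardiac cycle on a pulsatile waveform.

    A refractory period of ``60/max_hr`` seconds is enforced between peaks;
    the prominence threshold is ``prominence_frac`` of the robust signal
    excursion (2nd–98th percentile).  A flat (all-equal) waveform yields an
    empty series.
    """
    x = np.asarray(waveform, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    if x.size < int(2 * rate):
        raise ValueError("waveform must cover at least 2 s")
    if np.ptp(x) == 0:
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    xf = _condition(x, rate)
    lo, hi = np.percentile(xf, [2, 98])
    prominence = prominence_frac * (hi - lo)
    distance = max(1, int(round(rate * 60.0 / max_hr)))
    peaks, _ = sps.find_peaks(xf, distance=distance, prominence=prominence)
    if peaks.size == 0:
        return BeatSeries(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    # Foot of each beat: minimum in the inter-beat interval preceding the peak.
    max_rr = int(round(rate * 60.0 / min_hr))
    feet = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        start = peaks[i - 1] if i > 0 else max(0, p - max_rr)
        seg = xf[start:p + 1]
        feet[i] = start + int(np.argmin(seg))
    return BeatSeries(
        beat_times=t0 + peaks / rate,
        systolic=xf[peaks],
        diastolic=xf[feet],
        foot_times=t0 + feet / rate,
    )


def block_average(series: np.ndarray, rate: float, window: float,
                  t0: float = 0.0) -> TrendSeries:
    """Non-overlapping arithmetic means; the trailing partial block is dropped.

    Each value is stamped at the *end* of its block, so the k-th 10-s
    average of a recording starting at t0=0 is stamped 10·(k+1) s.
    """
    x = np.asarray(series, dtype=float)
    n_per = int(round(window * rate))
    if n_per < 1:
        raise ValueError("window times rate must be at least 1 sample")
    nb = x.size // n_per
    if nb == 0:
        return TrendSeries(np.empty(0), np.empty(0), window, window)
    vals = x[: nb * n_per].reshape(nb, n_per).mean(axis=1)
    ts = t0 + window * np.arange(1, nb + 1)
    return TrendSeries(ts, vals, window, window)


def mean_trend(waveform: np.ndarray, rate: float, window: float,
               step: float = 1.0, t0: float = 0.0) -> TrendSeries:
    """Sliding trailing-window mean, emitted every ``step`` seconds.

    The first value appears once one full window of samples exists; a
    window covering the whole series therefore yields a single value equal
    to the global mean.
    """
    x = np.asarray(waveform, dtype=float)
    w = int(round(window * rate))
    s = max(1, int(round(step * rate)))
    if w < 1:
        raise ValueError("window times rate must be at least 1 sample")
    if x.size < w:
        return TrendSeries(np.empty(0), np.empty(0), window, step)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    ends = np.arange(w, x.size + 1, s)  # exclusive end indices
    vals = (cs[ends] - cs[ends - w]) / w
    ts = t0 + ends / rate
    return TrendSeries(ts, vals, window, s / rate)


def reg_integral_pipeline(reg: np.ndarray, rate: float,
                          window: float = 60.0, t0: float = 0.0) -> TrendSeries:
    """REG integral: first derivative, rectification, trailing running sum.

    Steps: (1) first difference scaled by the sampling rate (ohm/s);
    (2) absolute value; (3) running sum over a trailing ``window`` of
    samples times 1/rate, emitted per sample once a full window exists.
    Constant offsets vanish in step (1); respiratory baseline wander is
    small against the pulse slope and is further averaged by step (3).
    """
    x = np.asarray(reg, dtype=float)
    if rate <= 0:
        raise ValueError("rate must be positive")
    w = int(round(window * rate))
    if w < 2:
        raise ValueError("window times rate must be at least 2 samples")
    if x.size < w + 1:
        return TrendSeries(np.empty(0), np.empty(0), window, 1.0 / rate)
    d = np.abs(np.diff(x) * rate)
    cs = np.concatenate(([0.0], np.cumsum(d)))
    vals = (cs[w:] - cs[:-w]) / rate
    # d[j] sits between samples j and j+1; stamp each integral at the time
    # of the last raw sample entering its window.
    ts = t0 + np.arange(w, d.size + 1) / rate
    return TrendSeries(ts, vals, window, 1.0 / rate)


def amplitude_trend(beats: BeatSeries, window: float = 10.0,
                    step: float = 1.0, t_start: float | None = None,
                    t_end: float | None = None) -> TrendSeries:
    """Sliding mean of per-beat pulse amplitudes on a regular time grid."""
    return _beat_value_trend(beats.beat_times, beats.amplitude, window, step,
                             t_start, t_end)


def _beat_value_trend(times: np.ndarray, values: np.ndarray, window: float,
                      step: float, t_start: float | None,
                      t_end: float | None) -> TrendSeries:
    if times.size == 0:
        return TrendSeries(np.empty(0), np.empty(0), window, step)
    lo = times[0] if t_start is None else t_start
    hi = times[-1] if t_end is None else t_end
    ends = np.arange(lo + window, hi + 1e-9, step)
    if ends.size == 0:
        return TrendSeries(np.empty(0), np.empty(0), window, step)
    cs = np.concatenate(([0.0], np.cumsum(values)))
    i0 = np.searchsorted(times, ends - window, side="left")
    i1 = np.searchsorted(times, ends, side="right")
    cnt = i1 - i0
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, (cs[i1] - cs[i0]) / np.maximum(cnt, 1), np.nan)
    return TrendSeries(ends, vals, window, step)


def systolic_diastolic(beats: BeatSeries, window: float,
                       t0: float = 0.0,
                       duration: float | None = None) -> pd.DataFrame:
    """Per-window SBP/DBP/mean/HR from a beat series.

    SBP (DBP) is the mean of per-beat maxima (minima) inside each
    non-overlapping window; HR is 60 × beats/window; the mean pressure uses
    the conventional (SBP + 2·DBP)/3 estimate.  Windows without beats give
    NaN rows flagged in the ``valid`` column.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t_last = (t0 if len(beats) == 0 else beats.beat_times[-1])
    total = duration if duration is not None else (t_last - t0)
    n_win = int(total // window)
    rows = []
    for k in range(n_win):
        a, b = t0 + k * window, t0 + (k + 1) * window
        m = (beats.beat_times >= a) & (beats.beat_times < b)
        if not np.any(m):
            rows.append((b, np.nan, np.nan, np.nan, np.nan, False))
            continue
        sbp = float(np.mean(beats.systolic[m]))
        dbp = float(np.mean(beats.diastolic[m]))
        hr = 60.0 * int(np.count_nonzero(m)) / window
        rows.append((b, sbp, dbp, (sbp + 2 * dbp) / 3.0, hr, True))
    return pd.DataFrame(rows, columns=["time", "sbp", "dbp", "map", "hr", "valid"])
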