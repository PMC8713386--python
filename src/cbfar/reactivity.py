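"""Moving-correlation reactivity indices (PRx and REGx).

PRx is the Pearson correlation between 10-s averages of arterial pressure
and intracranial pressure, evaluated over a moving window of 30 averages
(300 s) advancing one average at a time.  REGx substitutes the REG integral
for ICP.  Values near −1 indicate intact (active) autoregulation — slow
pressure waves are countered by the cranial channels — while values near +1
indicate passive, pressure-following behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import SignalBundle
from .preprocess import TrendSeries, block_average, reg_integral_pipeline

#: Conventional averaging window (s) for the index inputs.
AVERAGING_WINDOW = 10.0
#: Conventional correlation window, in number of averages (30 × 10 s = 300 s).
CORRELATION_WINDOW = 30


@dataclass
class ReactivitySeries:
    """A windowed correlation index over time, values in [−1, 1] or NaN."""

    timestamps: np.ndarray
    values: np.ndarray
    window_samples: int
    step: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must match in shape")

    def __len__(self) -> int:
        return self.timestamps.size

    def restrict(self, t0: float, t1: float) -> "ReactivitySeries":
        m = (self.timestamps >= t0) & (self.timestamps <= t1)
        return ReactivitySeries(self.timestamps[m], self.values[m],
                                self.window_samples, self.step)


def moving_correlation_index(
    pressure_avg: TrendSeries,
    modality_avg: TrendSeries,
    window_samples: int = CORRELATION_WINDOW,
    step: int = 1,
) -> ReactivitySeries:
    """Pearson correlation of the last ``window_samples`` paired averages.

    Both inputs must sit on identical timestamps.  Each output value is the
    correlation over the trailing window, stamped at the window's last
    timestamp; with the conventional 10-s averages and a 30-sample window
    the first value appears at 300 s.  A window in which either input has
    zero variance yields NaN (not 0 — zero is a meaningful, dissociated
    reading).
    """
    if window_samples < 3:
        raise ValueError("window_samples must be at least 3")
    if step < 1:
        raise ValueError("step must be at least 1")
    tp, tm = pressure_avg.timestamps, modality_avg.timestamps
    if tp.shape != tm.shape or not np.allclose(tp, tm, rtol=0, atol=1e-9):
        raise ValueError("pressure and modality trends must share timestamps")
    x = pressure_avg.values.astype(float)
    y = modality_avg.values.astype(float)
    n = x.size
    if n < window_samples:
        return ReactivitySeries(np.empty(0), np.empty(0), window_samples,
                                step * pressure_avg.step)
    w = window_samples
    # Global centering keeps the running sums well conditioned.
    xc, yc = x - x.mean(), y - y.mean()
    cs = lambda a: np.concatenate(([0.0], np.cumsum(a)))
    sx, sy = cs(xc), cs(yc)
    sxx, syy, sxy = cs(xc * xc), cs(yc * yc), cs(xc * yc)
    ends = np.arange(w, n + 1, step)
    lo = ends - w
    dx = sxx[ends] - sxx[lo] - (sx[ends] - sx[lo]) ** 2 / w
    dy = syy[ends] - syy[lo] - (sy[ends] - sy[lo]) ** 2 / w
    cov = sxy[ends] - sxy[lo] - (sx[ends] - sx[lo]) * (sy[ends] - sy[lo]) / w
    # A window is degenerate exactly when min == max within it.
    roll = lambda a, f: getattr(pd.Series(a).rolling(w), f)().to_numpy()
    const_x = (roll(x, "max") - roll(x, "min"))[ends - 1] == 0
    const_y = (roll(y, "max") - roll(y, "min"))[ends - 1] == 0
    scale = np.sqrt(np.maximum(dx, 0.0) * np.maximum(dy, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(const_x | const_y | (scale == 0), np.nan, cov / scale)
    r = np.clip(r, -1.0, 1.0)
    return ReactivitySeries(tp[ends - 1], r, window_samples,
                            step * pressure_avg.step)


def prx(bundle: SignalBundle,
        averaging_window: float = AVERAGING_WINDOW,
        window_samples: int = CORRELATION_WINDOW) -> ReactivitySeries:
    """Pressure reactivity index from a bundle's SAP and ICP channels."""
    t0 = float(bundle.time[0])
    p = block_average(bundle["SAP"], bundle.rate, averaging_window, t0=t0)
    m = block_average(bundle["ICP"], bundle.rate, averaging_window, t0=t0)
    return moving_correlation_index(p, m, window_samples)


def regx(bundle: SignalBundle,
         averaging_window: float = AVERAGING_WINDOW,
         window_samples: int = CORRELATION_WINDOW,
         integral_window: float = 60.0) -> ReactivitySeries:
    """REG-based reactivity index: SAP averages vs. REG-integral averages.

    The REG integral only exists once its own 60-s window has filled, so
    the paired 10-s averages start at the first full integral window and
    the index start shifts accordingly.
    """
    t0 = float(bundle.time[0])
    integral = reg_integral_pipeline(bundle["REG"], bundle.rate,
                                     window=integral_window, t0=t0)
    if len(integral) == 0:
        return ReactivitySeries(np.empty(0), np.empty(0), window_samples,
                                averaging_window)
    ti0 = float(integral.timestamps[0])
    # Align the pressure averages to the integral's availability: integral
    # value j corresponds to raw sample w+j, so skip the first w samples.
    i_skip = int(round((ti0 - t0) * bundle.rate))
    m = block_average(integral.values, bundle.rate, averaging_window, t0=ti0)
    p = block_average(bundle["SAP"][i_skip:], bundle.rate, averaging_window,
                      t0=ti0)
    k = min(len(p), len(m))
    p = TrendSeries(p.timestamps[:k], p.values[:k], p.window_length, p.step)
    m = TrendSeries(m.timestamps[:k], m.values[:k], m.window_length, m.step)
    return moving_correlation_index(p, m, window_samples)
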