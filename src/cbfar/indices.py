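"""Scalar hemodynamic indices and session bookkeeping.

Shock index (SI = HR/SBP), the modified Kerdo autonomic-balance index,
pulse pressure, cerebral perfusion pressure (CPP = mean SAP − mean ICP),
the graded-bleed volume schedule, start-vs-end Welch comparison of a trend,
and between-channel correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
from scipy import stats

from .preprocess import TrendSeries


@dataclass(frozen=True)
class VitalIndices:
    si: np.ndarray | float
    ki: np.ndarray | float
    pp: np.ndarray | float
    cpp: np.ndarray | float


def vital_indices(sbp, dbp, hr, sap_mean, icp_mean,
                  ki_variant: str = "printed") -> VitalIndices:
    """SI, KI, PP and CPP from window-level vitals.

    SI = HR/SBP; PP = SBP − DBP; CPP = mean SAP − mean ICP.  The Kerdo
    index has two variants: the modified, as-printed form
    ``(1 − DBP/HR) + 100`` (default; >100 means sympathetic predominance)
    and the classic ``100 × (1 − DBP/HR)`` (``ki_variant="classic"``,
    positive means sympathetic predominance).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(sbp <= 0) or np.any(hr <= 0):
        raise ValueError("sbp and hr must be positive")
    if ki_variant not in ("printed", "classic"):
        raise ValueError("ki_variant must be 'printed' or 'classic'")
    si = hr / sbp
    ratio = 1.0 - dbp / hr
    ki = ratio + 100.0 if ki_variant == "printed" else 100.0 * ratio
    pp = sbp - dbp
    cpp = np.asarray(sap_mean, dtype=float) - np.asarray(icp_mean, dtype=float)
    squeeze = lambda a: float(a) if np.ndim(a) == 0 else a
    return VitalIndices(squeeze(si), squeeze(ki), squeeze(pp), squeeze(cpp))


def _truncate3(x: float) -> float:
    """Truncate (never round up) to 3 decimals, guarding float fuzz."""
    return floor(round(x * 1000.0, 6)) / 1000.0


@dataclass(frozen=True)
class BleedSchedule:
    """Graded hemorrhage bookkeeping.

    ``per_bleed_l``/``cumulative_l`` are exact; the ``display_*`` values are
    truncated to 3 decimals in litres, matching the convention under which
    65 mL/kg × 68.7 kg with 15% steps prints 0.669, 1.339 and 2.009 L.
    """

    body_mass_kg: float
    per_kg_volume_ml: float
    fraction_per_bleed: float
    n_bleeds: int
    estimated_blood_volume_l: float
    per_bleed_l: float
    cumulative_l: tuple[float, ...]
    display_per_bleed_l: float
    display_cumulative_l: tuple[float, ...]
    cumulative_fraction: tuple[float, ...]


def bleed_schedule(body_mass_kg: float = 68.7,
                   per_kg_volume_ml: float = 65.0,
                   fraction: float = 0.15,
                   n_bleeds: int = 3) -> BleedSchedule:
    """Volumes for ``n_bleeds`` withdrawals of ``fraction`` of blood volume.

    Estimated blood volume = body mass × per-kg volume; each bleed removes
    the same fraction of it, so the exact cumulative volume is linear in
    the bleed number.  Display values are truncated, not rounded.
    """
    if body_mass_kg <= 0 or per_kg_volume_ml <= 0 or fraction <= 0 or n_bleeds < 1:
        raise ValueError("all schedule inputs must be positive")
    if fraction * n_bleeds > 1.0 + 1e-12:
        raise ValueError("total withdrawn fraction exceeds the blood volume")
    ebv = body_mass_kg * per_kg_volume_ml / 1000.0
    per = fraction * ebv
    cum = tuple(k * per for k in range(1, n_bleeds + 1))
    return BleedSchedule(
        body_mass_kg=body_mass_kg,
        per_kg_volume_ml=per_kg_volume_ml,
        fraction_per_bleed=fraction,
        n_bleeds=n_bleeds,
        estimated_blood_volume_l=ebv,
        per_bleed_l=per,
        cumulative_l=cum,
        display_per_bleed_l=_truncate3(per),
        display_cumulative_l=tuple(_truncate3(c) for c in cum),
        cumulative_fraction=tuple(k * fraction for k in range(1, n_bleeds + 1)),
    )


@dataclass(frozen=True)
class StartEndComparison:
    t_statistic: float
    p_value: float
    start_mean: float
    end_mean: float
    span: float


def start_end_comparison(series: TrendSeries,
                         span: float = 1800.0) -> StartEndComparison:
    """Welch t-test between the first and last ``span`` seconds of a trend."""
    ts, v = series.timestamps, series.values
    if ts.size == 0 or (ts[-1] - ts[0]) < 2 * span:
        raise ValueError("series must cover at least twice the comparison span")
    a = v[ts <= ts[0] + span]
    b = v[ts >= ts[-1] - span]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each comparison window needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return StartEndComparison(float(t), float(p), float(a.mean()),
                              float(b.mean()), span)


@dataclass(frozen=True)
class ChannelCorrelation:
    r: float
    r_squared: float
    n: int
    degenerate: bool = False


def channel_correlation(a: TrendSeries, b: TrendSeries,
                        window: tuple[float, float]) -> ChannelCorrelation:
    """Pearson correlation of two trends over a shared time window.

    Values are paired on (near-)identical timestamps inside ``window``;
    zero variance in either input yields a degenerate NaN result rather
    than an error.
    """
    t0, t1 = window
    ar = a.restrict(t0, t1)
    br = b.restrict(t0, t1)
    # Pair on common timestamps (tolerance: half the finer step).
    tol = 0.5 * min(ar.step, br.step)
    ia = np.searchsorted(br.timestamps, ar.timestamps - tol, side="left")
    keep, jb = [], []
    for i, t in enumerate(ar.timestamps):
        j = ia[i]
        if j < br.timestamps.size and abs(br.timestamps[j] - t) <= tol:
            keep.append(i)
            jb.append(j)
    x = ar.values[keep]
    y = br.values[np.asarray(jb, dtype=int)] if jb else np.empty(0)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 3:
        raise ValueError("need at least 3 paired values in the window")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ChannelCorrelation(float("nan"), float("nan"), int(x.size), True)
    r = float(np.corrcoef(x, y)[0, 1])
    return ChannelCorrelation(r, r * r, int(x.size))
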