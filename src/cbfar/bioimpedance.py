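"""Bioimpedance analytics: Cole fitting, fluid compartments, IPG flow.

Multifrequency electrical impedance spectroscopy (EIS) of a limb segment is
summarised by the four-parameter Cole dispersion

    Z(f) = R_inf + (R0 − R_inf) / (1 + (j·2πf·τ)^α),

whose low- and high-frequency limits separate the extracellular resistance
(Re = R0, current shunted around cells) from the combined pathway that
yields the intracellular resistance Ri = R0·R_inf/(R0 − R_inf).  With a
resistivity-cylinder model the segment's extra- and intracellular volumes
follow from those resistances; the extracellular volume is further split
into intravascular and interstitial parts by a configurable fraction with
a hematocrit-dependent correction (the vendor partition is proprietary, so
this split is a documented approximation).  Fixed-frequency impedance
plethysmography (IPG) of the same segment yields per-beat flow metrics:
the relative blood-flow index %BF and the arterial inflow / venous outflow
times TIN and TOUT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .preprocess import BeatSeries


@dataclass(frozen=True)
class ColeParams:
    """Cole dispersion parameters (resistances in ohm, tau in seconds)."""

    r0: float
    rinf: float
    tau: float
    alpha: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r0 > self.rinf > 0):
            raise ValueError("require R0 > Rinf > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def re(self) -> float:
        """Extracellular resistance (zero-frequency limit)."""
        return self.r0

    @property
    def ri(self) -> float:
        """Intracellular resistance: R0·Rinf/(R0 − Rinf)."""
        return self.r0 * self.rinf / (self.r0 - self.rinf)


def cole_impedance(frequencies_hz: np.ndarray, params: ColeParams) -> np.ndarray:
    """Forward Cole model: complex impedance at the given frequencies."""
    f = np.asarray(frequencies_hz, dtype=float)
    jwt = (1j * 2 * np.pi * f * params.tau) ** params.alpha
    return params.rinf + (params.r0 - params.rinf) / (1.0 + jwt)


@dataclass
class ImpedanceSpectrumSeries:
    """Complex impedance spectra over time (n_times × n_frequencies)."""

    timestamps: np.ndarray
    frequencies_hz: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if self.z.shape != (self.timestamps.size, self.frequencies_hz.size):
            raise ValueError("z must be (n_times, n_frequencies)")

    def __len__(self) -> int:
        return self.timestamps.size


def fit_cole(frequencies_hz: np.ndarray, z: np.ndarray,
             alpha_starts: tuple[float, ...] = (0.7, 0.9, 1.0),
             max_rel_residual: float = 0.5) -> ColeParams:
    """Least-squares Cole fit on real and imaginary parts jointly.

    R0 is initialised from the lowest-frequency |Z|, Rinf from the highest;
    tau from the frequency of the largest reactance; several alpha starts
    are tried and the best converged fit kept.  Raises if no start
    converges to a residual below ``max_rel_residual`` (relative RMS).
    """
    f = np.asarray(frequencies_hz, dtype=float)
    zz = np.asarray(z, dtype=complex)
    if f.size < 5:
        raise ValueError("need at least 5 frequencies")
    if f.max() / f.min() < 10.0:
        raise ValueError("frequencies must span at least one decade")
    mag = np.abs(zz)
    r0_init = float(mag[np.argmin(f)])
    rinf_init = float(mag[np.argmax(f)])
    rinf_init = min(rinf_init, 0.95 * r0_init)
    k = int(np.argmax(-zz.imag))
    tau_init = 1.0 / (2 * np.pi * f[k]) if zz.imag[k] < 0 else 1.0 / (2 * np.pi * np.median(f))

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        p = ColeParams(pars["rinf"].value + pars["delta"].value,
                       pars["rinf"].value, pars["tau"].value,
                       pars["alpha"].value)
        d = cole_impedance(f, p) - zz
        return np.concatenate([d.real, d.imag])

    best: tuple[float, lmfit.Parameters] | None = None
    for a0 in alpha_starts:
        pars = lmfit.Parameters()
        pars.add("rinf", value=rinf_init, min=1e-6)
        pars.add("delta", value=max(r0_init - rinf_init, 1e-3), min=1e-6)
        pars.add("tau", value=tau_init, min=1e-12, max=1.0)
        pars.add("alpha", value=a0, min=0.05, max=1.0)
        try:
            out = lmfit.minimize(residual, pars, method="leastsq")
        except Exception:
            continue
        chi = float(np.sqrt(np.mean(residual(out.params) ** 2)))
        if best is None or chi < best[0]:
            best = (chi, out.params)
    if best is None:
        raise RuntimeError("Cole fit failed to converge from any start")
    chi, pars = best
    rel = chi / float(np.mean(mag))
    if rel > max_rel_residual:
        raise RuntimeError(
            f"Cole fit did not converge: relative residual {rel:.3g} "
            f"(absolute {chi:.3g} ohm)")
    return ColeParams(pars["rinf"].value + pars["delta"].value,
                      pars["rinf"].value, pars["tau"].value,
                      pars["alpha"].value, residual=rel)


@dataclass(frozen=True)
class VolumeConstants:
    """Resistivity-cylinder constants mapping resistances to volumes.

    Volumes follow V = ρ · L² / R (cm³), with apparent resistivities for
    the extra- and intracellular pathways and the segment length L in cm.
    The intravascular fraction splits the extracellular volume into blood
    and interstitial parts; the hematocrit correction rescales the blood
    part for red-cell content (approximation — see module docstring).
    """

    segment_length_cm: float = 35.0
    rho_extracellular_ohm_cm: float = 40.0
    rho_intracellular_ohm_cm: float = 100.0
    intravascular_fraction: float = 0.35
    hematocrit: float = 0.40
    reference_hematocrit: float = 0.40
    hematocrit_slope: float = 0.5

    def blood_fraction(self) -> float:
        corr = 1.0 + self.hematocrit_slope * (self.hematocrit
                                              - self.reference_hematocrit)
        return float(np.clip(self.intravascular_fraction * corr, 0.0, 1.0))


def compartment_volumes(params: ColeParams,
                        constants: VolumeConstants | None = None,
                        ) -> tuple[float, float]:
    """(Vec, Vic) in litres from fitted Cole resistances.

    Monotone decreasing in the respective resistance; a zero-length
    segment gives zero volumes.
    """
    c = constants or VolumeConstants()
    if params.re <= 0 or params.ri <= 0:
        raise ValueError("resistances must be positive")
    if c.segment_length_cm < 0:
        raise ValueError("segment length must be non-negative")
    l2 = c.segment_length_cm ** 2
    vec = c.rho_extracellular_ohm_cm * l2 / params.re / 1000.0
    vic = c.rho_intracellular_ohm_cm * l2 / params.ri / 1000.0
    return vec, vic


def volumes_to_cole(vec_l: float, vic_l: float,
                    constants: VolumeConstants | None = None,
                    tau: float = 2e-6, alpha: float = 0.8) -> ColeParams:
    """Inverse of :func:`compartment_volumes`: prescribe volumes, get Cole
    parameters (used by the forward EIS simulator)."""
    c = constants or VolumeConstants()
    if vec_l <= 0 or vic_l <= 0:
        raise ValueError("volumes must be positive")
    l2 = c.segment_length_cm ** 2
    re = c.rho_extracellular_ohm_cm * l2 / (vec_l * 1000.0)
    ri = c.rho_intracellular_ohm_cm * l2 / (vic_l * 1000.0)
    r0 = re
    rinf = re * ri / (re + ri)
    return ColeParams(r0=r0, rinf=rinf, tau=tau, alpha=alpha)


@dataclass
class CompartmentState:
    """Per-time-point fluid compartment volumes (litres) and derived series.

    Vec = Vb + Vi always; ``normalize_and_transfer`` fills the normalized
    series (each volume divided by its baseline-window mean) and the
    transfer series Fc/Fi/Fb (litres moved *out of* each compartment since
    baseline — positive means loss from that compartment).
    """

    timestamps: np.ndarray
    vic: np.ndarray
    vec: np.ndarray
    vb: np.ndarray
    vi: np.ndarray
    nv_cellular: np.ndarray | None = None
    nv_blood: np.ndarray | None = None
    nv_interstitial: np.ndarray | None = None
    fc: np.ndarray | None = None
    fi: np.ndarray | None = None
    fb: np.ndarray | None = None
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("timestamps", "vic", "vec", "vb", "vi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.timestamps.size
        for name in ("vic", "vec", "vb", "vi"):
            if getattr(self, name).size != n:
                raise ValueError("all volume series must match timestamps")
        if not np.allclose(self.vec, self.vb + self.vi, rtol=0, atol=1e-9):
            raise ValueError("Vec must equal Vb + Vi")

    @staticmethod
    def from_extracellular_split(timestamps, vic, vec,
                                 constants: VolumeConstants | None = None,
                                 ) -> "CompartmentState":
        c = constants or VolumeConstants()
        vec = np.asarray(vec, dtype=float)
        vb = c.blood_fraction() * vec
        return CompartmentState(timestamps=np.asarray(timestamps, dtype=float),
                                vic=np.asarray(vic, dtype=float),
                                vec=vec, vb=vb, vi=vec - vb)

    @property
    def total(self) -> np.ndarray:
        return self.vic + self.vec


def normalize_and_transfer(state: CompartmentState,
                           baseline_window: tuple[float, float],
                           ) -> CompartmentState:
    """Fill normalized volumes and inter-compartment transfer series.

    Normalization divides each series by its mean over the baseline window
    (the pre-first-bleed period by convention).  Transfers are
    F_x(t) = −(V_x(t) − ⟨V_x⟩_baseline): a compartment that loses volume
    shows a positive transfer-out.  Fc + Fi + Fb + (total change) = 0 by
    construction.
    """
    t0, t1 = baseline_window
    m = (state.timestamps >= t0) & (state.timestamps <= t1)
    if not np.any(m):
        raise ValueError("baseline window contains no samples")

    def base(v: np.ndarray) -> float:
        b = float(np.mean(v[m]))
        if b == 0:
            raise ValueError("zero baseline mean volume")
        return b

    b_ic, b_b, b_i = base(state.vic), base(state.vb), base(state.vi)
    return replace(
        state,
        nv_cellular=state.vic / b_ic,
        nv_blood=state.vb / b_b,
        nv_interstitial=state.vi / b_i,
        fc=-(state.vic - b_ic),
        fb=-(state.vb - b_b),
        fi=-(state.vi - b_i),
        baseline_window=baseline_window,
    )


@dataclass
class IPGMetrics:
    """Per-beat IPG flow metrics.

    percent_blood_flow is the percent change of (pulse amplitude × HR)
    relative to the baseline segment; TIN is foot-to-peak time; TOUT the
    time from the peak to a configurable fractional return toward the next
    foot.
    """

    timestamps: np.ndarray
    percent_blood_flow: np.ndarray
    tin: np.ndarray
    tout: np.ndarray
    valid: np.ndarray


def ipg_flow_metrics(waveform: np.ndarray, rate: float, beats: BeatSeries,
                     baseline_window: tuple[float, float] | None = None,
                     return_fraction: float = 0.9,
                     calibration: float = 1.0,
                     t0: float = 0.0) -> IPGMetrics:
    """Beat-wise %BF, TIN and TOUT from a pulsatile impedance waveform.

    For each beat with a detectable foot: TIN = time from foot to peak;
    TOUT = time from peak until the waveform has returned
    ``return_fraction`` of the way to the *next* beat's foot value
    (linearly interpolated).  %BF for a beat is
    ``100·(calibration·amplitude·HR_local)/(baseline mean) − 100``, with
    the baseline mean of calibration·amplitude·HR taken over
    ``baseline_window`` (the whole recording when omitted); unchanged
    amplitude and rate therefore read 0 %.
    """
    x = np.asarray(waveform, dtype=float)
    if len(beats) < 3:
        raise ValueError("need at least 3 beats")
    if not 0 < return_fraction <= 1:
        raise ValueError("return_fraction must be in (0, 1]")
    n_beats = len(beats)
    tin = np.full(n_beats, np.nan)
    tout = np.full(n_beats, np.nan)
    flow = np.full(n_beats, np.nan)
    valid = np.zeros(n_beats, dtype=bool)
    rr = np.diff(beats.beat_times)
    for i in range(n_beats):
        foot_t = beats.foot_times[i]
        if not np.isfinite(foot_t) or foot_t >= beats.beat_times[i]:
            continue
        tin[i] = beats.beat_times[i] - foot_t
        hr_local = 60.0 / rr[min(i, rr.size - 1)]
        flow[i] = calibration * (beats.systolic[i] - beats.diastolic[i]) * hr_local
        if i + 1 < n_beats and np.isfinite(beats.foot_times[i + 1]):
            p_idx = int(round((beats.beat_times[i] - t0) * rate))
            f_idx = int(round((beats.foot_times[i + 1] - t0) * rate))
            if f_idx <= p_idx or f_idx > x.size:
                continue
            seg = x[p_idx:f_idx + 1]
            peak_v = seg[0]
            target = peak_v - return_fraction * (peak_v - x[min(f_idx, x.size - 1)])
            below = np.nonzero(seg <= target)[0]
            if below.size == 0:
                continue
            k = below[0]
            if k == 0:
                tout[i] = 0.0
            else:
                # linear interpolation between samples k-1 and k
                v0, v1 = seg[k - 1], seg[k]
                frac = 0.0 if v1 == v0 else (v0 - target) / (v0 - v1)
                tout[i] = (k - 1 + frac) / rate
            valid[i] = True
    if baseline_window is None:
        sel = np.isfinite(flow)
    else:
        b0, b1 = baseline_window
        sel = np.isfinite(flow) & (beats.beat_times >= b0) & (beats.beat_times <= b1)
    if not np.any(sel):
        raise ValueError("no valid beats in the %BF baseline window")
    ref = float(np.mean(flow[sel]))
    pbf = 100.0 * flow / ref - 100.0
    return IPGMetrics(timestamps=beats.beat_times.copy(),
                      percent_blood_flow=pbf, tin=tin, tout=tout, valid=valid)
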