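"""Seeded synthetic physiological recordings with known autoregulation state.

The generator emulates the scripted porcine PEEP/graded-hemorrhage session
well enough to exercise every analysis stage: pulsatile pressure and flow
waveforms (asymmetric gamma-like pulse, fast upstroke / slow decay), slow
vasogenic (B-wave) oscillations and a respiratory sinusoid, logistic
epoch responses to PEEP, CO2, anesthesia transition and bleeds, and a
per-epoch active/passive autoregulation flag that sets the *sign* with
which the cranial channels (ICP, REG pulse amplitude, carotid-flow pulse
amplitude) respond to systemic-pressure changes — opposite when active,
identical when passive.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bioimpedance import (CompartmentState, ImpedanceSpectrumSeries,
                           VolumeConstants, cole_impedance, volumes_to_cole)
from .bundle import SignalBundle
from .script import ARProfile, ChallengeKind, ChallengeScript

#: Logistic transition time-scale (s); onset/offset complete within ~30 s.
_TAU = 5.0
#: Response centres lag the epoch boundaries by this many seconds.
_LAG = 15.0


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise and slow-oscillation amplitudes (channel units)."""

    sap_sd: float = 0.3
    icp_sd: float = 0.05
    reg_sd: float = 0.003
    cf_sd: float = 0.3
    cbf_sd: float = 0.5
    ldf_sd: float = 0.5
    cvp_sd: float = 0.05
    pap_sd: float = 0.05
    co2_sd: float = 0.03
    po2_sd: float = 0.008
    slow_wave_mmhg: float = 2.5     # B-wave amplitude in SAP
    icp_slow_mmhg: float = 0.15    # coupled B-wave amplitude in ICP
    amp_slow_frac: float = 0.012   # coupled relative amplitude modulation
    resp_icp_mmhg: float = 0.3
    resp_reg_ohm: float = 0.04
    resp_freq_hz: float = 0.25
    b_freqs_hz: tuple[float, float] = (0.02, 0.0314)


@dataclass(frozen=True)
class PhysioParams:
    """Baseline physiology and epoch response gains."""

    sbp0: float = 120.0
    dbp0: float = 80.0
    hr0: float = 90.0
    icp0: float = 12.0
    reg0: float = 100.0
    reg_amp0: float = 0.15
    cf0: float = 60.0
    cf_amp0: float = 20.0
    cbf0: float = 100.0
    ldf0: float = 100.0
    cvp0: float = 6.0
    pap0: float = 18.0
    co2_0: float = 5.0
    po2_amp0: float = 1.0
    sv0: float = 55.0
    icp_pulse_amp: float = 1.2
    # SAP responses (mmHg) per challenge
    sap_per_cmh2o_peep: float = -0.9
    sap_per_bleed: float = -10.0       # per 15% blood-volume step
    sap_lethal: float = -25.0
    sap_co2: float = 8.0
    sap_transition: float = 10.0
    # cranial gains
    icp_gain: float = 0.25             # mmHg per mmHg SAP change
    icp_gain_bleed: float = 0.15
    reg_amp_coeff: float = 0.015       # log-amplitude per mmHg
    cf_amp_coeff: float = 0.012
    hr_per_bleed: float = 8.0
    hr_drift_per_s: float = 0.002      # upward drift after first bleed


def _pulse_shape(phase: np.ndarray, c: float = 0.25, k: float = 3.0) -> np.ndarray:
    """Asymmetric gamma-like pulse on phase in [0, 1): unit peak at c."""
    r = phase / c
    return r ** k * np.exp(k * (1.0 - r))


def _env(t: np.ndarray, ep_start: float, ep_end: float | None) -> np.ndarray:
    """Logistic onset (and offset unless persistent) response envelope."""
    e = expit((t - (ep_start + _LAG)) / _TAU)
    if ep_end is not None:
        e = e - expit((t - (ep_end + _LAG)) / _TAU)
    return e


def _sap_delta(kind: ChallengeKind, magnitude: float, p: PhysioParams) -> float:
    if kind == ChallengeKind.PEEP:
        return p.sap_per_cmh2o_peep * magnitude
    if kind == ChallengeKind.HEMORRHAGE:
        return p.sap_per_bleed * (magnitude / 0.15)
    if kind == ChallengeKind.LETHAL:
        return p.sap_lethal * (magnitude / 0.15)
    if kind == ChallengeKind.CO2:
        return p.sap_co2
    return p.sap_transition


def simulate_bundle(script: ChallengeScript, profile: ARProfile,
                    noise: NoiseParams | None = None, seed: int = 0,
                    rate: float = 200.0,
                    physio: PhysioParams | None = None) -> SignalBundle:
    """Generate a multichannel recording for a challenge script.

    For every epoch flagged active in ``profile`` the cranial channels
    (ICP, REG pulse amplitude, CF pulse amplitude) respond with the sign
    opposite to the SAP change and the slow waves couple invertedly; for
    passive epochs both follow pressure.  Identical inputs and seed yield
    a bit-identical bundle.
    """
    nz = noise or NoiseParams()
    ph = physio or PhysioParams()
    if rate < 50:
        raise ValueError("rate must be at least 50 Hz")
    if script.total_duration <= 0:
        raise ValueError("script duration must be positive")
    profile.validate_against(script)
    rng = np.random.default_rng(seed)
    n = int(round(script.total_duration * rate))
    t = np.arange(n) / rate

    # --- epoch drives -----------------------------------------------------
    d_sap = np.zeros(n)          # total SAP mean shift
    d_sap_hem = np.zeros(n)      # hemorrhage-driven part (persists)
    cranial_icp = np.zeros(n)    # signed ICP drive, gains folded in
    cranial_mod = np.zeros(n)    # signed drive for amplitude modulation
    peep_cmh2o = np.zeros(n)     # currently applied PEEP pressure
    hem_cum = np.zeros(n)        # cumulative bleed count (smooth)
    co2_env = np.zeros(n)
    persistent = (ChallengeKind.HEMORRHAGE, ChallengeKind.LETHAL)
    first_bleed_start = None
    for i, ep in enumerate(script.epochs):
        persist = ep.kind in persistent
        env = _env(t, ep.t_start, None if persist else ep.t_end)
        dsap = _sap_delta(ep.kind, ep.magnitude, ph)
        d_sap += dsap * env
        s = -1.0 if profile.active[i] else 1.0
        gain = ph.icp_gain_bleed if persist else ph.icp_gain
        cranial_icp += s * gain * dsap * env
        cranial_mod += s * dsap * env
        if persist:
            d_sap_hem += dsap * env
            hem_cum += env
            if first_bleed_start is None:
                first_bleed_start = ep.t_start
        if ep.kind == ChallengeKind.PEEP:
            peep_cmh2o += ep.magnitude * env
        if ep.kind == ChallengeKind.CO2:
            co2_env += env

    # --- slow oscillations and coupling sign ------------------------------
    f1, f2 = nz.b_freqs_hz
    p1, p2, pr = rng.uniform(0, 2 * np.pi, size=3)
    b = (np.sin(2 * np.pi * f1 * t + p1)
         + 0.6 * np.sin(2 * np.pi * f2 * t + p2)) / 1.6
    resp = np.sin(2 * np.pi * nz.resp_freq_hz * t + pr)
    couple = np.full(n, -1.0)  # active coupling before the first epoch
    for i, ep in enumerate(script.epochs):
        couple[t >= ep.t_start] = -1.0 if profile.active[i] else 1.0

    # --- cardiac pulse train ----------------------------------------------
    hr = ph.hr0 + ph.hr_per_bleed * hem_cum
    if first_bleed_start is not None:
        hr = hr + ph.hr_drift_per_s * np.clip(t - first_bleed_start, 0, None)
    phase = np.cumsum(hr / 60.0) / rate
    pulse = _pulse_shape(np.mod(phase, 1.0))

    # --- channels ----------------------------------------------------------
    dbp = ph.dbp0 + 0.8 * (d_sap + nz.slow_wave_mmhg * b)
    pp = (ph.sbp0 - ph.dbp0) + 0.35 * d_sap_hem
    sap = dbp + pp * pulse + rng.normal(0, nz.sap_sd, n)

    icp = (ph.icp0 + cranial_icp + couple * nz.icp_slow_mmhg * b
           + nz.resp_icp_mmhg * resp + ph.icp_pulse_amp * pulse
           + rng.normal(0, nz.icp_sd, n))
    icp = np.clip(icp, 0.2, 39.5)

    reg_amp = ph.reg_amp0 * np.exp(ph.reg_amp_coeff * cranial_mod
                                   + couple * nz.amp_slow_frac * b)
    reg = (ph.reg0 + nz.resp_reg_ohm * resp + reg_amp * pulse
           + rng.normal(0, nz.reg_sd, n))

    cf_amp = ph.cf_amp0 * np.exp(ph.cf_amp_coeff * cranial_mod
                                 + couple * nz.amp_slow_frac * b)
    cf = (ph.cf0 + 0.4 * d_sap + cf_amp * pulse + rng.normal(0, nz.cf_sd, n))

    cbf = ph.cbf0 + 0.5 * d_sap + 0.3 * b + rng.normal(0, nz.cbf_sd, n)
    ldf = ph.ldf0 + 0.4 * d_sap + rng.normal(0, nz.ldf_sd, n)
    cvp = (ph.cvp0 + 0.12 * peep_cmh2o - 1.2 * hem_cum + 0.05 * b
           + rng.normal(0, nz.cvp_sd, n))
    pap = (ph.pap0 + (0.08 + 0.12 * hem_cum) * peep_cmh2o + 0.6 * hem_cum
           + rng.normal(0, nz.pap_sd, n))
    co2 = (ph.co2_0 + 2.0 * co2_env + 0.15 * resp
           + rng.normal(0, nz.co2_sd, n))
    po2 = (ph.po2_amp0 * np.exp(0.01 * d_sap) * pulse
           + rng.normal(0, nz.po2_sd, n))
    sv = ph.sv0 + 0.4 * d_sap + rng.normal(0, 0.1, n)
    hr_chan = hr + rng.normal(0, 0.2, n)
    co = hr_chan * sv / 1000.0

    channels = {
        "SAP": sap, "ICP": icp, "REG": reg, "CF": cf, "CBF": cbf,
        "LDF": ldf, "CVP": cvp, "PAP": pap, "CO2": co2, "pO2": po2,
        "HR": hr_chan, "SV": sv, "CO": co,
    }
    meta = {"seed": seed, "n_epochs": len(script),
            "active_flags": list(map(bool, profile.active))}
    return SignalBundle(time=t, channels=channels, rate=rate, meta=meta)


def simulate_compartments(script: ChallengeScript, dt: float = 10.0,
                          vic0: float = 1.00, vb0: float = 0.20,
                          vi0: float = 0.30) -> CompartmentState:
    """Prescribed calf fluid-compartment trajectory for a bleed script.

    Each bleed draws volume out of all three compartments toward the
    central circulation: intravascular volume falls first, then refills
    partly at the expense of the interstitial and cellular spaces
    (logistic kinetics, consistent with the generator's epoch envelopes).
    """
    n = max(int(script.total_duration // dt), 1)
    t = np.arange(n) * dt
    hem = np.zeros(n)
    refill = np.zeros(n)
    for ep in script.epochs:
        if ep.kind in (ChallengeKind.HEMORRHAGE, ChallengeKind.LETHAL):
            hem += _env(t, ep.t_start, None)
            refill += _env(t, ep.t_start + 60.0, None)
    vb = vb0 - 0.030 * hem + 0.018 * refill
    vi = vi0 - 0.012 * refill
    vic = vic0 - 0.008 * refill
    return CompartmentState(timestamps=t, vic=vic, vec=vb + vi, vb=vb, vi=vi)


def simulate_eis_series(state: CompartmentState,
                        frequencies_hz: np.ndarray | None = None,
                        noise_sd_ohm: float = 0.02, seed: int = 0,
                        constants: VolumeConstants | None = None,
                        tau: float = 2e-6, alpha: float = 0.8,
                        ) -> ImpedanceSpectrumSeries:
    """Forward Cole spectra for a prescribed volume trajectory.

    Extra-/intracellular resistances are derived from the prescribed
    volumes through the same resistivity-cylinder constants the analysis
    uses, so a noiseless round trip through ``fit_cole`` and
    ``compartment_volumes`` recovers the trajectory.
    """
    if frequencies_hz is None:
        frequencies_hz = np.logspace(3, 6, 25)
    f = np.asarray(frequencies_hz, dtype=float)
    if f.size < 5:
        raise ValueError("need at least 5 frequencies")
    if np.any(state.vec <= 0) or np.any(state.vic <= 0):
        raise ValueError("volumes must be positive")
    rng = np.random.default_rng(seed)
    z = np.empty((state.timestamps.size, f.size), dtype=complex)
    for k in range(state.timestamps.size):
        params = volumes_to_cole(float(state.vec[k]), float(state.vic[k]),
                                 constants=constants, tau=tau, alpha=alpha)
        zk = cole_impedance(f, params)
        if noise_sd_ohm > 0:
            zk = (zk + rng.normal(0, noise_sd_ohm, f.size)
                  + 1j * rng.normal(0, noise_sd_ohm, f.size))
        z[k] = zk
    return ImpedanceSpectrumSeries(timestamps=state.timestamps.copy(),
                                   frequencies_hz=f, z=z)
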