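"""End-to-end pipeline: simulate/load → preprocess → indices → report.

``run_pipeline`` orchestrates the stages on one bundle and writes
machine-readable tables plus a human-readable text report: the
sign/status grid with per-modality active counts, the stagewise
percent-change table for mean ICP and the REG integral, the vital-index
trends, PRx/REGx, and (when spectra are supplied) the fluid-compartment
section.  Given a fixed config and seed the outputs are byte-identical
across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from .bioimpedance import (CompartmentState, VolumeConstants,
                           compartment_volumes, fit_cole,
                           normalize_and_transfer)
from .bundle import SignalBundle
from .indices import vital_indices
from .io import load_bundle, load_spectra, save_bundle
from .preprocess import detect_beats, mean_trend, reg_integral_pipeline, systolic_diastolic
from .reactivity import prx, regx
from .script import ARProfile, ChallengeScript, ScriptConfig, build_challenge_script
from .simulate import simulate_bundle

log = logging.getLogger("cbfar")


@dataclass
class PipelineResult:
    status_table: cls.ARStatusTable
    summary: pd.DataFrame
    percent_change: pd.DataFrame
    vitals: pd.DataFrame
    prx_series: object
    regx_series: object
    compartments: CompartmentState | None


def run_pipeline(bundle: SignalBundle, script: ChallengeScript,
                 out_dir: str | Path | None = None,
                 threshold: float = 0.03,
                 spectra_path: str | Path | None = None,
                 eis_baseline: tuple[float, float] | None = None,
                 constants: VolumeConstants | None = None) -> PipelineResult:
    """Run classification, indices, reactivity and (optionally) EIS stages."""
    log.info("status table: %d epochs, threshold %.3f", len(script), threshold)
    table = cls.build_status_table(bundle, script, threshold=threshold)
    summary = cls.summarize_active(table) if len(script) else pd.DataFrame()

    t0 = float(bundle.time[0])
    icp_trend = mean_trend(bundle["ICP"], bundle.rate, 10.0, t0=t0)
    reg_int = reg_integral_pipeline(bundle["REG"], bundle.rate, t0=t0)
    stages = cls.stages_from_script(script)
    log.info("percent-change table: %d stages", len(stages))
    pct = cls.percent_change_table({"ICP": icp_trend, "REG": reg_int}, stages)

    log.info("vital indices")
    beats = detect_beats(bundle["SAP"], bundle.rate, t0=t0)
    vit = systolic_diastolic(beats, 60.0, t0=t0, duration=bundle.duration)
    icp_win = mean_trend(bundle["ICP"], bundle.rate, 60.0, step=60.0, t0=t0)
    n = min(len(vit), len(icp_win))
    vi = vital_indices(vit["sbp"].to_numpy()[:n], vit["dbp"].to_numpy()[:n],
                       vit["hr"].to_numpy()[:n], vit["map"].to_numpy()[:n],
                       icp_win.values[:n])
    vitals = vit.iloc[:n].assign(si=vi.si, ki=vi.ki, pp=vi.pp, cpp=vi.cpp)

    log.info("reactivity indices")
    prx_s = prx(bundle)
    regx_s = regx(bundle)

    comp: CompartmentState | None = None
    if spectra_path is not None:
        log.info("EIS compartment volumes from %s", spectra_path)
        spectra = load_spectra(spectra_path)
        vec = np.empty(len(spectra))
        vic = np.empty(len(spectra))
        for k in range(len(spectra)):
            p = fit_cole(spectra.frequencies_hz, spectra.z[k])
            vec[k], vic[k] = compartment_volumes(p, constants)
        comp = CompartmentState.from_extracellular_split(
            spectra.timestamps, vic, vec, constants)
        base = eis_baseline
        if base is None and script.epochs:
            first_bleed = next((ep for ep in script.epochs
                                if ep.kind.value in ("hemorrhage", "lethal")), None)
            base = ((float(spectra.timestamps[0]), first_bleed.t_start)
                    if first_bleed else
                    (float(spectra.timestamps[0]), float(spectra.timestamps[-1])))
        comp = normalize_and_transfer(comp, base)

    result = PipelineResult(table, summary, pct, vitals, prx_s, regx_s, comp)
    if out_dir is not None:
        _write_report(result, Path(out_dir))
    return result


def _fmt_reactivity(series) -> pd.DataFrame:
    return pd.DataFrame({"time": series.timestamps, "value": series.values})


def _write_report(res: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res.status_table.signs.to_csv(out_dir / "sign_grid.tsv", sep="\t")
    res.status_table.calls.to_csv(out_dir / "ar_calls.tsv", sep="\t")
    res.summary.to_csv(out_dir / "active_summary.tsv", sep="\t")
    res.percent_change.to_csv(out_dir / "percent_change.tsv", sep="\t",
                              float_format="%.3f")
    res.vitals.to_csv(out_dir / "vitals.tsv", sep="\t", index=False,
                      float_format="%.4f")
    _fmt_reactivity(res.prx_series).to_csv(out_dir / "prx.tsv", sep="\t",
                                           index=False, float_format="%.6f")
    _fmt_reactivity(res.regx_series).to_csv(out_dir / "regx.tsv", sep="\t",
                                            index=False, float_format="%.6f")
    lines = ["Cerebral autoregulation status report", "=" * 38, ""]
    lines.append("Sign grid (rows: challenges; +: rise, -: fall, 0: none):")
    lines.append(res.status_table.signs.to_string())
    lines.append("")
    lines.append("Active autoregulation counts per modality:")
    lines.append(res.summary.to_string())
    lines.append("")
    lines.append("Percent change at PEEP 15/20 per bleeding stage "
                 "(vs own pre-series baseline):")
    lines.append(res.percent_change.to_string(float_format="%.1f"))
    if res.status_table.flagged_channels:
        lines.append("")
        lines.append("Flagged (missing) channels: "
                     + ", ".join(res.status_table.flagged_channels))
    if res.compartments is not None:
        comp = res.compartments
        lines += ["", "Fluid compartments (approximate intravascular/"
                  "interstitial split):"]
        df = pd.DataFrame({
            "time": comp.timestamps,
            "nV_cellular": comp.nv_cellular,
            "nV_blood": comp.nv_blood,
            "nV_interstitial": comp.nv_interstitial,
            "Fc": comp.fc, "Fb": comp.fb, "Fi": comp.fi,
        })
        df.to_csv(out_dir / "compartments.tsv", sep="\t", index=False,
                  float_format="%.5f")
        lines.append(df.describe().loc[["min", "max"]].to_string(
            float_format="%.4f"))
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")


def simulate_session(seed: int = 0, compact: bool = True,
                     profile_kind: str = "staged", rate: float = 100.0,
                     out: str | Path | None = None,
                     ) -> tuple[SignalBundle, ChallengeScript, ARProfile]:
    """Convenience wrapper: canonical script + simulated bundle.

    ``profile_kind`` is one of active/passive/staged; "staged" mirrors the
    modelled experiment (autoregulation lost from the second bleed on).
    """
    cfg = ScriptConfig().compact() if compact else ScriptConfig()
    script = build_challenge_script(cfg)
    makers = {"active": ARProfile.all_active, "passive": ARProfile.all_passive,
              "staged": ARProfile.staged}
    profile = makers[profile_kind](script)
    bundle = simulate_bundle(script, profile, seed=seed, rate=rate)
    if out is not None:
        save_bundle(bundle, out)
    return bundle, script, profile
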