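"""Plain-text formats: bundles, spectra, trend tables, configuration.

Bundles are tab-separated tables (one ``time`` column plus named channels)
with a JSON sidecar (``<path>.meta.json``) holding the rate, units and
provenance; spectra use a long format (time, frequency_hz, z_real_ohm,
z_imag_ohm).  All files are UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bioimpedance import ImpedanceSpectrumSeries
from .bundle import SignalBundle

_FLOAT_FMT = "%.6f"


def save_bundle(bundle: SignalBundle, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time": bundle.time, **bundle.channels})
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {"rate_hz": bundle.rate, "units": bundle.units, "meta": bundle.meta}
    Path(f"{path}.meta.json").write_text(json.dumps(meta, indent=2))


def load_bundle(path: str | Path, rate: float | None = None) -> SignalBundle:
    """Read a bundle table; columns are matched by name, order-independent.

    The rate comes from the sidecar when present, else from the time
    column; a non-monotone or non-uniform time column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        if np.ptp(dt) > 1e-4 * np.median(dt):
            raise ValueError(f"{path}: time column is not uniformly sampled")
    units: dict[str, str] = {}
    meta: dict = {}
    sidecar = Path(f"{path}.meta.json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        rate = rate or info.get("rate_hz")
        units = info.get("units", {})
        meta = info.get("meta", {})
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"}
    return SignalBundle(time=t, channels=channels, rate=float(rate),
                        units=units, meta=meta)


def save_spectra(series: ImpedanceSpectrumSeries, path: str | Path) -> None:
    nt, nf = series.z.shape
    df = pd.DataFrame({
        "time": np.repeat(series.timestamps, nf),
        "frequency_hz": np.tile(series.frequencies_hz, nt),
        "z_real_ohm": series.z.real.ravel(),
        "z_imag_ohm": series.z.imag.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)


def load_spectra(path: str | Path) -> ImpedanceSpectrumSeries:
    df = pd.read_csv(path, sep="\t")
    times = np.unique(df["time"].to_numpy(dtype=float))
    freqs = np.unique(df["frequency_hz"].to_numpy(dtype=float))
    z = np.full((times.size, freqs.size), np.nan, dtype=complex)
    ti = np.searchsorted(times, df["time"].to_numpy(dtype=float))
    fi = np.searchsorted(freqs, df["frequency_hz"].to_numpy(dtype=float))
    z[ti, fi] = (df["z_real_ohm"].to_numpy(dtype=float)
                 + 1j * df["z_imag_ohm"].to_numpy(dtype=float))
    return ImpedanceSpectrumSeries(timestamps=times, frequencies_hz=freqs, z=z)


def load_config(path: str | Path) -> dict:
    """YAML (or JSON — a YAML subset) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
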