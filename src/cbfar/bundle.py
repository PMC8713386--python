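"""Uniformly sampled multichannel recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default physical units per canonical channel name.
DEFAULT_UNITS = {
    "SAP": "mmHg",
    "ICP": "mmHg",
    "REG": "ohm",
    "CF": "a.u.",
    "CBF": "a.u.",
    "LDF": "a.u.",
    "CVP": "mmHg",
    "PAP": "mmHg",
    "CO2": "%",
    "pO2": "a.u.",
    "HR": "bpm",
    "SV": "mL",
    "CO": "L/min",
}


@dataclass
class SignalBundle:
    """A uniformly sampled multichannel recording.

    time is in seconds and strictly uniform at ``rate`` Hz; every channel
    array has the same length as time.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    rate: float
    units: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = self.time.size
        if n >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, 1.0 / self.rate, rtol=0, atol=1e-6 / self.rate):
                raise ValueError("time axis is not uniform at the declared rate")
        for name, x in self.channels.items():
            x = np.asarray(x, dtype=float)
            if x.shape != (n,):
                raise ValueError(f"channel {name!r} length {x.size} != time length {n}")
            self.channels[name] = x
        for name in self.channels:
            self.units.setdefault(name, DEFAULT_UNITS.get(name, "a.u."))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]
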