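"""Challenge scripts: the timed sequence of autoregulation challenges.

A recording session is described by an ordered list of labelled epochs
(PEEP steps, graded hemorrhages, CO2 inhalation, an anesthesia transition,
and a terminal bleed), each with a challenge window and a baseline window
immediately preceding it.  The canonical script reproduces the 16-challenge
sequence of the porcine PEEP/hemorrhage experiment this package models:
an anesthesia transition, three PEEP series (10/15/20 cmH2O) interleaved
with three 15%-blood-volume bleeds, one CO2 inhalation, a fourth PEEP 10,
and a lethal bleed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence


class ChallengeKind(str, Enum):
    PEEP = "peep"
    HEMORRHAGE = "hemorrhage"
    CO2 = "co2"
    ANESTHESIA_TRANSITION = "anesthesia_transition"
    LETHAL = "lethal"


@dataclass(frozen=True)
class ChallengeEpoch:
    """One labelled challenge.

    magnitude is in cmH2O for PEEP epochs and in fraction of estimated
    blood volume for hemorrhage/lethal epochs; unused otherwise.
    baseline_window is a (t0, t1) interval ending at or before t_start.
    """

    label: str
    kind: ChallengeKind
    magnitude: float
    t_start: float
    t_end: float
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"epoch {self.label!r}: t_start must precede t_end")
        b0, b1 = self.baseline_window
        if not b0 < b1:
            raise ValueError(f"epoch {self.label!r}: empty baseline window")
        if b1 > self.t_start + 1e-9:
            raise ValueError(
                f"epoch {self.label!r}: baseline window must end at or before t_start"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ChallengeScript:
    epochs: tuple[ChallengeEpoch, ...]
    total_duration: float

    def __post_init__(self) -> None:
        prev_end = -float("inf")
        for ep in self.epochs:
            if ep.t_start < prev_end - 1e-9:
                raise ValueError(f"epoch {ep.label!r} overlaps its predecessor")
            prev_end = ep.t_end
        if self.epochs and self.epochs[-1].t_end > self.total_duration + 1e-9:
            raise ValueError("total_duration shorter than last epoch")

    def __len__(self) -> int:
        return len(self.epochs)

    def by_kind(self, kind: ChallengeKind) -> tuple[ChallengeEpoch, ...]:
        return tuple(ep for ep in self.epochs if ep.kind == kind)


@dataclass(frozen=True)
class ARProfile:
    """Simulator ground truth: per-epoch active/passive autoregulation flag.

    ``active[i]`` is True when, during epoch i, the cranial channels (ICP,
    REG pulse amplitude, carotid-flow pulse amplitude) respond with the
    *opposite* sign to the systemic-pressure change (intact autoregulation);
    False means they passively follow pressure.  ``coupling_gain`` scales
    the slow-wave coupling from systemic pressure into the cranial channels.
    """

    active: tuple[bool, ...]
    coupling_gain: float = 1.0

    @staticmethod
    def all_active(script: ChallengeScript, coupling_gain: float = 1.0) -> "ARProfile":
        return ARProfile((True,) * len(script), coupling_gain)

    @staticmethod
    def all_passive(script: ChallengeScript, coupling_gain: float = 1.0) -> "ARProfile":
        return ARProfile((False,) * len(script), coupling_gain)

    @staticmethod
    def staged(script: ChallengeScript, passive_from_label: str = "hemorrhage 2",
               coupling_gain: float = 1.0) -> "ARProfile":
        """Active until (exclusive) the named epoch, passive from it onward.

        Mirrors the experiment's course: autoregulation intact through the
        first bleed, lost after the second.
        """
        labels = [ep.label for ep in script.epochs]
        if passive_from_label not in labels:
            raise ValueError(f"label {passive_from_label!r} not in script")
        k = labels.index(passive_from_label)
        return ARProfile(tuple(i < k for i in range(len(script))), coupling_gain)

    def validate_against(self, script: ChallengeScript) -> None:
        if len(self.active) != len(script):
            raise ValueError("profile length does not match script")


@dataclass(frozen=True)
class ScriptConfig:
    """Timing parameters for :func:`build_challenge_script`.

    Durations are seconds.  The default values give the canonical ~4.1 h
    session (PEEP steps of about 8 minutes); :meth:`compact` shrinks every
    epoch and gap so the whole session fits in ~1 h-equivalent simulated
    time for tests and examples.
    """

    bleed_fraction: float = 0.15
    peep_levels: tuple[float, float, float] = (10.0, 15.0, 20.0)
    lead_in: float = 600.0          # quiet baseline before the first epoch
    peep_duration: float = 480.0
    hemorrhage_duration: float = 480.0
    co2_duration: float = 300.0
    transition_duration: float = 300.0
    lethal_duration: float = 480.0
    gap: float = 300.0              # recovery+baseline interval between epochs
    baseline_length: float = 240.0  # trailing part of each gap used as baseline
    tail: float = 120.0

    def compact(self) -> "ScriptConfig":
        return replace(
            self,
            lead_in=420.0,
            peep_duration=90.0,
            hemorrhage_duration=90.0,
            co2_duration=90.0,
            transition_duration=90.0,
            lethal_duration=90.0,
            gap=120.0,
            baseline_length=60.0,
            tail=60.0,
        )


_CANONICAL_ORDER: tuple[tuple[str, ChallengeKind], ...] = (
    ("iso-prop transit", ChallengeKind.ANESTHESIA_TRANSITION),
    ("PEEP 10 (1)", ChallengeKind.PEEP),
    ("PEEP 15 (1)", ChallengeKind.PEEP),
    ("PEEP 20 (1)", ChallengeKind.PEEP),
    ("hemorrhage 1", ChallengeKind.HEMORRHAGE),
    ("PEEP 10 (2)", ChallengeKind.PEEP),
    ("PEEP 15 (2)", ChallengeKind.PEEP),
    ("PEEP 20 (2)", ChallengeKind.PEEP),
    ("CO2 inhalation", ChallengeKind.CO2),
    ("hemorrhage 2", ChallengeKind.HEMORRHAGE),
    ("PEEP 10 (3)", ChallengeKind.PEEP),
    ("PEEP 15 (3)", ChallengeKind.PEEP),
    ("PEEP 20 (3)", ChallengeKind.PEEP),
    ("hemorrhage 3", ChallengeKind.HEMORRHAGE),
    ("PEEP 10 (4)", ChallengeKind.PEEP),
    ("lethal bleeding", ChallengeKind.LETHAL),
)


def build_challenge_script(
    config: ScriptConfig | None = None,
    order: Sequence[tuple[str, ChallengeKind]] | None = None,
) -> ChallengeScript:
    """Assemble a time-ordered challenge script.

    With the default (canonical) order this returns the 16-epoch sequence of
    the modelled experiment: the anesthesia transition, three PEEP series at
    10/15/20 cmH2O bracketing three 15% bleeds, a CO2 inhalation, a final
    PEEP 10, and the lethal bleed.  Pass ``order=[]`` for an empty script.
    """
    cfg = config or ScriptConfig()
    seq = _CANONICAL_ORDER if order is None else tuple(order)
    durations = {
        ChallengeKind.PEEP: cfg.peep_duration,
        ChallengeKind.HEMORRHAGE: cfg.hemorrhage_duration,
        ChallengeKind.CO2: cfg.co2_duration,
        ChallengeKind.ANESTHESIA_TRANSITION: cfg.transition_duration,
        ChallengeKind.LETHAL: cfg.lethal_duration,
    }
    if cfg.baseline_length > cfg.gap:
        raise ValueError("baseline_length cannot exceed the inter-epoch gap")
    n_peep = 0
    epochs: list[ChallengeEpoch] = []
    t = cfg.lead_in
    for label, kind in seq:
        if kind == ChallengeKind.PEEP:
            mag = cfg.peep_levels[n_peep % len(cfg.peep_levels)]
            n_peep += 1
        elif kind in (ChallengeKind.HEMORRHAGE, ChallengeKind.LETHAL):
            mag = cfg.bleed_fraction
        else:
            mag = 0.0
        dur = durations[kind]
        epochs.append(
            ChallengeEpoch(
                label=label,
                kind=kind,
                magnitude=mag,
                t_start=t,
                t_end=t + dur,
                baseline_window=(t - cfg.baseline_length, t),
            )
        )
        t += dur + cfg.gap
    total = (epochs[-1].t_end + cfg.tail) if epochs else 0.0
    return ChallengeScript(epochs=tuple(epochs), total_duration=total)
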