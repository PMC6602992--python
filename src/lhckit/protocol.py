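"""Light protocols for PAM state-transition induction.

A protocol is an ordered list of timed events: measuring light on
(``ML_ON``), actinic light on (``AL_ON``), far-red light switches
(``FR_ON`` / ``FR_OFF``) and saturating pulses (``SP``).  A state
transition *cycle* is one far-red off/on excursion: LHCII migrates to
PSI while far red is off (State II) and returns once far red is
restored (State I).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

EVENT_KINDS = ("ML_ON", "AL_ON", "FR_ON", "FR_OFF", "SP")


class ProtocolError(ValueError):
    """Raised when a light protocol is malformed or incomplete."""


@dataclass(frozen=True)
class LightEvent:
    time_s: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ProtocolError(f"unknown event kind {self.kind!r}")
        if not (self.time_s == self.time_s):  # NaN guard
            raise ProtocolError("event time is NaN")


@dataclass
class LightProtocol:
    """Timed illumination schedule driving a fluorescence trace.

    Parameters
    ----------
    events
        Time-ordered events (strictly increasing times).
    pulse_s
        Duration of the saturating-pulse plateau, seconds.
    """

    events: list[LightEvent] = field(default_factory=list)
    pulse_s: float = 0.8

    def __post_init__(self) -> None:
        self.events = [
            e if isinstance(e, LightEvent) else LightEvent(*e) for e in self.events
        ]
        times = [e.time_s for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ProtocolError("event times must be strictly increasing")
        if self.pulse_s <= 0:
            raise ProtocolError("pulse_s must be positive")
        for t in self.sp_times:
            for s in self.times_of("FR_ON") + self.times_of("FR_OFF"):
                if t <= s < t + self.pulse_s:
                    raise ProtocolError(
                        f"SP at t={t} s overlaps FR switch at t={s} s"
                    )

    # -- convenience accessors -------------------------------------------------

    def times_of(self, kind: str) -> list[float]:
        return [e.time_s for e in self.events if e.kind == kind]

    @property
    def sp_times(self) -> list[float]:
        return self.times_of("SP")

    @property
    def cycles(self) -> list[tuple[float, float]]:
        """(FR_OFF, next FR_ON) pairs, one per state-transition cycle."""
        offs = self.times_of("FR_OFF")
        ons = self.times_of("FR_ON")
        pairs = []
        for t_off in offs:
            later = [t for t in ons if t > t_off]
            if later:
                pairs.append((t_off, min(later)))
        return pairs

    def fr_is_on(self, t: float) -> bool:
        """Far-red state at time ``t``.

        Dark-adapted material is treated as State I, so far red counts
        as "on" (oxidised PQ pool) outside explicit FR_OFF..FR_ON spans.
        """
        for t_off, t_on in self.cycles:
            if t_off <= t < t_on:
                return False
        # an FR_OFF without a closing FR_ON keeps FR off to the end
        offs = self.times_of("FR_OFF")
        ons = self.times_of("FR_ON")
        if offs and t >= offs[-1] and not any(x > offs[-1] for x in ons):
            return False
        return True

    def validate_for_analysis(self, n_cycles: int = 1) -> None:
        if not self.times_of("ML_ON"):
            raise ProtocolError("protocol has no ML_ON event")
        if not self.times_of("AL_ON"):
            raise ProtocolError("protocol has no AL_ON event")
        if len(self.cycles) < n_cycles:
            raise ProtocolError(
                f"protocol has {len(self.cycles)} full FR off/on cycle(s); "
                f"{n_cycles} required"
            )

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pulse_s": self.pulse_s,
            "events": [{"t_s": e.time_s, "event": e.kind} for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightProtocol":
        events = [LightEvent(ev["t_s"], ev["event"]) for ev in d["events"]]
        return cls(events=events, pulse_s=d.get("pulse_s", 0.8))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "LightProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_protocol(
    fr_interval_s: float = 900.0,
    induction_s: float = 120.0,
    n_cycles: int = 2,
    sp_offset_s: float = 30.0,
    pulse_s: float = 0.8,
) -> LightProtocol:
    """Two-cycle far-red on/off induction schedule.

    Measuring light starts at t=0 with a dark-adapted saturating pulse at
    30 s; actinic plus far-red light start after ``induction_s``; far red
    is then switched off/on in ``fr_interval_s`` intervals for
    ``n_cycles`` cycles.  Saturating pulses are placed ``sp_offset_s``
    after each switch and before the next, revealing Fm' in either state.
    """
    events: list[tuple[float, str]] = [(0.0, "ML_ON"), (30.0, "SP")]
    t_al = induction_s
    events.append((t_al, "AL_ON"))
    events.append((t_al + 0.5, "FR_ON"))
    # switch times: FR goes off/on every fr_interval_s after induction
    switches = [t_al + (k + 1) * fr_interval_s for k in range(2 * n_cycles)]
    boundaries = [t_al + 0.5] + switches + [switches[-1] + fr_interval_s]
    for i, t in enumerate(switches):
        events.append((t, "FR_OFF" if i % 2 == 0 else "FR_ON"))
    # SPs 30 s after each segment start and 30 s before each segment end
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        events.append((t0 + sp_offset_s, "SP"))
        events.append((t1 - sp_offset_s, "SP"))
    events = sorted(set(events))
    return LightProtocol(
        events=[LightEvent(t, k) for t, k in events], pulse_s=pulse_s
    )


def protocol_span(protocol: LightProtocol, tail_s: float = 30.0) -> float:
    """Recording length needed to cover the protocol plus a tail."""
    return max(e.time_s for e in protocol.events) + tail_s
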