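"""State-transition statistics from PAM chlorophyll fluorescence traces.

The analysis locates fluorescence landmarks on a trace driven by a
far-red on/off induction protocol and computes three statistics:

* ``IB = (FsI' - FsI) / Fo`` — energy imbalance on far-red removal,
  i.e. the fractional steady-state fluorescence rise when PSI excitation
  is withdrawn and the PQ pool becomes reduced.
* ``qT = (FmI' - FmII') / FmI'`` — the relative drop in light-adapted
  maximal fluorescence between State I and State II, reflecting the
  change in PSII absorption cross-section as mobile LHCII leaves PSII.
* ``qS = (FsI' - FsII') / (FsI' - FsII)`` — how completely the steady
  state fluorescence relaxes back, i.e. how fully the state transition
  rebalances energy flow between the photosystems (1 = complete).

Values are reported unclipped: biological replicates can legitimately
exceed the nominal ranges (qT 0–0.25, qS 0–1) and such results are
flagged, not altered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import LightProtocol, ProtocolError


class TraceError(ValueError):
    """Raised for malformed traces or unusable landmark windows."""


@dataclass
class FluorescenceTrace:
    """A fluorescence time series F(t) in arbitrary units."""

    time_s: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.shape != self.fluorescence.shape or self.time_s.ndim != 1:
            raise TraceError("time and fluorescence must be equal-length 1-D")
        if self.time_s.size < 2:
            raise TraceError("trace needs at least two samples")
        if not np.all(np.diff(self.time_s) > 0):
            raise TraceError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.fluorescence))):
            raise TraceError("trace contains non-finite values")

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_s": self.time_s, "fluorescence": self.fluorescence}
        ).to_csv(path, index=False)


def read_trace(path: str | Path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "fluorescence"} - set(df.columns)
    if missing:
        raise TraceError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise TraceError(f"{path}: empty trace file")
    return FluorescenceTrace(df["time_s"].to_numpy(), df["fluorescence"].to_numpy())


def read_protocol(path: str | Path) -> LightProtocol:
    return LightProtocol.read_json(path)


# -- landmark machinery --------------------------------------------------------


def detect_pulses(
    trace: FluorescenceTrace, protocol: LightProtocol
) -> list[tuple[float, float]]:
    """Saturating-pulse plateau values: (SP time, max F within the pulse
    window [t, t + pulse duration])."""
    out = []
    t, f = trace.time_s, trace.fluorescence
    for t_sp in protocol.sp_times:
        if t_sp < t[0] or t_sp + protocol.pulse_s > t[-1]:
            raise TraceError(
                f"SP window [{t_sp}, {t_sp + protocol.pulse_s}] s outside "
                f"trace span [{t[0]}, {t[-1]}] s"
            )
        sel = (t >= t_sp) & (t <= t_sp + protocol.pulse_s)
        if not sel.any():
            raise TraceError(f"no samples inside SP window at t={t_sp} s")
        out.append((t_sp, float(f[sel].max())))
    return out


@dataclass
class Landmarks:
    """Named fluorescence levels with the windows they were read from.

    Window semantics (w = steady-state window, w_spike = transient
    search window, both seconds): FsI is the pre-FR-off steady state,
    FsI' the post-FR-off maximum, FsII' the end-of-FR-off steady state,
    FsII the post-FR-restoration minimum ("dip"); FmI/FmII are the
    saturating-pulse plateaus closest before the FR-off and FR-on
    switches (light-adapted Fm', State I and State II respectively).
    """

    fo: float
    fm: float
    fs_i: float
    fs_i_prime: float
    fs_ii_prime: float
    fs_ii: float
    fm_i: float
    fm_ii: float
    windows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fm < self.fo:
            warnings.warn("Fm < Fo: trace may be inverted or mislabelled")
        if self.fs_i_prime < self.fs_i:
            warnings.warn(
                "FsI' < FsI: no fluorescence rise on FR removal "
                "(unresponsive leaf?)"
            )

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "fo", "fm", "fs_i", "fs_i_prime", "fs_ii_prime",
                "fs_ii", "fm_i", "fm_ii",
            )
        }
        d["windows"] = {k: list(v) for k, v in self.windows.items()}
        return d


def _masked_smooth(
    t: np.ndarray, f: np.ndarray, valid: np.ndarray, smooth_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar mean of the valid samples within +-smooth_s/2 of each
    sample time; returns (smoothed, has_support)."""
    if smooth_s <= 0:
        out = np.where(valid, f, np.nan)
        return out, valid.copy()
    half = smooth_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    fv = np.where(valid, f, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(fv)])
    ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
    counts = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        sm = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), np.nan)
    return sm, counts > 0


def extract_landmarks(
    trace: FluorescenceTrace,
    protocol: LightProtocol,
    cycle: int = 2,
    w: float = 30.0,
    w_spike: float = 60.0,
    smooth_s: float = 15.0,
    sp_pad_s: float = 2.0,
) -> Landmarks:
    """Locate all landmark fluorescence levels for one FR off/on cycle.

    The second cycle is analysed by default so that dark-to-light
    induction kinetics from the first cycle do not contaminate the
    steady states.  Steady-state landmarks are means over ``w``-second
    windows ending at the switch; transient landmarks (FsI', FsII) are
    extrema of a lightly smoothed trace within ``w_spike`` seconds after
    the switch.  Saturating-pulse windows (padded by ``sp_pad_s``) are
    excluded everywhere.
    """
    protocol.validate_for_analysis(n_cycles=1)
    cycles = protocol.cycles
    if not 1 <= cycle <= len(cycles):
        raise ProtocolError(
            f"cycle {cycle} not found (protocol has {len(cycles)} cycle(s))"
        )
    t_off, t_on = cycles[cycle - 1]
    t, f = trace.time_s, trace.fluorescence

    valid = np.ones(t.size, dtype=bool)
    for t_sp in protocol.sp_times:
        valid &= ~((t >= t_sp - 0.5) & (t <= t_sp + protocol.pulse_s + sp_pad_s))

    def window_mean(t0: float, t1: float, name: str) -> float:
        # half-open [t0, t1): pre-switch steady states must not include
        # the switch instant, where the signal has already jumped
        sel = (t >= t0) & (t < t1) & valid
        if not sel.any():
            raise TraceError(f"no usable samples in {name} window [{t0}, {t1}] s")
        return float(f[sel].mean())

    sm, support = _masked_smooth(t, f, valid, smooth_s)

    def window_extremum(t0: float, t1: float, name: str, kind: str) -> float:
        sel = (t >= t0) & (t <= t1) & support & valid
        if not sel.any():
            raise TraceError(f"no usable samples in {name} window [{t0}, {t1}] s")
        return float(sm[sel].max() if kind == "max" else sm[sel].min())

    al_on = protocol.times_of("AL_ON")[0]
    sp_times = sorted(protocol.sp_times)
    if not sp_times:
        raise TraceError("protocol has no saturating pulses")
    plateaus = dict(detect_pulses(trace, protocol))

    def plateau_before(t_switch: float, after: float, name: str) -> float:
        candidates = [s for s in sp_times if after <= s < t_switch]
        if not candidates:
            raise TraceError(
                f"no saturating pulse before {name} switch at t={t_switch} s"
            )
        return plateaus[max(candidates)]

    lm = Landmarks(
        fo=window_mean(al_on - w, al_on, "Fo"),
        fm=plateaus[sp_times[0]],
        fs_i=window_mean(t_off - w, t_off, "FsI"),
        fs_i_prime=window_extremum(t_off, t_off + w_spike, "FsI'", "max"),
        fs_ii_prime=window_mean(t_on - w, t_on, "FsII'"),
        fs_ii=window_extremum(t_on, t_on + w_spike, "FsII", "min"),
        fm_i=plateau_before(t_off, al_on, "FR_OFF"),
        fm_ii=plateau_before(t_on, t_off, "FR_ON"),
        windows={
            "fo": (al_on - w, al_on),
            "fm": (sp_times[0], sp_times[0] + protocol.pulse_s),
            "fs_i": (t_off - w, t_off),
            "fs_i_prime": (t_off, t_off + w_spike),
            "fs_ii_prime": (t_on - w, t_on),
            "fs_ii": (t_on, t_on + w_spike),
        },
    )
    return lm


# -- the three statistics ------------------------------------------------------


def compute_ib(lm: Landmarks) -> float:
    """Energy imbalance on FR removal: (FsI' - FsI) / Fo."""
    if lm.fo <= 0:
        raise ValueError(f"Fo must be positive, got {lm.fo}")
    return (lm.fs_i_prime - lm.fs_i) / lm.fo


def compute_qt(lm: Landmarks) -> float:
    """PSII cross-section change: (FmI' - FmII') / FmI'."""
    if lm.fm_i <= 0:
        raise ValueError(f"FmI must be positive, got {lm.fm_i}")
    return (lm.fm_i - lm.fm_ii) / lm.fm_i


def compute_qs(lm: Landmarks, denom_tol: float = 1e-9) -> float:
    """Rebalancing completeness: (FsI' - FsII') / (FsI' - FsII).

    A degenerate denominator (|FsI' - FsII| below ``denom_tol``) yields
    NaN with a warning; callers flag it rather than silently propagate.
    """
    denom = lm.fs_i_prime - lm.fs_ii
    if abs(denom) < denom_tol:
        warnings.warn(
            f"qS denominator FsI' - FsII = {denom:.3g} is degenerate"
        )
        return float("nan")
    return (lm.fs_i_prime - lm.fs_ii_prime) / denom


@dataclass
class StateTransitionResult:
    landmarks: Landmarks
    ib: float
    qt: float
    qs: float
    cycle: int
    flags: list[str] = field(default_factory=list)

    @property
    def ib_pct(self) -> float:
        return 100.0 * self.ib

    @property
    def qt_pct(self) -> float:
        return 100.0 * self.qt

    @property
    def qs_pct(self) -> float:
        return 100.0 * self.qs

    def to_dict(self) -> dict:
        return {
            "cycle": self.cycle,
            "ib": self.ib,
            "qt": self.qt,
            "qs": self.qs,
            "ib_pct": self.ib_pct,
            "qt_pct": self.qt_pct,
            "qs_pct": self.qs_pct,
            "flags": list(self.flags),
            "landmarks": self.landmarks.to_dict(),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def analyze_trace(
    trace: FluorescenceTrace,
    protocol: LightProtocol,
    cycle: int = 2,
    **landmark_kwargs,
) -> StateTransitionResult:
    """Full analysis: landmarks then IB, qT, qS, with nominal-range flags."""
    lm = extract_landmarks(trace, protocol, cycle=cycle, **landmark_kwargs)
    flags: list[str] = []
    ib = compute_ib(lm)
    qt = compute_qt(lm)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        qs = compute_qs(lm)
    if any("degenerate" in str(c.message) for c in caught):
        flags.append("qs_degenerate")
    if not 0.0 <= qt <= 0.25:
        flags.append("qt_out_of_nominal_range")
    if qs == qs and not 0.0 <= qs <= 1.0:
        flags.append("qs_out_of_nominal_range")
    if ib < 0:
        flags.append("ib_negative")
    return StateTransitionResult(
        landmarks=lm, ib=ib, qt=qt, qs=qs, cycle=cycle, flags=flags
    )


def batch_table(results: dict[str, StateTransitionResult]) -> pd.DataFrame:
    """Flat per-sample table of the three statistics (fraction and %)."""
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "sample": label,
                "ib": r.ib,
                "qt": r.qt,
                "qs": r.qs,
                "ib_pct": r.ib_pct,
                "qt_pct": r.qt_pct,
                "qs_pct": r.qs_pct,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
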