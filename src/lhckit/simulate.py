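"""Synthetic inputs with known ground truth for every analyzer.

The fluorescence simulator is a deliberately minimal phenomenological
model of LHCII migration, built so the PAM analyzer can be tested
against closed-form truth, not a mechanistic photosynthesis model:

* x(t) in [0, 1] is the fraction of mobile LHCII attached to PSII and
  relaxes as dx/dt = (x_target - x)/tau_st, with x_target = 1 while far
  red is on (oxidised PQ pool, State I) and x_target = 1 - st_capacity
  while it is off.  ``st_capacity`` is the fraction of antenna able to
  migrate: 1 reproduces a wild-type-like response, 0 a cybrid-like flat
  response in which qT and qS vanish.
* the PSII cross-section is sigma(t) = sigma_min + (sigma_max -
  sigma_min) * x(t); steady-state fluorescence is Fo scaled by
  sigma(t)/sigma(0) plus an energy-imbalance term ``imbalance_gain *
  u(t)`` where the PQ-reduction proxy u(t) is x(t) during far-red-off
  periods and 0 otherwise.
* saturating pulses replace the signal by fm_level * sigma(t)/sigma(0)
  for the pulse duration (only the plateau is consumed downstream).

Because every segment of the ODE solution is a single exponential, all
landmark values have closed forms, giving exact expectations for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gel import LaneProfile
from .pam import FluorescenceTrace
from .proteins import AMINO_ACIDS, ProteinRecord
from .protocol import LightProtocol, default_protocol, protocol_span
from .spectra import EmissionSpectrum77K


# -- fluorescence traces -------------------------------------------------------


@dataclass
class SimPlantParams:
    """Ground-truth parameters of one simulated plant phenotype."""

    sigma_min: float = 0.89  # relative PSII cross-section, full State II
    sigma_max: float = 1.0  # relative PSII cross-section, State I
    st_capacity: float = 1.0  # mobile LHCII fraction; 0 = cybrid-like
    tau_st: float = 120.0  # state-transition time constant, s
    fo_level: float = 0.2  # dark-adapted minimal fluorescence, a.u.
    fm_level: float = 1.0  # dark-adapted maximal fluorescence, a.u.
    imbalance_gain: float = 0.112  # Fs rise per unit PQ-reduction proxy
    noise_sd: float = 0.005  # additive Gaussian noise SD, a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError("need 0 < sigma_min <= sigma_max")
        if not 0.0 <= self.st_capacity <= 1.0:
            raise ValueError("st_capacity must be in [0, 1]")
        if self.tau_st <= 0:
            raise ValueError("tau_st must be positive")
        if not 0 <= self.fo_level < self.fm_level:
            raise ValueError("need 0 <= fo_level < fm_level")
        if self.noise_sd < 0 or self.imbalance_gain < 0:
            raise ValueError("noise_sd and imbalance_gain must be >= 0")


def wildtype_params(seed: int = 0, **overrides) -> SimPlantParams:
    """Transition-competent phenotype (full mobile antenna)."""
    return SimPlantParams(st_capacity=1.0, seed=seed, **overrides)


def cybrid_params(seed: int = 0, **overrides) -> SimPlantParams:
    """Transition-incompetent phenotype: no LHCII migrates, the
    steady-state fluorescence stays elevated after FR removal."""
    return SimPlantParams(st_capacity=0.0, seed=seed, **overrides)


def _lhcii_fraction(
    t: np.ndarray, protocol: LightProtocol, params: SimPlantParams
) -> np.ndarray:
    """Piecewise-exponential solution of the relaxation ODE on the
    sample grid (exact per segment, no numerical integration)."""
    switches = sorted(
        protocol.times_of("FR_OFF") + protocol.times_of("FR_ON")
    )
    bounds = [t[0]] + [s for s in switches if t[0] < s <= t[-1]] + [np.inf]
    x = np.empty_like(t)
    x0 = 1.0  # dark-adapted leaves start in State I
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        target = 1.0 if protocol.fr_is_on(t0) else 1.0 - params.st_capacity
        sel = (t >= t0) & (t < t1)
        x[sel] = target + (x0 - target) * np.exp(-(t[sel] - t0) / params.tau_st)
        if t1 is not np.inf and np.isfinite(t1):
            x0 = target + (x0 - target) * np.exp(-(t1 - t0) / params.tau_st)
    return x


def simulate_trace(
    protocol: LightProtocol | None = None,
    params: SimPlantParams | None = None,
    dt_s: float = 0.5,
) -> FluorescenceTrace:
    """Simulate a PAM fluorescence trace under an induction protocol."""
    protocol = protocol if protocol is not None else default_protocol()
    params = params if params is not None else SimPlantParams()
    if dt_s <= 0:
        raise ValueError("sampling interval must be positive")
    sp = sorted(protocol.sp_times)
    for t1, t2 in zip(sp, sp[1:]):
        if t2 < t1 + protocol.pulse_s:
            raise ValueError(f"overlapping SP events at t={t1} and t={t2} s")

    t_end = protocol_span(protocol)
    t = np.arange(0.0, t_end + dt_s / 2, dt_s)
    x = _lhcii_fraction(t, protocol, params)
    sigma = params.sigma_min + (params.sigma_max - params.sigma_min) * x
    sigma_rel = sigma / sigma[0]

    fr_off_spans = protocol.cycles
    u = np.zeros_like(t)
    for t_off, t_on in fr_off_spans:
        sel = (t >= t_off) & (t < t_on)
        u[sel] = x[sel]

    f = params.fo_level * sigma_rel + params.imbalance_gain * u
    ml_on = protocol.times_of("ML_ON")[0]
    f[t < ml_on] = 0.0  # no measuring light, no signal
    for t_sp in sp:
        sel = (t >= t_sp) & (t <= t_sp + protocol.pulse_s)
        f[sel] = params.fm_level * sigma_rel[sel]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f + rng.normal(0.0, params.noise_sd, size=f.size)
    return FluorescenceTrace(time_s=t, fluorescence=f)


# -- 77 K spectra --------------------------------------------------------------


@dataclass
class SimSpectrumParams:
    """Three-Gaussian emission model: PSII core (685 nm), PSII vibronic
    shoulder (695 nm) and PSI (735 nm)."""

    centers_nm: tuple[float, float, float] = (685.0, 695.0, 735.0)
    widths_nm: tuple[float, float, float] = (8.0, 9.0, 16.0)
    amplitudes: tuple[float, float, float] = (1.0, 0.45, 0.8)
    psi_boost_state2: float = 1.5  # 735 nm amplitude factor in State II
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if self.psi_boost_state2 < 1.0:
            raise ValueError("psi_boost_state2 must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_spectrum_77k(
    state: str,
    params: SimSpectrumParams | None = None,
    wavelength_nm: np.ndarray | None = None,
) -> EmissionSpectrum77K:
    """Simulate one 77 K emission spectrum for State I or State II."""
    params = params if params is not None else SimSpectrumParams()
    if state not in ("I", "II"):
        raise ValueError("state must be 'I' or 'II'")
    wl = (
        np.arange(600.0, 800.0 + 0.5, 1.0)
        if wavelength_nm is None
        else np.asarray(wavelength_nm, dtype=float)
    )
    if wl[0] > 685.0 or wl[-1] < 735.0:
        raise ValueError("wavelength grid must cover both 685 and 735 nm")
    amps = list(params.amplitudes)
    if state == "II":
        amps[2] *= params.psi_boost_state2
    y = np.zeros_like(wl)
    for a, c, w in zip(amps, params.centers_nm, params.widths_nm):
        y += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    if params.noise_sd > 0:
        rng = np.random.default_rng(
            params.seed + (1 if state == "II" else 0)
        )
        y = y + rng.normal(0.0, params.noise_sd, size=y.size)
    return EmissionSpectrum77K(wavelength_nm=wl, intensity=y, state=state)


# -- gel lanes -----------------------------------------------------------------


@dataclass
class SimLaneParams:
    """Gaussian-band lane model with a log-linear migration map."""

    # (true MW kDa, relative amount) pairs; defaults emulate a 7-band
    # LHC separation in the 20-26 kDa region
    bands: tuple = (
        (25.1, 35.1),
        (24.6, 20.6),
        (23.9, 9.4),
        (23.6, 17.8),
        (23.1, 7.3),
        (22.2, 4.5),
        (20.7, 5.2),
    )
    band_width_mm: float = 0.25  # Gaussian SD of one band
    marker_mws_kda: tuple = (32.0, 25.0, 22.0, 17.0, 11.0)
    slope_mm_per_decade: float = -180.0  # distance per log10(MW)
    mw_ref_kda: float = 25.0
    distance_ref_mm: float = 20.0
    baseline_slope: float = 0.0  # density units per mm
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    grid_step_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(mw <= 0 for mw, _ in self.bands) or any(
            m <= 0 for m in self.marker_mws_kda
        ):
            raise ValueError("molecular weights must be positive")
        if self.slope_mm_per_decade >= 0:
            raise ValueError(
                "slope must be negative: larger proteins migrate less"
            )
        if self.band_width_mm <= 0 or self.grid_step_mm <= 0:
            raise ValueError("band width and grid step must be positive")

    def distance_of(self, mw_kda: float) -> float:
        """The generating migration map (inverse of the calibration)."""
        return self.distance_ref_mm + self.slope_mm_per_decade * (
            np.log10(mw_kda) - np.log10(self.mw_ref_kda)
        )


def cybrid_lane_bands() -> tuple:
    """8-band comparison-lane preset including a novel mid-MW band."""
    return (
        (25.0, 20.4),
        (24.7, 17.2),
        (23.7, 25.4),
        (23.3, 13.7),
        (22.9, 6.1),
        (22.6, 6.7),
        (21.9, 7.5),
        (20.6, 3.0),
    )


def simulate_lane(
    params: SimLaneParams | None = None,
) -> tuple[LaneProfile, LaneProfile]:
    """Simulate (sample lane, marker lane) density profiles.

    Band centres are placed by the log-linear migration map; each band
    is a Gaussian whose integrated area equals its relative amount; a
    linear baseline and Gaussian noise are added to the sample lane.
    """
    params = params if params is not None else SimLaneParams()
    centres = [params.distance_of(mw) for mw, _ in params.bands]
    marker_centres = [params.distance_of(mw) for mw in params.marker_mws_kda]
    d_max = max(centres + marker_centres) + 8.0
    d = np.arange(0.0, d_max, params.grid_step_mm)

    def gaussians(centre_amounts) -> np.ndarray:
        y = np.zeros_like(d)
        w = params.band_width_mm
        for c, amount in centre_amounts:
            y += (
                amount
                / (w * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((d - c) / w) ** 2)
            )
        return y

    sample = gaussians(
        [(c, amount) for c, (_, amount) in zip(centres, params.bands)]
    )
    sample = sample + params.baseline_offset + params.baseline_slope * d
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        sample = sample + rng.normal(0.0, params.noise_sd, size=sample.size)
    marker = gaussians([(c, 1.0) for c in marker_centres])
    return (
        LaneProfile(d.copy(), sample, label="sample"),
        LaneProfile(d.copy(), marker, label="marker"),
    )


# -- lhcb-like sequences -------------------------------------------------------

# base composition (relative weights) biased towards acidic residues so
# that generated mature proteins land in the pI 4.5-5.5 window typical
# of LHC apoproteins; residue order is randomised but the composition is
# held near-fixed so the pI does not wander
_COMPOSITION = {
    "A": 9, "D": 7, "E": 7, "F": 4, "G": 8, "I": 4, "L": 8, "N": 4,
    "P": 5, "Q": 3, "S": 6, "T": 5, "V": 6, "W": 2, "Y": 3, "K": 6,
    "R": 5, "H": 1, "M": 2, "C": 1,
}


def _composition_counts(n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` residues to the base
    composition (exact total, deterministic)."""
    total = sum(_COMPOSITION.values())
    raw = {aa: n * w / total for aa, w in _COMPOSITION.items()}
    counts = {aa: int(v) for aa, v in raw.items()}
    short = n - sum(counts.values())
    for aa in sorted(raw, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[aa] += 1
    return counts


def make_lhcb_like_sequence(
    length: int = 232, seed: int = 0, transit_length: int = 0
) -> ProteinRecord:
    """Generate a mature LHCII-apoprotein-like sequence.

    The mature chain starts Arg-X-Thr — an arginine at mature position 1
    and the state-transition phospho-threonine at position 3 — with an
    acidic-biased composition (shuffled per seed, plus a small random
    acidic-count jitter).  ``transit_length`` residues of a
    serine/threonine-rich transit peptide may be prepended; deterministic
    per seed.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    counts = _composition_counts(length)
    counts["R"] = max(1, counts["R"])
    counts["T"] = max(1, counts["T"])
    # +-1 acidic residue of per-seed wobble, charge-compensated from A
    wobble = int(rng.integers(-1, 2))
    counts["D"] = max(0, counts["D"] + wobble)
    counts["A"] = max(0, counts["A"] - wobble)
    pool = [aa for aa, n in counts.items() for _ in range(n)]
    pool.remove("R")
    pool.remove("T")
    x = pool.pop(int(rng.integers(len(pool))))
    body = [pool[i] for i in rng.permutation(len(pool))]
    mature = "R" + x + "T" + "".join(body)
    mature = mature[:length]
    transit = ""
    if transit_length:
        transit_letters = np.array(list("MASTSLV"))
        transit = "M" + "".join(
            rng.choice(transit_letters, size=transit_length - 1)
        )
    return ProteinRecord(
        identifier=f"synthetic_lhcb_seed{seed}",
        sequence=transit + mature,
        transit_end=transit_length if transit_length else None,
        description="synthetic lhcb-like sequence (generated, not a real protein)",
    )
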