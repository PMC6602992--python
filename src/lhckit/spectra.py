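"""77 K fluorescence emission spectra: PSII-normalised PSI contribution.

At liquid-nitrogen temperature the emission of PSII (~685 nm, with a
~695 nm shoulder) and PSI (~735 nm) resolve into separate bands.  After
normalising a spectrum at the PSII maximum (685 nm), the height at
735 nm measures the relative PSI contribution; a State II spectrum of a
transition-competent plant shows an increased 735 nm band because
mobile LHCII has docked at PSI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


class SpectrumError(ValueError):
    pass


def smooth_savgol(
    spec: "EmissionSpectrum77K", window: int = 11, polyorder: int = 3
) -> "EmissionSpectrum77K":
    """Savitzky-Golay smoothing of the intensity vector.

    Off by default throughout the module; intended for noisy measured
    spectra before point-ratio reading, where single-pixel noise would
    otherwise dominate the F735/F685 comparison.
    """
    if window >= spec.intensity.size:
        raise SpectrumError("smoothing window longer than spectrum")
    return EmissionSpectrum77K(
        wavelength_nm=spec.wavelength_nm.copy(),
        intensity=savgol_filter(spec.intensity, window, polyorder),
        excitation_nm=spec.excitation_nm,
        state=spec.state,
        normalized_at=spec.normalized_at,
    )


@dataclass
class EmissionSpectrum77K:
    """Emission intensity on a wavelength grid covering 600-800 nm."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float = 435.0
    state: str = "unknown"  # "I", "II" or "unknown"
    normalized_at: float | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise SpectrumError("wavelength and intensity length mismatch")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("intensities must be finite")

    def value_at(self, lambda_nm: float) -> float:
        wl = self.wavelength_nm
        if not wl[0] <= lambda_nm <= wl[-1]:
            raise SpectrumError(
                f"{lambda_nm} nm outside measured range [{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(lambda_nm, wl, self.intensity))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelength_nm, "intensity": self.intensity}
        ).to_csv(path, index=False)


def read_spectrum(path: str | Path, state: str = "unknown") -> EmissionSpectrum77K:
    df = pd.read_csv(path)
    missing = {"wavelength_nm", "intensity"} - set(df.columns)
    if missing:
        raise SpectrumError(f"{path}: missing column(s) {sorted(missing)}")
    return EmissionSpectrum77K(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(), state=state
    )


def normalize_at(
    spec: EmissionSpectrum77K, lambda0: float = 685.0
) -> EmissionSpectrum77K:
    """Divide by the (interpolated) intensity at ``lambda0``.

    Idempotent and scale-invariant; the result has intensity exactly 1
    at ``lambda0``.
    """
    ref = spec.value_at(lambda0)
    if ref <= 0:
        raise SpectrumError(
            f"intensity at {lambda0} nm is {ref}; cannot normalise"
        )
    return EmissionSpectrum77K(
        wavelength_nm=spec.wavelength_nm.copy(),
        intensity=spec.intensity / ref,
        excitation_nm=spec.excitation_nm,
        state=spec.state,
        normalized_at=lambda0,
    )


def psi_ratio(spec: EmissionSpectrum77K, lambda_psi: float = 735.0) -> float:
    """Normalised intensity at the PSI band (F735/F685 by default)."""
    if spec.normalized_at is None:
        spec = normalize_at(spec)
    return spec.value_at(lambda_psi)


def compare_states(
    spec_i: EmissionSpectrum77K,
    spec_ii: EmissionSpectrum77K,
    threshold: float = 0.02,
    smooth: bool = False,
) -> dict:
    """State II minus State I PSI contribution after 685 nm normalisation.

    Returns ``delta_psi`` (F735/F685 difference) and ``increased``
    (True when the rise exceeds ``threshold``).  ``smooth`` applies
    Savitzky-Golay filtering before the ratio is read (recommended for
    noisy measured spectra).  Mismatched wavelength grids are resampled
    onto the State I grid with a warning.
    """
    if smooth:
        spec_i, spec_ii = smooth_savgol(spec_i), smooth_savgol(spec_ii)
    spec_i = normalize_at(spec_i) if spec_i.normalized_at is None else spec_i
    spec_ii = normalize_at(spec_ii) if spec_ii.normalized_at is None else spec_ii
    if spec_i.wavelength_nm.shape != spec_ii.wavelength_nm.shape or not np.allclose(
        spec_i.wavelength_nm, spec_ii.wavelength_nm
    ):
        warnings.warn("wavelength grids differ; resampling State II onto State I grid")
        spec_ii = EmissionSpectrum77K(
            spec_i.wavelength_nm.copy(),
            np.interp(
                spec_i.wavelength_nm, spec_ii.wavelength_nm, spec_ii.intensity
            ),
            state=spec_ii.state,
            normalized_at=spec_ii.normalized_at,
        )
    delta = psi_ratio(spec_ii) - psi_ratio(spec_i)
    return {"delta_psi": delta, "increased": bool(delta > threshold)}
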