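"""SDS-PAGE lane densitometry: band detection, MW calibration, matching.

A lane is a density-vs-migration-distance profile (the 1-D readout of a
stained gel lane).  Bands are local density maxima; their areas are
integrated valley-to-valley and expressed as percent of the total over
detected bands.  Apparent molecular weight follows the standard
log-linear gel calibration, log10(MW) = slope * distance + intercept,
fitted on a marker lane.  Cross-lane matching pairs bands of nearest MW
under a tolerance; unmatched comparison bands are flagged as novel, and
a delta-MW report against a chosen anchor band supports truncation-series
interpretation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


class GelError(ValueError):
    pass


@dataclass
class LaneProfile:
    """Density profile of one gel lane."""

    distance_mm: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.distance_mm.shape != self.density.shape:
            raise GelError("distance and density length mismatch")
        if not np.all(np.diff(self.distance_mm) > 0):
            raise GelError("distances must be strictly increasing")
        if not np.all(np.isfinite(self.density)):
            raise GelError("densities must be finite")

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"distance_mm": self.distance_mm, "density": self.density}
        ).to_csv(path, index=False)


def read_lane(path: str | Path, label: str = "") -> LaneProfile:
    df = pd.read_csv(path)
    missing = {"distance_mm", "density"} - set(df.columns)
    if missing:
        raise GelError(f"{path}: missing column(s) {sorted(missing)}")
    return LaneProfile(
        df["distance_mm"].to_numpy(), df["density"].to_numpy(), label=label
    )


@dataclass
class Band:
    apex_mm: float
    area: float
    percent_of_total: float = float("nan")
    mw_kda: float = float("nan")
    label: str = ""


@dataclass
class MarkerCalibration:
    """Least-squares fit of log10(MW/kDa) against migration distance."""

    slope: float  # d log10(MW) / d distance, must be negative
    intercept: float
    rms_residual: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def mw_at(self, distance_mm: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** (self.slope * np.asarray(distance_mm) + self.intercept)


# -- operations ---------------------------------------------------------------


def correct_baseline(
    profile: LaneProfile, method: str = "linear", window_mm: float = 5.0
) -> LaneProfile:
    """Subtract a baseline and clip negatives to zero.

    ``linear``: straight line fitted to lower-envelope anchor points
    (samples below the 10th percentile in each quarter of the lane plus
    the profile ends).  ``rolling_min``: rolling-minimum envelope of
    width ``window_mm``.
    """
    if profile.density.size < 10:
        raise GelError("profile too short for baseline correction")
    d, y = profile.distance_mm, profile.density
    if np.ptp(y) == 0:
        baseline = y.astype(float)
    elif method == "linear":
        anchors = []
        for seg in np.array_split(np.arange(d.size), 4):
            cut = np.percentile(y[seg], 10)
            anchors.extend(seg[y[seg] <= cut])
        anchors = np.unique(np.concatenate([anchors, [0, d.size - 1]]).astype(int))
        coef = np.polyfit(d[anchors], y[anchors], 1)
        baseline = np.polyval(coef, d)
    elif method == "rolling_min":
        step = np.median(np.diff(d))
        half = max(1, int(round(window_mm / (2 * step))))
        baseline = np.array(
            [y[max(0, i - half) : i + half + 1].min() for i in range(y.size)]
        )
    else:
        raise GelError(f"unknown baseline method {method!r}")
    corrected = np.clip(y - baseline, 0.0, None)
    return LaneProfile(d.copy(), corrected, label=profile.label)


def detect_bands(
    profile: LaneProfile,
    min_prominence: float | None = None,
    mw_window_kda: tuple[float, float] | None = None,
    calibration: MarkerCalibration | None = None,
) -> list[Band]:
    """Find bands as prominent local maxima; integrate valley-to-valley.

    ``min_prominence`` defaults to 2% of the profile maximum.  Areas are
    trapezoid integrals between the flanking valleys (local minima of
    the profile, or the profile ends); percent_of_total is over the
    detected (and optionally MW-windowed) bands.
    """
    d, y = profile.distance_mm, profile.density
    if min_prominence is None:
        min_prominence = 0.02 * y.max() if y.max() > 0 else 0.0
    peaks, _ = find_peaks(y, prominence=min_prominence)
    if peaks.size == 0:
        raise GelError("no bands found above the prominence threshold")
    valleys, _ = find_peaks(-y)
    edges = np.concatenate([[0], valleys, [y.size - 1]])
    bands = []
    for p in peaks:
        left = edges[edges < p].max()
        right = edges[edges > p].min()
        area = float(np.trapezoid(y[left : right + 1], d[left : right + 1]))
        bands.append(Band(apex_mm=float(d[p]), area=area))
    if calibration is not None:
        bands = assign_mw(calibration, bands)
        if mw_window_kda is not None:
            lo, hi = mw_window_kda
            bands = [b for b in bands if lo <= b.mw_kda <= hi]
            if not bands:
                raise GelError("no bands inside the MW window")
    total = sum(b.area for b in bands)
    for b in bands:
        b.percent_of_total = 100.0 * b.area / total if total > 0 else float("nan")
    return bands


def calibrate_mw(
    marker: LaneProfile,
    marker_mws_kda: list[float],
    min_prominence: float | None = None,
) -> MarkerCalibration:
    """Fit the log-linear migration calibration on a marker lane.

    The detected marker peak count must equal the number of supplied
    MWs; peaks are paired with MWs by migration order (largest MW
    migrates least).
    """
    if len(marker_mws_kda) < 3:
        raise GelError("need at least 3 marker points for calibration")
    bands = detect_bands(marker, min_prominence=min_prominence)
    if len(bands) != len(marker_mws_kda):
        raise GelError(
            f"detected {len(bands)} marker peaks but {len(marker_mws_kda)} "
            "MWs supplied"
        )
    mws = sorted(marker_mws_kda, reverse=True)  # increasing distance
    dist = np.array([b.apex_mm for b in bands])
    logmw = np.log10(mws)
    slope, intercept = np.polyfit(dist, logmw, 1)
    if slope >= 0:
        raise GelError(
            "calibration slope is non-negative; marker order inconsistent "
            "with gel migration"
        )
    resid = logmw - (slope * dist + intercept)
    return MarkerCalibration(
        slope=float(slope),
        intercept=float(intercept),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        points=list(zip(dist.tolist(), mws)),
    )


def assign_mw(cal: MarkerCalibration, bands: list[Band]) -> list[Band]:
    for b in bands:
        b.mw_kda = float(cal.mw_at(b.apex_mm))
    return bands


def label_bands(bands: list[Band], style: str = "numbers") -> list[Band]:
    """Label bands in MW-descending order: 1..n or A..Z."""
    ordered = sorted(bands, key=lambda b: -b.mw_kda)
    for i, b in enumerate(ordered):
        b.label = str(i + 1) if style == "numbers" else chr(ord("A") + i)
    return bands


@dataclass
class BandMatch:
    pairs: list[tuple[Band, Band]]
    unmatched_reference: list[Band]
    unmatched_comparison: list[Band]
    tol_kda: float

    @property
    def novel_bands(self) -> list[Band]:
        """Comparison-lane bands with no reference equivalent."""
        return self.unmatched_comparison

    def delta_vs_anchor(self, anchor_label: str) -> dict[str, float]:
        """MW difference of every comparison band against one anchor
        band of the comparison lane (e.g. a novel truncation product)."""
        comp = [b for p in self.pairs for b in (p[1],)] + self.unmatched_comparison
        anchors = [b for b in comp if b.label == anchor_label]
        if not anchors:
            raise GelError(f"anchor band {anchor_label!r} not present")
        anchor = anchors[0]
        return {
            b.label: round(b.mw_kda - anchor.mw_kda, 10)
            for b in sorted(comp, key=lambda b: -b.mw_kda)
            if b is not anchor
        }

    def to_dict(self) -> dict:
        return {
            "tol_kda": self.tol_kda,
            "pairs": [
                {
                    "reference": p[0].label,
                    "comparison": p[1].label,
                    "reference_mw_kda": p[0].mw_kda,
                    "comparison_mw_kda": p[1].mw_kda,
                    "delta_mw_kda": p[1].mw_kda - p[0].mw_kda,
                }
                for p in self.pairs
            ],
            "novel": [
                {"label": b.label, "mw_kda": b.mw_kda}
                for b in self.unmatched_comparison
            ],
            "unmatched_reference": [
                {"label": b.label, "mw_kda": b.mw_kda}
                for b in self.unmatched_reference
            ],
        }


def match_bands(
    reference_bands: list[Band],
    comparison_bands: list[Band],
    tol_kda: float = 0.3,
) -> BandMatch:
    """Order-preserving minimum-cost alignment of two band series.

    Bands cannot cross on a gel, so both lanes are taken in descending
    MW order and aligned by dynamic programming: pairing two bands costs
    their |delta MW| (only allowed within ``tol_kda``), leaving a band
    unpaired costs ``tol_kda``.  A purely nearest-neighbour pairing can
    mis-assign a band between two near-equidistant partners and cascade
    errors down the lane; the alignment resolves such ties globally.
    Comparison bands left unpaired are novel (no reference equivalent).
    """
    ref = sorted(reference_bands, key=lambda b: -b.mw_kda)
    comp = sorted(comparison_bands, key=lambda b: -b.mw_kda)
    n, m = len(ref), len(comp)
    gap = tol_kda
    inf = float("inf")
    cost = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[""] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cost[i][0], move[i][0] = i * gap, "r"
    for j in range(1, m + 1):
        cost[0][j], move[0][j] = j * gap, "c"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = abs(ref[i - 1].mw_kda - comp[j - 1].mw_kda)
            # small epsilon so boundary cases (e.g. a printed 0.3 kDa
            # difference stored as 0.30000000000000004) stay inside
            pair = cost[i - 1][j - 1] + d if d <= gap + 1e-9 else inf
            skip_r = cost[i - 1][j] + gap
            skip_c = cost[i][j - 1] + gap
            best = min(pair, skip_r, skip_c)
            cost[i][j] = best
            move[i][j] = "p" if best == pair else ("r" if best == skip_r else "c")
    pairs: list[tuple[Band, Band]] = []
    un_r: list[Band] = []
    un_c: list[Band] = []
    i, j = n, m
    while i > 0 or j > 0:
        step = move[i][j]
        if step == "p":
            pairs.append((ref[i - 1], comp[j - 1]))
            i, j = i - 1, j - 1
        elif step == "r":
            un_r.append(ref[i - 1])
            i -= 1
        else:
            un_c.append(comp[j - 1])
            j -= 1
    pairs.reverse()
    un_r.reverse()
    un_c.reverse()
    return BandMatch(
        pairs=pairs,
        unmatched_reference=un_r,
        unmatched_comparison=un_c,
        tol_kda=tol_kda,
    )


def bands_from_mws(mws_kda: list[float], labels: list[str] | None = None) -> list[Band]:
    """Convenience: build MW-only band objects (e.g. from a published
    band table) for matching and delta reports."""
    if labels is None:
        labels = [str(i + 1) for i in range(len(mws_kda))]
    return [
        Band(apex_mm=float("nan"), area=float("nan"), mw_kda=m, label=l)
        for m, l in zip(mws_kda, labels)
    ]


def band_table(bands: list[Band]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": b.label,
                "distance_mm": b.apex_mm,
                "MW_kDa": b.mw_kda,
                "area": b.area,
                "percent": b.percent_of_total,
            }
            for b in sorted(
                bands, key=lambda b: b.apex_mm if b.apex_mm == b.apex_mm else -b.mw_kda
            )
        ]
    )
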