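"""Shared fixtures and independent closed-form oracles.

The analytic helpers here re-derive expected landmark values from the
piecewise-exponential relaxation model with scalar arithmetic — a
deliberately separate code path from the vectorised simulator they are
used to check.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import pytest

from lhckit import LightProtocol, default_protocol
from lhckit.simulate import SimPlantParams

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def protocol() -> LightProtocol:
    return default_protocol()


@dataclass
class AnalyticTruth:
    fo: float
    fm: float
    fs_i: float
    fs_i_prime: float
    fs_ii_prime: float
    fs_ii: float
    fm_i: float
    fm_ii: float
    ib: float
    qt: float
    qs: float


def analytic_truth(
    params: SimPlantParams,
    fr_interval_s: float = 900.0,
    cycle: int = 2,
    sp_offset_s: float = 30.0,
) -> AnalyticTruth:
    """Closed-form landmark values for the relaxation model.

    x relaxes towards 1 while far red is on and towards 1 - st_capacity
    while it is off; each segment is one exponential, so the value of x
    at any switch or saturating-pulse instant follows by recursion.
    """
    c, tau = params.st_capacity, params.tau_st
    e_full = math.exp(-fr_interval_s / tau)
    e_sp = math.exp(-(fr_interval_s - sp_offset_s) / tau)

    x = 1.0  # dark-adapted: State I
    seg = []
    for _ in range(cycle):
        x_off_start = x
        x_at_sp_off = (1 - c) + (x_off_start - (1 - c)) * e_sp
        x_off_end = (1 - c) + (x_off_start - (1 - c)) * e_full
        seg.append((x_off_start, x_at_sp_off, x_off_end))
        x = 1 + (x_off_end - 1) * e_full
    x_start, x_sp_off, x_end = seg[cycle - 1]

    def sigma(xv: float) -> float:
        return params.sigma_min + (params.sigma_max - params.sigma_min) * xv

    s0 = sigma(1.0)
    fo, fm, g = params.fo_level, params.fm_level, params.imbalance_gain

    fs_i = fo * sigma(x_start) / s0
    fs_i_prime = fo * sigma(x_start) / s0 + g * x_start
    fs_ii_prime = fo * sigma(x_end) / s0 + g * x_end
    fs_ii = fo * sigma(x_end) / s0
    fm_i = fm * sigma(x_start) / s0  # SP shortly before FR_OFF
    fm_ii = fm * sigma(x_sp_off) / s0  # SP shortly before FR_ON
    return AnalyticTruth(
        fo=fo,
        fm=fm,
        fs_i=fs_i,
        fs_i_prime=fs_i_prime,
        fs_ii_prime=fs_ii_prime,
        fs_ii=fs_ii,
        fm_i=fm_i,
        fm_ii=fm_ii,
        ib=(fs_i_prime - fs_i) / fo,
        qt=(fm_i - fm_ii) / fm_i,
        qs=(fs_i_prime - fs_ii_prime) / (fs_i_prime - fs_ii),
    )


def random_peptide(rng: random.Random, min_len: int = 5, max_len: int = 60) -> str:
    return "".join(rng.choices(AA, k=rng.randint(min_len, max_len)))


def brute_force_tryptic(seq: str, max_missed: int) -> set[tuple[int, str]]:
    """Enumeration oracle: every substring that starts at the sequence
    start or right after a cleavage site, ends at a site or the end, and
    spans at most max_missed internal sites."""
    sites = [
        i for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [len(seq)]
    out = set()
    for s in starts:
        for e in ends:
            if e <= s:
                continue
            internal = [i for i in sites if s <= i < e - 1]
            if len(internal) <= max_missed:
                out.add((s + 1, seq[s:e]))
    return out


def grid_scan_pi(seq: str, step: float = 0.001) -> float:
    """Dense-grid oracle for the isoelectric point."""
    from lhckit import net_charge

    best_ph, best = 0.0, float("inf")
    n = int(round(14.0 / step))
    for i in range(n + 1):
        ph = i * step
        c = abs(net_charge(seq, ph))
        if c < best:
            best, best_ph = c, ph
    return best_ph
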