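"""Theoretical protein chemistry for LHC antenna polypeptides.

Average molecular weight, Bjellqvist-pKa isoelectric point (charge
bisection), sequential N-terminal truncation scans, in-silico tryptic
digestion and per-residue peptide-coverage masks.

The pI computation follows the charge model behind the ExPASy Compute
pI/MW tool: each ionisable group contributes a Henderson–Hasselbalch
fractional charge, the alpha-amino pKa depends on the identity of the
first residue (so truncation shifts pI through both lost side chains and
the new N terminus), and the pI is the unique zero of the monotone net
charge curve.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TRANSIT_TAG = re.compile(r"\[transit=1\.\.(\d+)\]")


def _load_data(name: str) -> dict:
    with resources.files("lhckit.data").joinpath(name).open() as fh:
        return json.load(fh)


_MASSES = _load_data("average_masses.json")
WATER_MASS = _MASSES["water"]
RESIDUE_MASSES: dict[str, float] = _MASSES["residues"]


@dataclass(frozen=True)
class PkaSet:
    """Group pKa values used for the net-charge model."""

    positive_side_chains: dict[str, float]
    negative_side_chains: dict[str, float]
    nterm_default: float
    nterm_by_residue: dict[str, float]
    cterm_default: float
    cterm_by_residue: dict[str, float]

    def __post_init__(self) -> None:
        for pka in (
            *self.positive_side_chains.values(),
            *self.negative_side_chains.values(),
            self.nterm_default,
            self.cterm_default,
            *self.nterm_by_residue.values(),
            *self.cterm_by_residue.values(),
        ):
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa {pka} outside (0, 14)")

    def nterm_pka(self, first_residue: str) -> float:
        return self.nterm_by_residue.get(first_residue, self.nterm_default)

    def cterm_pka(self, last_residue: str) -> float:
        return self.cterm_by_residue.get(last_residue, self.cterm_default)

    @classmethod
    def bjellqvist(cls) -> "PkaSet":
        d = _load_data("pka_bjellqvist.json")
        return cls(
            positive_side_chains=d["positive_side_chains"],
            negative_side_chains=d["negative_side_chains"],
            nterm_default=d["nterm_default"],
            nterm_by_residue=d["nterm_by_residue"],
            cterm_default=d["cterm_default"],
            cterm_by_residue=d["cterm_by_residue"],
        )


DEFAULT_PKA = PkaSet.bjellqvist()


@dataclass
class ProteinRecord:
    """A protein with an optional chloroplast transit peptide.

    ``transit_end`` is the 1-based inclusive end of the transit peptide
    (which always starts at residue 1); the mature sequence is the
    remainder after import-cleavage.
    """

    identifier: str
    sequence: str
    transit_end: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.identifier}: illegal residue(s) {sorted(bad)}"
            )
        if self.transit_end is not None:
            if not 0 < self.transit_end < len(self.sequence):
                raise ValueError(
                    f"{self.identifier}: transit span 1..{self.transit_end} "
                    f"invalid for length {len(self.sequence)}"
                )

    @property
    def mature(self) -> str:
        if self.transit_end is None:
            return self.sequence
        return self.sequence[self.transit_end:]


def read_fasta(
    path: str | Path, transit_table: str | Path | None = None
) -> list[ProteinRecord]:
    """Read protein records; transit spans via ``[transit=1..N]`` header
    tags or a sidecar TSV with columns ``identifier<TAB>transit_end``."""
    spans: dict[str, int] = {}
    if transit_table is not None:
        for line in Path(transit_table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ident, end = line.split("\t")[:2]
            spans[ident] = int(end)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _TRANSIT_TAG.search(rec.description)
        end = int(m.group(1)) if m else spans.get(rec.id)
        records.append(
            ProteinRecord(
                identifier=rec.id,
                sequence=str(rec.seq),
                transit_end=end,
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tag = f" [transit=1..{rec.transit_end}]" if rec.transit_end else ""
            fh.write(f">{rec.identifier}{tag}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# -- MW and pI -----------------------------------------------------------------


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (residue masses plus one water)."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(RESIDUE_MASSES[a] for a in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


def net_charge(seq: str, pH: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Net charge (elementary charges) of a peptide at a given pH."""
    if not seq:
        raise ValueError("empty sequence")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.nterm_pka(seq[0])))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.cterm_pka(seq[-1]) - pH))
    for aa, k in pka.positive_side_chains.items():
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - k))
    for aa, k in pka.negative_side_chains.items():
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (k - pH))
    return charge


@dataclass(frozen=True)
class PiResult:
    pi: float
    at_boundary: bool = False


def isoelectric_point(
    seq: str, pka: PkaSet = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge is continuous and strictly decreasing in pH, so the
    zero is unique when it exists; sequences whose charge does not change
    sign on [0, 14] return the boundary value with a warning.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo, pka), net_charge(seq, hi, pka)
    if c_lo <= 0:
        warnings.warn("net charge non-positive over [0, 14]; pI at boundary 0")
        return lo
    if c_hi >= 0:
        warnings.warn("net charge non-negative over [0, 14]; pI at boundary 14")
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- truncation scan -----------------------------------------------------------


@dataclass
class TruncationStep:
    k: int
    removed: str
    mw_da: float
    pi: float
    dmw_kda: float
    dpi: float


@dataclass
class TruncationScan:
    identifier: str
    steps: list[TruncationStep]

    def as_rows(self) -> list[dict]:
        return [vars(s) for s in self.steps]

    def write_tsv(self, path: str | Path) -> None:
        lines = ["k\tremoved\tMW_Da\tpI\tdMW_kDa\tdpI"]
        for s in self.steps:
            lines.append(
                f"{s.k}\t{s.removed or '-'}\t{s.mw_da:.3f}\t{s.pi:.2f}\t"
                f"{s.dmw_kda:.4f}\t{s.dpi:.3f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def truncation_scan(
    record: ProteinRecord, max_remove: int, pka: PkaSet = DEFAULT_PKA
) -> TruncationScan:
    """pI and MW of the mature protein as N-terminal residues are removed
    one by one.

    Step k removes the first k residues; ΔMW and ΔpI are reported against
    the intact mature protein (k=0).  The alpha-amino pKa is re-selected
    at every step for the newly exposed first residue.
    """
    mature = record.mature
    if max_remove >= len(mature):
        raise ValueError(
            f"max_remove={max_remove} >= mature length {len(mature)}"
        )
    mw0 = molecular_weight(mature)
    pi0 = isoelectric_point(mature, pka)
    steps = []
    for k in range(max_remove + 1):
        seq = mature[k:]
        mw = molecular_weight(seq)
        pi = isoelectric_point(seq, pka)
        steps.append(
            TruncationStep(
                k=k,
                removed=mature[:k],
                mw_da=mw,
                pi=pi,
                dmw_kda=(mw - mw0) / 1000.0,
                dpi=pi - pi0,
            )
        )
    return TruncationScan(identifier=record.identifier, steps=steps)


# -- tryptic digestion and coverage --------------------------------------------


@dataclass(frozen=True)
class Peptide:
    sequence: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    missed_cleavages: int


def cleavage_sites(seq: str) -> list[int]:
    """0-based indices i such that trypsin cuts between seq[i] and
    seq[i+1]: after K or R, except when the next residue is P."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def digest_tryptic(seq: str, max_missed: int = 2) -> list[Peptide]:
    """All tryptic peptides with 0..max_missed internal missed cleavages."""
    if not seq:
        raise ValueError("empty sequence")
    sites = cleavage_sites(seq)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            peptides.append(
                Peptide(
                    sequence=seq[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=m,
                )
            )
    return peptides


@dataclass
class CoverageMask:
    identifier: str
    mask: list[bool]
    unmatched_peptides: list[str] = field(default_factory=list)

    @property
    def n_term_gap(self) -> int:
        """Number of uncovered residues before the first covered one."""
        for i, covered in enumerate(self.mask):
            if covered:
                return i
        return len(self.mask)

    @property
    def fraction_covered(self) -> float:
        return sum(self.mask) / len(self.mask) if self.mask else 0.0

    def phospho_covered(self, mature_seq: str) -> bool:
        """True when the state-transition phospho-threonine (mature
        position 3) exists and is covered by an observed peptide."""
        return (
            len(mature_seq) >= 3
            and mature_seq[2] == "T"
            and len(self.mask) >= 3
            and self.mask[2]
        )

    def write_tsv(self, path: str | Path, seq: str | None = None) -> None:
        lines = ["position\tresidue\tcovered"]
        for i, covered in enumerate(self.mask):
            res = seq[i] if seq else "."
            lines.append(f"{i + 1}\t{res}\t{int(covered)}")
        Path(path).write_text("\n".join(lines) + "\n")


def coverage_map(
    record: ProteinRecord, observed_peptides: Sequence[str]
) -> CoverageMask:
    """Per-residue coverage of the mature sequence by observed peptides.

    Peptides are matched as exact substrings (all occurrences count);
    peptides that do not match anywhere are reported, not fatal.
    """
    mature = record.mature
    mask = [False] * len(mature)
    unmatched = []
    for pep in observed_peptides:
        pep = pep.upper()
        found = False
        start = mature.find(pep)
        while start != -1:
            found = True
            for i in range(start, start + len(pep)):
                mask[i] = True
            start = mature.find(pep, start + 1)
        if not found:
            unmatched.append(pep)
    if unmatched:
        warnings.warn(
            f"{record.identifier}: {len(unmatched)} observed peptide(s) "
            "did not match the mature sequence"
        )
    return CoverageMask(
        identifier=record.identifier, mask=mask, unmatched_peptides=unmatched
    )
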