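"""Protein chemistry: masses, charge, pI, truncation, digestion, coverage."""

from __future__ import annotations

import random
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lhckit import (
    PkaSet,
    ProteinRecord,
    coverage_map,
    digest_tryptic,
    isoelectric_point,
    molecular_weight,
    net_charge,
    read_fasta,
    truncation_scan,
)
from lhckit.proteins import WATER_MASS, write_fasta

from conftest import AA, brute_force_tryptic, grid_scan_pi, random_peptide

peptides = st.text(alphabet=AA, min_size=1, max_size=50)


# -- molecular weight ----------------------------------------------------------


def test_single_glycine_weight():
    # one residue plus one water
    assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)


@given(a=peptides, b=peptides)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_weight_additivity(a, b):
    # concatenation forms one peptide bond: one water is released
    assert molecular_weight(a + b) == pytest.approx(
        molecular_weight(a) + molecular_weight(b) - WATER_MASS, abs=1e-6
    )


def test_weight_matches_biopython_within_table_differences():
    # Biopython uses IUPAC atomic weights; our table follows the
    # pI/MW-tool convention — they agree to ~0.005 Da per residue
    from Bio.SeqUtils import molecular_weight as bio_mw

    rng = random.Random(7)
    for _ in range(50):
        s = random_peptide(rng)
        assert molecular_weight(s) == pytest.approx(
            bio_mw(s, "protein", monoisotopic=False), abs=0.005 * len(s) + 0.01
        )


def test_weight_rejects_empty_and_illegal():
    with pytest.raises(ValueError):
        molecular_weight("")
    with pytest.raises(ValueError):
        molecular_weight("ACDX")


# -- net charge and pI ---------------------------------------------------------


def test_polyala_charge_limits():
    # at pH 0 only the termini ionise: +1; at pH 14: -1
    assert net_charge("AAAAAA", 0.0) == pytest.approx(1.0, abs=1e-3)
    assert net_charge("AAAAAA", 14.0) == pytest.approx(-1.0, abs=1e-3)


@given(seq=st.text(alphabet=AA, min_size=1, max_size=30))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_net_charge_strictly_decreasing(seq):
    phs = [i * 0.35 for i in range(41)]
    charges = [net_charge(seq, ph) for ph in phs]
    assert all(c1 > c2 for c1, c2 in zip(charges, charges[1:]))


def test_two_glycine_pi_analytic():
    # two ionisable groups with symmetric Henderson-Hasselbalch terms:
    # pI is the pKa midpoint
    pka = PkaSet.bjellqvist()
    expected = (pka.nterm_pka("G") + pka.cterm_pka("G")) / 2
    assert isoelectric_point("GG") == pytest.approx(expected, abs=1e-3)


def test_pi_bisection_agrees_with_grid_oracle():
    rng = random.Random(42)
    for _ in range(30):
        s = random_peptide(rng)
        assert isoelectric_point(s) == pytest.approx(
            grid_scan_pi(s), abs=0.005
        )


def test_pi_loose_agreement_with_biopython():
    # Biopython stops at |charge| < 0.05, so only loose agreement is
    # expected; this guards against charge-model errors, not precision
    from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

    rng = random.Random(3)
    for _ in range(30):
        s = random_peptide(rng)
        ref = IsoelectricPoint(s).pi(pH=7.0, min_=0.0, max_=14.0)
        assert isoelectric_point(s) == pytest.approx(ref, abs=0.1)


def test_net_charge_rejects_bad_inputs():
    with pytest.raises(ValueError):
        net_charge("", 7.0)
    with pytest.raises(ValueError):
        net_charge("AAA", 15.0)


# -- truncation scan -----------------------------------------------------------


def test_truncation_scan_step0_and_mass_consistency():
    from lhckit.proteins import RESIDUE_MASSES

    rec = ProteinRecord("toy", "RKTADDEEVVLKGHWY")
    scan = truncation_scan(rec, 8)
    assert scan.steps[0].dpi == 0.0 and scan.steps[0].dmw_kda == 0.0
    for step in scan.steps:
        removed_mass = sum(RESIDUE_MASSES[a] for a in step.removed)
        assert abs(step.dmw_kda) * 1000 == pytest.approx(removed_mass, abs=1e-6)
    mws = [s.mw_da for s in scan.steps]
    assert all(m1 > m2 for m1, m2 in zip(mws, mws[1:]))


def test_polyglycine_truncation_pi_invariant():
    # identical termini chemistry at every step: pI never moves
    rec = ProteinRecord("polyG", "G" * 20)
    scan = truncation_scan(rec, 10)
    assert all(abs(s.dpi) < 1e-3 for s in scan.steps)


def test_removing_arginine_more_acidifying_than_neutral_residue():
    scaffold = "ADDEEGGKLVVT"
    rec_r = ProteinRecord("r", "R" + scaffold)
    rec_v = ProteinRecord("v", "V" + scaffold)
    dpi_r = truncation_scan(rec_r, 1).steps[1].dpi
    dpi_v = truncation_scan(rec_v, 1).steps[1].dpi
    assert dpi_r < 0  # losing a basic residue moves pI acidic
    assert dpi_r < dpi_v
    assert abs(dpi_r) > abs(dpi_v)


def test_truncation_scan_rejects_overlong_removal():
    rec = ProteinRecord("toy", "RKTADDEE")
    with pytest.raises(ValueError):
        truncation_scan(rec, 8)


# -- digestion -----------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,max_missed,expected",
    [
        ("AKPGR", 0, {"AKPGR"}),  # KP suppresses the K site
        ("AKRG", 0, {"AK", "R", "G"}),
        ("GGGG", 2, {"GGGG"}),  # no K/R at all
    ],
)
def test_digestion_rule_cases(seq, max_missed, expected):
    assert {p.sequence for p in digest_tryptic(seq, max_missed)} == expected


def test_digestion_matches_enumeration_oracle():
    rng = random.Random(11)
    for _ in range(60):
        s = random_peptide(rng, 5, 80)
        m = rng.randint(0, 2)
        mine = {(p.start, p.sequence) for p in digest_tryptic(s, m)}
        assert mine == brute_force_tryptic(s, m)


def test_digestion_matches_pyteomics():
    from pyteomics import parser as pt

    rng = random.Random(5)
    for _ in range(30):
        s = random_peptide(rng, 5, 80)
        mine = {p.sequence for p in digest_tryptic(s, 2)}
        ref = pt.cleave(
            s, pt.expasy_rules["trypsin"], missed_cleavages=2, min_length=0
        )
        assert mine == set(ref)


def test_zero_missed_peptides_tile_sequence():
    rng = random.Random(13)
    for _ in range(20):
        s = random_peptide(rng, 10, 120)
        peps = [p for p in digest_tryptic(s, 2) if p.missed_cleavages == 0]
        peps.sort(key=lambda p: p.start)
        assert peps[0].start == 1 and peps[-1].end == len(s)
        assert all(
            p1.end + 1 == p2.start for p1, p2 in zip(peps, peps[1:])
        )
        assert "".join(p.sequence for p in peps) == s
        # every m-missed peptide concatenates m+1 adjacent 0-missed ones
        zero_by_start = {p.start: p for p in peps}
        for p in digest_tryptic(s, 2):
            parts, pos = [], p.start
            while pos <= p.end:
                q = zero_by_start[pos]
                parts.append(q.sequence)
                pos = q.end + 1
            assert "".join(parts) == p.sequence
            assert len(parts) == p.missed_cleavages + 1


# -- coverage ------------------------------------------------------------------


def test_full_coverage_and_gap():
    rec = ProteinRecord("toy", "RKTADDEEVVLKGHWY")
    peps = [p.sequence for p in digest_tryptic(rec.mature, 0)]
    mask = coverage_map(rec, peps)
    assert mask.n_term_gap == 0
    assert all(mask.mask)
    assert mask.phospho_covered(rec.mature)


def test_nterm_truncated_coverage():
    rec = ProteinRecord("toy", "RKTADDEEKVVLKGHWYR" + "AEDLK" * 4)
    full = digest_tryptic(rec.mature, 2)
    observed = [p.sequence for p in full if p.start > 8]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = coverage_map(rec, observed)
    assert mask.n_term_gap >= 8
    assert not mask.phospho_covered(rec.mature)


def test_empty_observed_set():
    rec = ProteinRecord("toy", "RKTADDEEVVLK")
    mask = coverage_map(rec, [])
    assert not any(mask.mask)
    assert mask.n_term_gap == len(rec.mature)
    assert mask.fraction_covered == 0.0


def test_unmatched_peptides_warn_not_fail():
    rec = ProteinRecord("toy", "RKTADDEEVVLK")
    with pytest.warns(UserWarning):
        mask = coverage_map(rec, ["WWWWW"])
    assert mask.unmatched_peptides == ["WWWWW"]


# -- FASTA IO ------------------------------------------------------------------


def test_fasta_round_trip_with_transit_tags(tmp_path):
    recs = [
        ProteinRecord("prot1", "MASTR" + "ADEK" * 10, transit_end=5),
        ProteinRecord("prot2", "RKT" + "GAVL" * 5),
    ]
    path = tmp_path / "x.fasta"
    write_fasta(recs, path)
    back = read_fasta(path)
    assert [r.identifier for r in back] == ["prot1", "prot2"]
    assert back[0].transit_end == 5
    assert back[0].mature == recs[0].mature
    assert back[1].sequence == recs[1].sequence


def test_fasta_sidecar_transit_table(tmp_path):
    path = tmp_path / "x.fasta"
    path.write_text(">acc1 some protein\nMASTRADEKADEK\n")
    sidecar = tmp_path / "transit.tsv"
    sidecar.write_text("# identifier\ttransit_end\nacc1\t5\n")
    rec = read_fasta(path, transit_table=sidecar)[0]
    assert rec.transit_end == 5
    assert rec.mature == "ADEKADEK"


def test_fasta_lowercase_uppercased_and_illegal_rejected(tmp_path):
    path = tmp_path / "lc.fasta"
    path.write_text(">p\nmastr\n")
    assert read_fasta(path)[0].sequence == "MASTR"
    bad = tmp_path / "bad.fasta"
    bad.write_text(">p\nMASTRZ\n")
    with pytest.raises(ValueError):
        read_fasta(bad)


def test_empty_fasta_rejected(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with pytest.raises(ValueError):
        read_fasta(path)
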