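# Methods

## Fluorescence trace model and the state-transition statistics

### The generative model

The simulator is a phenomenological two-state relaxation model, chosen
as the smallest model that (i) reproduces the qualitative shape of a
far-red on/off induction trace and (ii) gives every landmark a closed
form so the analyzer can be tested against exact expectations. It is
not a mechanistic model of electron transport.

Let `x(t) ∈ [0, 1]` be the fraction of mobile LHCII attached to PSII.
It relaxes as

    dx/dt = (x_target − x) / tau_st

with `x_target = 1` while far red is on (oxidised PQ pool, State I) and
`x_target = 1 − st_capacity` while it is off. `st_capacity` is the
fraction of antenna able to migrate: 1 emulates a transition-competent
(wild-type-like) leaf, 0 a transition-incompetent (cybrid-like) one in
which the trace stays flat after the initial rise. The PSII
cross-section is `σ(t) = σ_min + (σ_max − σ_min)·x(t)`; steady-state
fluorescence is

    Fs(t) = fo_level · σ(t)/σ(0) + imbalance_gain · u(t)

where the PQ-reduction proxy `u(t)` equals `x(t)` during far-red-off
periods and 0 otherwise (far red keeps PSI drained, so removing it
reduces the pool roughly in proportion to how much antenna still feeds
PSII). Saturating pulses replace the signal by
`fm_level · σ(t)/σ(0)` for the pulse duration — a plateau, not a
kinetic rise, because only the plateau value is consumed downstream.
Before the measuring light the signal is zero; between measuring light
and actinic light it sits at `fo_level`. Noise is i.i.d. Gaussian; no
drift term, since the landmark estimators are window averages and drift
would only test baseline handling the instrument normally removes.

Each illumination segment makes `x(t)` a single exponential, so the
solution is evaluated exactly per segment (no numerical integration),
and the generators are bit-reproducible given (params, seed).

Default parameters:

| parameter | default | meaning / rationale |
|---|---|---|
| `sigma_min`, `sigma_max` | 0.89, 1.0 | ≈11 % cross-section loss on full transition, the magnitude typical of a competent tobacco leaf (qT ≈ 0.11) |
| `st_capacity` | 1 (wild type), 0 (cybrid preset) | fraction of mobile antenna |
| `tau_st` | 120 s | minutes-scale transition kinetics, comfortably inside a 15-min far-red interval |
| `fo_level`, `fm_level` | 0.2, 1.0 | Fo/Fm ≈ 0.2, a normal dark-adapted ratio |
| `imbalance_gain` | 0.112 | gives IB = gain/Fo ≈ 0.56, mid-range for a well-tuned protocol (nominal 0.5–0.7) |
| `noise_sd` | 0.005 (0.5 % of Fm) | quiet PAM signal; recovery tests use 0.01 |

The default protocol follows the standard room-temperature induction
scheme: measuring light at t = 0, a dark-adapted saturating pulse at
30 s, actinic + far-red light at 2 min, then far red switched off/on in
15-min intervals for two cycles, with saturating pulses 30 s after each
switch and 30 s before the next. Sampling interval 0.5 s, pulse
duration 0.8 s.

### Landmark estimation

Analysis uses the second cycle by default (the first is contaminated by
dark-to-light induction kinetics); cycle 1 is available by flag.
Steady-state landmarks (Fo, FsI, FsII′) are means over 30-s windows
ending at the relevant switch; the windows are half-open `[t0, t1)` so
the switch-instant sample — which already carries the post-switch
value — is excluded. Transient landmarks are searched within 60 s after
the switch: FsI′ is the maximum after far-red removal, FsII the minimum
("dip") after far-red restoration. FmI′/FmII′ are the
saturating-pulse plateaus (maximum within the pulse window) of the last
pulse before the respective switch. Saturating-pulse windows, padded by
2 s, are excluded from all steady-state and transient windows.

Transient extrema are read from a 15-s boxcar-smoothed signal (averaging
only non-excluded samples). A raw per-sample extremum carries an
extreme-value noise bias of order `2.5·noise_sd`, which propagates into
qS through both FsI′ and the denominator term FsII; smoothing over 15 s
(30 samples) suppresses that bias while remaining short against both
the 60-s search window and the 120-s transition time constant, so the
systematic underestimate from signal decay within the smoothing window
stays negligible. With 1 % noise this keeps the analyzer's qS within
0.05 of the model value (typical error ≈ 0.015); `smooth_s=0` restores
raw extrema for noise-free exactness checks.

### Statistics

`IB = (FsI′ − FsI)/Fo` (dark-adapted Fo, as written in the protocol
definition), `qT = (FmI′ − FmII′)/FmI′`, `qS = (FsI′ − FsII′)/(FsI′ −
FsII)`. Values are reported as fractions and percent, **never
clipped**: real replicates legitimately scatter above 1 or below 0, so
out-of-nominal-range values (qT outside 0–0.25, qS outside 0–1) are
flagged, not altered. A degenerate qS denominator (|FsI′ − FsII| below
1e-9) yields NaN plus a `qs_degenerate` flag rather than a silent NaN.
The two conventional writings of qT (with and without primes) are
treated as the same light-adapted quantities; the dark-adapted Fm enters
no statistic and is reported for reference only.

## 77 K spectra

Spectra are modelled as three Gaussians — PSII core (685 nm, SD 8 nm),
PSII vibronic shoulder (695 nm, SD 9 nm) and PSI (735 nm, SD 16 nm) —
on a 1-nm grid over 600–800 nm; in State II the 735-nm amplitude is
multiplied by `psi_boost_state2` (default 1.5; 1.0 emulates a
transition-incompetent sample). Analysis normalises at 685 nm (linear
interpolation on the measured grid; idempotent and scale-invariant) and
reads the PSI contribution as the point ratio F735/F685 — a band-height
comparison, not a spectral decomposition, matching how such spectra are
conventionally reported. No baseline correction is applied before
normalisation.

`compare_states` reports `delta_psi = F735/F685(II) − F735/F685(I)` and
flags an increase above a 0.02 threshold. By default no smoothing is
applied; for noisy spectra a Savitzky–Golay filter (window 11, order 3)
is available behind the `smooth` flag, because a single-pixel point
ratio at 1 % noise produces ≈ 0.014 SD in `delta_psi` and hence an
≈ 10 % false-positive rate at the 0.02 threshold. With smoothing, 100
simulated replicate pairs give 100/100 detections at boost 1.5 and
0/100 false calls at boost 1.0; the Monte-Carlo comparisons in the test
suite and acceptance script therefore use the flag.

## Gel densitometry

Lanes are density-vs-distance profiles. Baseline correction fits a
straight line through lower-envelope anchor points (10th-percentile
samples in each quarter of the lane plus the ends) and clips negatives;
a rolling-minimum envelope is available as an alternative. Bands are
local maxima above a prominence threshold (default 2 % of the profile
maximum); areas are trapezoid integrals between flanking valleys —
valley-to-valley rather than Gaussian fitting, which is what a density
plot supports without assuming peak shape. Percent-of-total is computed
over the detected bands, optionally restricted to a MW window (default
suggestion 20–26 kDa for LHC work). Calibration is a least-squares fit
of log10(MW) on migration distance over a marker lane (slope must be
negative; at least three markers; marker peak count must equal the
supplied MW count).

Cross-lane matching is an **order-preserving minimum-cost alignment**
(dynamic programming): both lanes sorted by descending MW, pairing two
bands costs their |ΔMW| and is allowed only within the tolerance
(default 0.3 kDa, chosen against typical replicate SDs of 0.03–0.6 kDa),
and leaving a band unpaired costs the tolerance. A greedy
nearest-neighbour pairing was rejected: when one band sits nearly
equidistant between two partners (e.g. 23.7 between 23.9 and 23.6 kDa)
greedy matching takes the locally closest partner, steals it from the
next band and cascades spurious "novel" calls down the lane — and its
outcome depends on tie order. Bands cannot cross on a gel, so the
order-preserving alignment is also the physically correct constraint.
Unmatched comparison bands are flagged novel; `delta_vs_anchor` reports
each band's MW offset from a chosen anchor band, the natural report when
a novel band is suspected to be a truncation series product. A small
epsilon (1e-9 kDa) on the tolerance comparison keeps printed one-decimal
values that differ by exactly the tolerance inside it.

## Protein chemistry

Molecular weight is the sum of average residue masses plus one water,
using the classical average-mass table of the online pI/MW calculators
(stored as versioned package data); these differ from current IUPAC
atomic-weight tables by up to ~0.004 Da/residue, and the classical table
is the convention under which published theoretical LHC MWs were
produced. Monoisotopic masses are out of scope.

The isoelectric point uses the Bjellqvist pKa set (side chains D, E, C,
Y, H, K, R; residue-specific α-amino pKa; α-carboxy pKa with D/E
overrides), also stored as package data. Net charge at a given pH is
the sum of Henderson–Hasselbalch fractional charges; it is continuous
and strictly decreasing in pH, so the zero is unique and bisection on
[0, 14] to |ΔpH| < 1e-4 finds it; property tests check agreement with a
0.001-step grid scan to within 0.005. If the charge does not change
sign on [0, 14] (only possible for non-standard group sets) the boundary
is returned with a warning. Cysteine is treated as fully reducible — no
fixed carbamidomethyl shift enters pI or MW; digestion-facing workflows
may pass modified masses downstream if needed. Truncation scans remove
N-terminal residues one at a time from the mature sequence,
**re-selecting the α-amino pKa for each newly exposed first residue**,
and report ΔMW (kDa) and ΔpI against the intact mature protein; removing
a charged N-terminal residue (Arg) therefore shifts pI acidward both by
the lost side chain and the changed terminus.

Transit peptides come only from explicit annotation — a
`[transit=1..N]` FASTA header tag or a sidecar TSV — never from
cleavage-site prediction; mature = full sequence minus the transit
span. Tryptic digestion cuts after K or R except before P, enumerating
all peptides with 0–2 missed cleavages (configurable) with 1-based
coordinates; zero-missed peptides tile the sequence exactly once and
every m-missed peptide is the concatenation of m+1 adjacent zero-missed
ones (both property-tested, plus cross-checks against an independent
enumeration oracle and pyteomics). Coverage masks mark every residue
contained in any exact-substring occurrence of an observed peptide
(no I/L equivalence by default); derived quantities are the N-terminal
gap (uncovered leading residues) and whether the phospho-threonine at
mature position 3 is covered — the decisive question when judging
whether an N-terminus was present in the sample.

## Synthetic sequences

`make_lhcb_like_sequence` emulates an LHCII apoprotein for machinery
tests: the mature chain starts Arg-X-Thr (phospho-Thr at mature
position 3), and the composition is an acidic-biased multiset
apportioned by largest remainder from fixed weights, shuffled per seed
with a ±1 acidic-residue wobble. Holding the composition near-fixed
keeps the mature pI in a narrow acidic window (4.87–5.02 over 50 seeds
at the default 232-residue length, inside the 4.5–5.5 window typical of
LHC apoproteins); very short sequences (< ~60 residues) leave that
window because single residues then move the pI by tenths of a unit.
These sequences are random-composition stand-ins — they have no
homology, secondary structure or real isoform structure, so passing
tests demonstrate correct analyzer machinery, not biological inference
on real LHC sequences.

## Problem sizes and numerics

The test suite and acceptance script use: 20 seeds for noisy qS
recovery (1 % noise), 100 replicate pairs per 77 K detection-rate
estimate, 100 random sequences each for the pI-solver and digestion
oracle comparisons, 50 seeds for the synthetic-sequence pI window, and
single noise-free runs for exactness checks (tolerances 1e-6 to 1e-12
as appropriate). The full suite runs in a few seconds.

## Known limitations

* The fluorescence model has no NPQ/qE, no photoinhibition, no
  induction-kinetics realism and makes no attempt to match absolute
  fluorescence magnitudes of real instruments; only the landmark
  geometry and the three statistics are faithful.
* Published mature MW/pI comparisons for the named tobacco accessions
  require the real UniProt sequences, which are fetched by script, not
  redistributed (see `data/uniprot/README.md`); the two tests that need
  them fail with a pointer when the file is absent.
* The lhcb3 entry (A0A076L1Y1) has no UniProt transit annotation; its
  cleavage site must be supplied manually for mature-protein numbers.
* Gel analysis starts from 1-D density profiles; image-to-profile
  extraction and 2-D gels are out of scope, as are spectral
  deconvolution and MS spectrum-to-peptide scoring.
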