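# Methods

## Scope and model

`wortpep` implements the desk half of a wort-protein characterisation
workflow: simulated enzymatic digestion of barley (*Hordeum vulgare*) and
hemp (*Cannabis sativa*) proteins with screening of the released peptides
against a peptide-activity database, and molecular-weight profiling of
size-exclusion (SEC-HPLC) traces with DPPH scavenging arithmetic for
collected fractions.  The wet-lab half (malting, mashing, extraction,
chromatography itself) is out of scope; the package consumes its outputs
as text tables.

### Cleavage model

An enzyme is a single-bond context rule in Schechter–Berger nomenclature:
the bond C-terminal to residue *i* is hydrolysed iff residue *i* (P1) is
in the rule's cleavable set and residue *i+1* (P1′) is not in its veto
set.  Digestion is deterministic and exhaustive — every matching bond is
cut and the released peptides are the maximal uncut runs.  Kinetics,
missed cleavages and partial digestion are deliberately not modelled;
the simulated quantity is the limiting digest.

For a chain of `N` residues (`D = N − 1` bonds) with `d` hydrolysed
bonds, the theoretical degree of hydrolysis is `DHt = 100·d/D`, reported
to 2 decimals.

### Release indicators

Against an activity database of (peptide, label) entries, for each
activity:

* `a` — number of (entry, start-position) substring matches in the
  intact chain; overlapping and repeated matches all count;
* `d` — number of released peptides whose full sequence equals an entry
  with that activity; duplicate released peptides each count;
* `A = a/N`, `Ae = d/N`, `W = Ae/A`, reported to 4 decimals (`W` is
  computed from the unrounded ratio `d/a` so rounding cannot push it
  above 1).  `W = 0` with an *undefined* convention when `a = d = 0`.

Counting with multiplicity makes `d ≤ a` a theorem (an exact released
match is in particular an occurrence), hence `0 ≤ W ≤ 1`; the test suite
property-checks this on random instances.  Whether a reference
implementation counts distinct sequences or occurrence multiplicity for
repeated released peptides is not documented anywhere we could verify;
the multiplicity convention is used consistently here.

Activity labels are free text compared case-insensitively after
whitespace normalisation, because published activity tables mix
capitalisations of the same label.

### The subtilisin A rule and its recovery

The study proteins were digested in silico with subtilisin A
(EC 3.4.21.62) through the BIOPEP-UWM web tool, whose internal residue
sets are not published.  The rule is recovered from published numbers
alone:

1. Each protein's printed 2-decimal DHt and printed length pin down the
   exact cut count `d = round(DHt·D/100)`; the inversion is unambiguous
   because changing `d` by one moves DHt by ≥ 0.13 percentage points.
   The six counts are (76, 21, 182) for the barley hordeins P06470,
   P06472, I6SW23 and (133, 74, 124) for the hemp proteins A0A090CXP9,
   A0A803Q1B3, A0A7J6FEU0.
2. `calibrate_rule` searches *all* P1 subsets for every P1′ veto set up
   to a requested size, in increasing veto-set size, and returns every
   rule whose digests reproduce all supplied counts exactly.  For a
   fixed veto set the cut count is additive over P1 residues, so each
   veto set reduces to an exact multi-dimensional subset-sum problem,
   solved completely by meet-in-the-middle enumeration with packed
   integer keys.  Residues never observed in cleavable context are
   excluded from the enumeration: they cannot affect the fit and would
   only duplicate solutions.  Ordering is deterministic (veto size, then
   P1 size, then lexicographic), so the selected rule is reproducible.

Findings from the complete search, which shape the package's defaults:

* Calibrated on the three barley hordeins alone, the P1-only grammar has
  a **unique** solution, P1 = {D,F,I,R,S,V,W,Y}.  Applied to the hemp
  proteins it predicts cut counts (203, 73, 176) against the published
  (133, 74, 124) — cross-family transfer fails.  This is not a corner
  case of the tie-break: **no** rule with a veto set of size ≤ 6
  reproduces all six counts, so no barley-only calibration in this
  grammar can generalise, whichever candidate is selected.  A dedicated
  test asserts this negative result.
* The minimal-complexity rules consistent with **all six** counts appear
  at veto size 7, and there are exactly two.  The selected one (smaller
  P1 set) is **P1 = {A,F,G,I,K,L,M,V}, veto = {A,C,G,H,K,M,R}** — a
  small/aliphatic-hydrophobic P1 preference consistent with subtilisin's
  broad specificity.  (The runner-up is P1 = {A,D,F,H,I,L,M,S,Y},
  veto = {C,D,I,K,N,R,S}.)  An independent mixed-integer feasibility
  formulation (HiGHS via `scipy.optimize.milp`) confirms the solution
  set.

The shipped `subtilisin A` entry in `data/enzymes.tsv` is that recovered
rule, and `wortpep.reference.recover_subtilisin_rule()` re-derives it
from scratch (≈ 1–2 min on one CPU; the barley-only P1 search takes
milliseconds).  The consequence is stated plainly: because the rule is
recovered from the same six cut counts it reproduces, the agreement of
the six DHt values is an internal-consistency check of the recovery, not
an out-of-sample prediction.  Truly independent validation would need a
seventh protein's published DHt under the same tool, or the tool's own
rule tables.

### Sequence masses

Average (not monoisotopic) chain masses use Biopython's standard residue
mass table plus one water, reported in kDa to 3 decimals.  All six
packaged sequences agree with their database-declared masses within
±0.001 kDa (three differ by exactly 0.001, a rounding artefact in the
source).

## HPSEC stage

* **Calibration** — ordinary least squares of log10(mass/kDa) on
  retention time, the standard working model for SEC columns.  Two
  standards are the minimum; a non-negative slope (larger molecules
  eluting later) flags the curve as suspect and warns.  The packaged
  standards table lists the usual protein standard set (thyroglobulin
  670, γ-globulin 150, ovalbumin 44.3, ribonuclease A 13.7,
  p-aminobenzoic acid 0.137 kDa) with *synthetic* retention times on a
  plausible curve, because instrument retention times are not published;
  nothing quantitative depends on them.
* **Class integration** — boundaries default to (3, 10, 50) kDa, giving
  the classes <3, 3–10, 10–50 and >50 kDa.  Classes are half-open
  [low, high) on the mass axis, so a molecule of exactly 10 kDa belongs
  to 10–50 kDa; for continuous areas the edge choice only matters at
  isolated points.  Boundaries are mapped to retention-time cut points
  through the calibration; window areas are trapezoidal with the trace
  linearly interpolated at cut points, so class areas and pooled
  fractions sum to the total area exactly.  Negative signal is clipped
  to zero by default (`clip_negative=False` preserves the unbiased
  integral under symmetric noise; any window total that is negative —
  possible only from noise in unclipped mode — is floored at zero before
  forming percentages).  An optional linear baseline between two
  user-chosen time points can be subtracted first; it is off by default
  because baseline handling is instrument-specific.
* **Fraction pooling** — fixed-width windows tile the run from time
  zero, so with the default 1-minute width the fraction index equals the
  elution minute, matching how an automated fraction collector labels
  tubes on a 45-minute isocratic run.

## DPPH arithmetic

Scavenging = ((A0 − A1)/A0)·100 with A0 the control absorbance at
516 nm.  Negative values are reported with a warning, not clamped: they
indicate blank or turbidity problems worth surfacing.  A generic linear
standard-curve helper is provided unparameterised; no Trolox-equivalent
factors are shipped because no standard-curve parameters are available.

## Synthetic generators

All generators use NumPy's PCG64 (`default_rng`) and are bit-reproducible
per seed.

* **Activity databases** — unique random canonical peptides in a length
  range, round-robin assigned to labels.
* **Planted proteins** — a peptide is released *exactly* by the
  single-bond model iff cuts open both of its boundaries, which requires
  its final residue to be cleavable, no other residue cleavable, and its
  first residue not vetoed; each copy is preceded by one cleavable flank
  residue and embedded in background drawn from letters that are neither
  cleavable, vetoed, nor used by any planted peptide.  Under these
  constraints the per-activity occurrence count `a` and released count
  `d` are exact by construction (plantings that cannot satisfy them
  raise rather than degrade to approximate truth).
* **Chromatograms** — Gaussian peaks centred at the retention times of
  the requested masses, plus additive white noise.  Real SEC band shapes
  (tailing, fronting, detector drift, heteroscedastic noise) are not
  modelled; passing recovery tests therefore demonstrates correctness of
  the integration arithmetic, not robustness to real instrument
  pathologies.
* **Standards** — log10-masses on a known line plus Gaussian noise in
  log units (0.01 log-units is a realistic run-to-run wobble).

## Problem sizes used by the test and acceptance runs

Digest invariants are checked on 1000 random protein/rule instances
against a naive per-bond oracle; release-indicator bounds on 300 random
protein/database pairs; chromatogram class recovery on 500 noisy
replicates (noise s.d. = 1 % of the tallest peak, 0.02-min sampling,
clipping off) with mean absolute class error required under
0.5 percentage points; calibration-slope recovery on 1000 simulated
standard sets at 0.01 log-unit noise with mean relative error under 2 %.
The full rule recovery runs once (veto sizes 0–7, ≈ 138 000 veto sets).

## Known limitations

* The per-activity released-peptide counts of the study's tables depend
  on the full BIOPEP-UWM bioactive-peptide database, an external,
  versioned resource that is not redistributable here; the packaged
  50-entry database is a clearly-labelled synthetic stand-in, and the
  pipeline makes no attempt to reproduce those counts.  Only the
  arithmetic identities on the printed counts (Ae = d/N) are checked.
* The molecular-weight distribution percentages and DPPH bar values of
  the study's figures are laboratory measurements from unpublished
  chromatograms and absorbances; they are covered by synthetic-recovery
  properties instead.
* The recovered subtilisin rule is the minimal-complexity single-bond
  rule consistent with the six published cut counts; the tool that
  produced them may use wider context (P2/P2′ and beyond), which six
  integers cannot identify.
* Sequences are used exactly as given: no signal-peptide trimming,
  post-translational modification, or isoform handling.
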