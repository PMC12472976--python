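"""Reference constants for the six study proteins and the subtilisin rule.

The in silico digestion that produced the published theoretical degrees of
hydrolysis used subtilisin A (EC 3.4.21.62) with a specificity rule whose
residue sets were never published.  The rule can, however, be recovered
from published quantities alone: each protein's 2-decimal DHt together
with its printed length pins down the exact hydrolysed-bond count
``d = round(DHt·D/100)`` (neighbouring integer values of ``d`` change DHt
by at least 0.13 percentage points, so the rounding is invertible), and an
exhaustive search over single-bond cleavage rules then yields every rule
consistent with all six counts.

Two facts about that search, established by complete enumeration and
worth knowing before relying on it:

* No P1-only rule is consistent with all six proteins, and neither is any
  rule with a P1′ veto set of size ≤ 6.  Restricted to the three barley
  hordeins the P1-only search has a *unique* solution ({D,F,I,R,S,V,W,Y}),
  which badly over-predicts cleavage of the hemp proteins — barley-only
  calibration does not transfer across protein families in this grammar.
* The minimal-complexity rules consistent with all six counts have a
  7-residue veto set, and there are exactly two of them.  The one with the
  smaller P1 set (shipped here as :data:`SUBTILISIN_EC`'s default) is
  P1 = {A,F,G,I,K,L,M,V}, veto = {A,C,G,H,K,M,R} — a small/aliphatic
  hydrophobic P1 preference consistent with subtilisin's broad specificity.

:func:`recover_subtilisin_rule` repeats the recovery from scratch.
"""

from __future__ import annotations

from .proteolysis import CalibrationReport, EnzymeRule, calibrate_rule
from .sequences import ProteinRecord, load_fixtures

SUBTILISIN_EC = "3.4.21.62"

#: Published theoretical degree of hydrolysis (percent, 2 decimals) of each
#: study protein under the simulated subtilisin A digestion.
REPORTED_DHT: dict[str, float] = {
    "P06470": 26.03,
    "P06472": 20.19,
    "I6SW23": 24.40,
    "A0A090CXP9": 27.14,
    "A0A803Q1B3": 34.58,
    "A0A7J6FEU0": 31.16,
}

#: The reference subtilisin A rule recovered by
#: :func:`recover_subtilisin_rule` (cached here for direct use).
SUBTILISIN_RULE = EnzymeRule(
    name="subtilisin A",
    ec_number=SUBTILISIN_EC,
    p1_residues=frozenset("AFGIKLMV"),
    p1prime_block=frozenset("ACGHKMR"),
)


def derived_cut_counts(proteins: list[ProteinRecord] | None = None
                       ) -> dict[str, int]:
    """Hydrolysed-bond counts implied by the published DHt values.

    ``d = round(DHt · D / 100)`` per protein; exact because the printed
    2-decimal DHt changes by more than the print precision between
    neighbouring integer ``d``.
    """
    proteins = proteins if proteins is not None else load_fixtures()
    out = {}
    for p in proteins:
        if p.id not in REPORTED_DHT:
            raise KeyError(f"no published DHt for {p.id}")
        out[p.id] = int(round(REPORTED_DHT[p.id] * p.n_bonds / 100.0))
    return out


def recover_subtilisin_rule(max_block_size: int = 7) -> CalibrationReport:
    """Re-derive the subtilisin A rule from the six published cut counts.

    Runs the exhaustive calibration search over all P1 subsets with P1′
    veto sets of increasing size, stopping at the smallest size admitting
    a consistent rule (7; roughly a minute of search).  The report's
    ``best`` rule equals :data:`SUBTILISIN_RULE`.
    """
    proteins = load_fixtures()
    targets = derived_cut_counts(proteins)
    report = calibrate_rule(
        proteins, [targets[p.id] for p in proteins],
        max_block_size=max_block_size,
        name="subtilisin A", ec_number=SUBTILISIN_EC,
    )
    return report
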