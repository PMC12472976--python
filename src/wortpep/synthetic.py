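"""Synthetic inputs with exact, by-construction ground truth.

Every analysis stage can be exercised without external data: activity
databases of unique random peptides, proteins with planted bioactive
peptides that a given cleavage rule provably releases, chromatograms
assembled from Gaussian peaks of known class composition, and noisy
calibration standards from a known log-linear curve.  All generators are
deterministic per seed (NumPy PCG64 via ``default_rng``).

Planted-peptide construction
----------------------------
A peptide is released *exactly* by the single-bond cleavage model iff a
cut opens its N-terminal boundary and a cut closes its C-terminal one.
The generator therefore requires each planted peptide to end in a
cleavable (P1-set) residue, to contain no other P1 residue, and not to
start with a vetoed P1′ residue; each copy is preceded by a single P1
flank residue, and background residues are drawn from letters that are
neither cleavable, vetoed, nor used by any planted peptide.  Under these
rules the planted occurrence and release counts are exact, not merely
expected.  (A peptide whose final residue is not cleavable cannot be
released exactly by any flanking construction — the fragment would run on
to the next cut — and is rejected as infeasible.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bioactivity import ActivityDatabase
from .hpsec import CalibrationCurve, CalibrationStandard, Chromatogram, mw_to_rt
from .proteolysis import EnzymeRule
from .sequences import CANONICAL_AA, ProteinRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"


class InfeasiblePlantError(ValueError):
    """Raised when the requested planting cannot be realised exactly."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth echoed by a generator, reproducible per seed."""

    seed: int
    params: dict = field(default_factory=dict)
    planted_occurrences: dict = field(default_factory=dict)  # activity -> a
    planted_released: dict = field(default_factory=dict)     # activity -> d
    true_class_percentages: tuple[float, ...] = ()


def simulate_activity_db(n_entries: int,
                         length_range: tuple[int, int],
                         activities: Sequence[str],
                         seed: int) -> ActivityDatabase:
    """Unique random canonical peptides, each with one activity label."""
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    n_possible = sum(20 ** L for L in range(lo, hi + 1))
    if n_entries > n_possible:
        raise ValueError(f"cannot draw {n_entries} unique peptides of "
                         f"length {lo}-{hi}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    entries = []
    while len(entries) < n_entries:
        L = int(rng.integers(lo, hi + 1))
        pep = "".join(_AA[i] for i in rng.integers(0, 20, size=L))
        if pep in seen:
            continue
        seen.add(pep)
        entries.append((pep, str(activities[len(entries) % len(activities)])))
    return ActivityDatabase(entries)


def _check_releasable(pep: str, rule: EnzymeRule) -> None:
    if not pep:
        raise InfeasiblePlantError("empty planted peptide")
    if pep[-1] not in rule.p1_residues:
        raise InfeasiblePlantError(
            f"{pep!r}: final residue must be cleavable (in the P1 set) for "
            "exact release")
    if any(c in rule.p1_residues for c in pep[:-1]):
        raise InfeasiblePlantError(
            f"{pep!r}: non-terminal residues must not be cleavable")
    if pep[0] in rule.p1prime_block:
        raise InfeasiblePlantError(
            f"{pep!r}: first residue is vetoed at P1′ and would suppress the "
            "opening cut")


def simulate_protein(length: int,
                     rule: EnzymeRule,
                     planted: Sequence[tuple[str, str, int]],
                     seed: int) -> tuple[ProteinRecord, SyntheticTruth]:
    """A random protein from which ``rule`` releases the planted peptides.

    ``planted`` lists (peptide, activity, copies).  The generated record
    has exactly ``length`` residues; the returned truth gives the exact
    per-activity occurrence count ``a`` and released count ``d``.
    """
    peps = [(p.upper(), act, int(copies)) for p, act, copies in planted]
    for pep, _, copies in peps:
        if copies < 0:
            raise ValueError("copies must be >= 0")
        _check_releasable(pep, rule)
    live = [(p, a, c) for p, a, c in peps if c > 0]
    for i, (pi, _, _) in enumerate(live):
        for j, (pj, _, _) in enumerate(live):
            if i != j and pi in pj:
                raise InfeasiblePlantError(
                    f"planted peptide {pi!r} is a substring of {pj!r}; "
                    "occurrence counts would not be exact")

    planted_letters = {c for p, _, _ in live for c in p}
    flank_pool = sorted(rule.p1_residues - rule.p1prime_block - planted_letters)
    if not flank_pool:
        flank_pool = sorted(rule.p1_residues - rule.p1prime_block)
    if live and not flank_pool:
        raise InfeasiblePlantError(
            "no P1 residue available as a flank (all are vetoed at P1′)")
    background_pool = sorted(
        CANONICAL_AA - rule.p1_residues - rule.p1prime_block - planted_letters)
    if not background_pool:
        raise InfeasiblePlantError("no residues left for background filler")

    rng = np.random.default_rng(seed)
    copies_list = [pep for pep, _, c in live for _ in range(c)]
    rng.shuffle(copies_list)
    core = sum(len(p) + 1 for p in copies_list)  # +1 per left flank
    n_fill = length - core
    if n_fill < 0:
        raise InfeasiblePlantError(
            f"length {length} cannot accommodate the planted copies "
            f"(need >= {core})")
    # Split the filler over the gaps around the planted copies.
    n_gaps = len(copies_list) + 1
    gap_sizes = rng.multinomial(n_fill, np.full(n_gaps, 1.0 / n_gaps))
    parts = []
    for gap, pep in zip(gap_sizes, copies_list + [None]):
        parts.append("".join(
            background_pool[i]
            for i in rng.integers(0, len(background_pool), size=int(gap))))
        if pep is not None:
            parts.append(str(rng.choice(flank_pool)))
            parts.append(pep)
    sequence = "".join(parts)
    assert len(sequence) == length

    occ: dict[str, int] = {}
    rel: dict[str, int] = {}
    for _, act, _ in peps:
        occ.setdefault(act, 0)
        rel.setdefault(act, 0)
    for _, act, c in live:
        occ[act] += c
        rel[act] += c
    record = ProteinRecord(id=f"synthetic-{seed}", name="synthetic protein",
                           sequence=sequence)
    truth = SyntheticTruth(
        seed=seed,
        params={"length": length, "rule": rule.name,
                "planted": [tuple(p) for p in planted]},
        planted_occurrences=occ,
        planted_released=rel,
    )
    return record, truth


def _class_index(mass_kda: float, boundaries: Sequence[float]) -> int:
    """Half-open classes [low, high): a mass exactly on a boundary belongs
    to the heavier class."""
    for i, b in enumerate(boundaries):
        if mass_kda < b:
            return i
    return len(boundaries)


def simulate_chromatogram(peaks: Sequence[tuple[float, float, float]],
                          curve: CalibrationCurve,
                          noise_sd: float,
                          sampling_interval_min: float,
                          seed: int,
                          *,
                          boundaries_kda: Sequence[float] = (3.0, 10.0, 50.0),
                          t_range: tuple[float, float] = (0.0, 45.0),
                          detector: str = "UV280",
                          ) -> tuple[Chromatogram, SyntheticTruth]:
    """Gaussian peaks at the retention times of the given masses.

    ``peaks`` lists (mass_kda, area, width_min); white Gaussian noise of
    standard deviation ``noise_sd`` is added.  The truth records the class
    percentages implied by the peak areas and ``boundaries_kda``.
    """
    if not peaks:
        raise ValueError("need at least one peak")
    for mass, area, width in peaks:
        if area < 0 or width <= 0:
            raise ValueError("peak areas must be >= 0 and widths > 0")
        if not curve.in_range(mw_to_rt(curve, mass)):
            raise ValueError(f"peak mass {mass} kDa elutes outside the "
                             "calibration range")
    rng = np.random.default_rng(seed)
    t = np.arange(t_range[0], t_range[1] + 1e-12, sampling_interval_min)
    signal = np.zeros_like(t)
    for mass, area, width in peaks:
        mu = mw_to_rt(curve, mass)
        signal += area / (width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - mu) / width) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=t.size)
    total = sum(area for _, area, _ in peaks)
    class_areas = np.zeros(len(boundaries_kda) + 1)
    for mass, area, _ in peaks:
        class_areas[_class_index(mass, boundaries_kda)] += area
    truth = SyntheticTruth(
        seed=seed,
        params={"peaks": [tuple(p) for p in peaks], "noise_sd": noise_sd,
                "sampling_interval_min": sampling_interval_min,
                "boundaries_kda": tuple(boundaries_kda),
                "t_range": tuple(t_range)},
        true_class_percentages=tuple(100.0 * a / total for a in class_areas),
    )
    return Chromatogram(detector, t, signal), truth


def simulate_standards(slope: float,
                       intercept: float,
                       retention_times_min: Sequence[float],
                       noise_sd_log: float,
                       seed: int) -> tuple[list[CalibrationStandard],
                                           SyntheticTruth]:
    """Standards whose log10-masses sit on a known line, plus noise.

    ``noise_sd_log`` is the standard deviation of the additive noise on
    log10(mass/kDa) — 0.01 log-units is a realistic run-to-run wobble.
    """
    rng = np.random.default_rng(seed)
    rts = np.asarray(retention_times_min, dtype=float)
    logm = slope * rts + intercept + rng.normal(0.0, noise_sd_log, rts.size)
    standards = [
        CalibrationStandard(f"std-{i+1}", float(10.0 ** lm), float(rt))
        for i, (rt, lm) in enumerate(zip(rts, logm))
    ]
    truth = SyntheticTruth(
        seed=seed,
        params={"slope": slope, "intercept": intercept,
                "noise_sd_log": noise_sd_log,
                "retention_times_min": tuple(float(x) for x in rts)},
    )
    return standards, truth
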