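"""Peptide-activity matching and the release indicators A, Ae and W.

Given a database of (peptide sequence, activity label) pairs, three
indicators summarise how rich a protein is in bioactive fragments and how
well a simulated digestion releases them:

* occurrence frequency  ``A  = a / N``  — ``a`` counts every (entry,
  start-position) substring match of a database peptide with the given
  activity inside the intact chain (overlaps and repeats all count);
* release frequency     ``Ae = d / N``  — ``d`` counts released peptides
  whose full sequence equals a database entry with the activity
  (duplicate released peptides each count);
* relative release      ``W  = Ae / A`` — the fraction of the potential
  that the enzyme actually liberates, in [0, 1] because an exact released
  match is in particular an intact-sequence occurrence.

``N`` is the chain length.  A release profile collects, per activity, the
quadruple (d, Ae, A, W) together with the digestion's DHt — one table
block per protein, matching the layout used to report such analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .proteolysis import DigestResult, EnzymeRule, digest, theoretical_dh
from .sequences import ProteinRecord, validate_sequence

AE_DECIMALS = 4
DHT_DECIMALS = 2


def _norm(label: str) -> str:
    """Activity labels compare case-insensitively after trimming."""
    return " ".join(label.split()).lower()


@dataclass(frozen=True)
class ActivityEntry:
    sequence: str
    activity: str

    @property
    def activity_key(self) -> str:
        return _norm(self.activity)


class ActivityDatabase:
    """A peptide-sequence → activity-label lookup.

    Entries are (canonical peptide, free-text label); the (sequence,
    normalised label) pairs must be unique.  A small packaged database of
    synthetic entries is available via :meth:`load_fixture`; it covers the
    activity classes relevant to cereal/hemp proteins but makes no claim
    to reproduce any external database's coverage.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        seen = set()
        self.entries: list[ActivityEntry] = []
        for seq, act in entries:
            validate_sequence(seq, record_id=f"db entry {seq!r}")
            e = ActivityEntry(seq, act)
            key = (seq, e.activity_key)
            if key in seen:
                raise ValueError(f"duplicate database entry {key}")
            seen.add(key)
            self.entries.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def activities(self) -> list[str]:
        """Distinct normalised activity labels, sorted."""
        return sorted({e.activity_key for e in self.entries})

    def sequences_for(self, activity: str) -> list[str]:
        key = _norm(activity)
        return [e.sequence for e in self.entries if e.activity_key == key]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityDatabase":
        """Read a two-column tab-separated table: ``sequence``, ``activity``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
        if not {"sequence", "activity"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'sequence' and 'activity'")
        return cls(zip(df["sequence"], df["activity"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.sequence, e.activity) for e in self.entries],
            columns=["sequence", "activity"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def load_fixture(cls) -> "ActivityDatabase":
        """The packaged synthetic activity database (v1, 50 entries)."""
        ref = resources.files("wortpep.data").joinpath(
            "activity_db_synthetic.tsv")
        with resources.as_file(ref) as p:
            return cls.from_tsv(p)


def _count_substring(hay: str, needle: str) -> int:
    """Occurrences of ``needle`` in ``hay``, counting overlaps."""
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def count_occurrences(sequence: str, db: ActivityDatabase,
                      activity: str) -> int:
    """``a`` — substring matches of all entries with ``activity`` in the
    intact sequence, overlapping and repeated matches each counted."""
    return sum(_count_substring(sequence, pep)
               for pep in db.sequences_for(activity))


def frequency_A(protein: ProteinRecord, db: ActivityDatabase,
                activity: str) -> float:
    """Occurrence frequency A = a/N, to 4 decimals."""
    return round(count_occurrences(protein.sequence, db, activity)
                 / protein.length_aa, AE_DECIMALS)


def released_matches(result: DigestResult, db: ActivityDatabase,
                     activity: str) -> int:
    """``d`` — released peptides whose full sequence carries ``activity``
    (each released instance counts, including duplicates)."""
    entries = set(db.sequences_for(activity))
    return sum(1 for pep in result.peptide_sequences if pep in entries)


def frequency_Ae(d: int, n: int) -> float:
    """Release frequency Ae = d/N, to 4 decimals."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if d < 0:
        raise ValueError("d must be >= 0")
    return round(d / n, AE_DECIMALS)


def relative_W(ae: float, a: float) -> float:
    """Relative release W = Ae/A, to 4 decimals.

    By convention W = 0 when A = Ae = 0 (no potential, nothing released);
    such rows are flagged ``undefined`` in profiles.  Ae > 0 with A = 0 is
    impossible when both come from the same matching and indicates an
    internal inconsistency.
    """
    if a == 0:
        if ae == 0:
            return 0.0
        raise ValueError("Ae > 0 with A = 0: inconsistent indicator inputs")
    return round(ae / a, AE_DECIMALS)


@dataclass(frozen=True)
class ActivityRow:
    activity: str
    d: int
    ae: float
    a_freq: float
    w: float


@dataclass(frozen=True)
class ReleaseProfile:
    """Per-activity release summary of one protein under one rule.

    Rows are sorted by descending released count then activity label, and
    activities with no released peptide are omitted, mirroring how such
    tables are reported.
    """

    protein_id: str
    dht_percent: float
    rows: tuple[ActivityRow, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(self.protein_id, self.dht_percent, r.activity, r.d, r.ae,
              r.a_freq, r.w) for r in self.rows],
            columns=["protein_id", "dht_percent", "activity",
                     "n_peptides", "Ae", "A", "W"],
        )
        if df.empty:  # keep the DHt visible even with no released activity
            df = pd.DataFrame(
                [(self.protein_id, self.dht_percent, None, 0, 0.0, 0.0, 0.0)],
                columns=df.columns,
            )
        return df


def profile(protein: ProteinRecord, rule: EnzymeRule,
            db: ActivityDatabase) -> ReleaseProfile:
    """Digest once and tabulate (d, Ae, A, W) for every released activity."""
    result = digest(protein, rule)
    dht = theoretical_dh(result, protein)
    rows = []
    for activity in db.activities():
        d = released_matches(result, db, activity)
        if d == 0:
            continue
        ae = frequency_Ae(d, protein.length_aa)
        a_freq = frequency_A(protein, db, activity)
        # Unrounded ratio; rounding A and Ae first can push W above 1.
        a_exact = count_occurrences(protein.sequence, db, activity)
        w = round(d / a_exact, AE_DECIMALS)
        rows.append(ActivityRow(activity, d, ae, a_freq, w))
    rows.sort(key=lambda r: (-r.d, r.activity))
    return ReleaseProfile(protein.id, dht, tuple(rows))


def profiles_frame(proteins: Sequence[ProteinRecord], rule: EnzymeRule,
                   db: ActivityDatabase) -> pd.DataFrame:
    """Concatenated release profiles for several proteins."""
    return pd.concat([profile(p, rule, db).to_frame() for p in proteins],
                     ignore_index=True)
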