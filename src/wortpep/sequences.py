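"""Protein sequence records, FASTA I/O and sequence-derived quantities.

The analysis operates on intact protein chains identified by a short
accession (UniProt style).  A record knows its residue count ``N`` and the
number of peptide bonds ``D = N - 1``, the two denominators used by the
release indicators and the theoretical degree of hydrolysis.  Average
molecular masses follow the standard average (not monoisotopic) residue
mass table, which is what UniProt prints for protein entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight

#: The 20 canonical amino-acid one-letter codes.  Ambiguity and rare codes
#: (B, J, O, U, X, Z) are rejected by default.
CANONICAL_AA: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accessions of the six study proteins shipped with the package, in
#: presentation order (three barley hordeins, then three hemp proteins).
FIXTURE_IDS = (
    "P06470",
    "P06472",
    "I6SW23",
    "A0A090CXP9",
    "A0A803Q1B3",
    "A0A7J6FEU0",
)

BARLEY_IDS = FIXTURE_IDS[:3]
HEMP_IDS = FIXTURE_IDS[3:]


class SequenceValidationError(ValueError):
    """Raised when a sequence contains non-canonical residues or is empty."""


def validate_sequence(sequence: str, *, record_id: str = "<sequence>",
                      allow_x: bool = False) -> None:
    """Validate that ``sequence`` is non-empty and canonical.

    With ``allow_x=True`` the placeholder residue ``X`` is tolerated (it is
    excluded from mass computation and never matches database entries);
    every other non-canonical letter is always an error.
    """
    if not sequence:
        raise SequenceValidationError(f"{record_id}: empty sequence")
    allowed = CANONICAL_AA | ({"X"} if allow_x else set())
    for pos, ch in enumerate(sequence, start=1):
        if ch not in allowed:
            raise SequenceValidationError(
                f"{record_id}: non-canonical residue {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein chain.

    Attributes
    ----------
    id:
        Short identifier, e.g. a UniProt accession.
    name:
        Free-text description (may be empty).
    sequence:
        Upper-case residue string over the canonical alphabet.
    declared_mass_kda:
        Optional reference mass in kDa (as printed by the source database);
        ``None`` when unknown.
    """

    id: str
    name: str
    sequence: str
    declared_mass_kda: float | None = None
    allow_x: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record_id=self.id, allow_x=self.allow_x)

    @property
    def length_aa(self) -> int:
        """Residue count ``N``."""
        return len(self.sequence)

    @property
    def n_bonds(self) -> int:
        """Number of peptide bonds ``D = N - 1``."""
        return self.length_aa - 1


def read_fasta(path: str | Path, *, allow_x: bool = False) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Headers are parsed as ``id [whitespace] free-text name``.  Sequences are
    upper-cased, whitespace-stripped and validated against the canonical
    alphabet; multi-line (wrapped) sequences are accepted.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        records.append(
            ProteinRecord(
                id=rec.id,
                name=rec.description[len(rec.id):].strip(),
                sequence=seq,
                allow_x=allow_x,
            )
        )
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to ``path`` in FASTA format (60-column wrapping)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def load_fixtures() -> list[ProteinRecord]:
    """Return the six packaged study proteins.

    Three *Hordeum vulgare* (barley) hordeins — B1-hordein P06470, C-hordein
    P06472, D-hordein I6SW23 — followed by three *Cannabis sativa* (hemp)
    proteins — 11S seed storage protein A0A090CXP9, bifunctional protein
    A0A803Q1B3 and storage protein A0A7J6FEU0.
    """
    ref = resources.files("wortpep.data").joinpath("proteins.fasta")
    with resources.as_file(ref) as p:
        records = read_fasta(p)
    order = {acc: i for i, acc in enumerate(FIXTURE_IDS)}
    records.sort(key=lambda r: order[r.id])
    # Declared masses from the source database, in kDa.
    declared = {
        "P06470": 33.422, "P06472": 12.180, "I6SW23": 79.350,
        "A0A090CXP9": 55.974, "A0A803Q1B3": 21.640, "A0A7J6FEU0": 45.680,
    }
    return [
        ProteinRecord(r.id, r.name, r.sequence, declared_mass_kda=declared[r.id])
        for r in records
    ]


def average_mass_kda(sequence: str) -> float:
    """Average molecular mass of a protein chain in kDa, to 3 decimals.

    Sum of standard average residue masses plus one water.  ``X`` residues
    (if present in a tolerant record) are excluded from the sum.
    """
    if not sequence:
        raise SequenceValidationError("cannot compute mass of an empty sequence")
    core = sequence.replace("X", "")
    if not core:
        raise SequenceValidationError("sequence contains only X residues")
    validate_sequence(core)
    mass_da = molecular_weight(core, seq_type="protein", monoisotopic=False)
    return round(mass_da / 1000.0, 3)
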