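"""Sequence and alignment data model with FASTA/PHYLIP I/O.

Alignments are ordered collections of equal-length sequence records over a
single alphabet. Gap ('-') and ambiguity characters (IUPAC nucleotide codes,
'X' for proteins) are preserved on input and treated as missing data by the
downstream likelihood and composition machinery.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from canaryseq.errors import AlignmentError


class Alphabet(enum.Enum):
    NUCLEOTIDE = "nucleotide"
    PROTEIN = "protein"


#: Concrete (unambiguous, non-gap) states per alphabet, in canonical order.
CONCRETE_STATES: dict[Alphabet, str] = {
    Alphabet.NUCLEOTIDE: "ACGT",
    Alphabet.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
}

#: IUPAC nucleotide ambiguity codes mapped to the concrete states they allow.
NUC_AMBIGUITY: dict[str, str] = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def state_sets(alphabet: Alphabet) -> dict[str, str]:
    """Map every legal character to the set of concrete states it may be.

    Gaps and fully ambiguous codes map to all states (missing data).
    """
    concrete = CONCRETE_STATES[alphabet]
    table = {c: c for c in concrete}
    table["-"] = concrete
    if alphabet is Alphabet.NUCLEOTIDE:
        table.update(NUC_AMBIGUITY)
    else:
        table["X"] = concrete
    return table


_NEWICK_RESERVED = set("(),:;")


@dataclass(frozen=True)
class SequenceRecord:
    """A single aligned sequence: an id, its residues, and the alphabet.

    Residues are case-folded to upper case on construction. Ids must be
    usable verbatim as Newick leaf labels, so whitespace and the characters
    ``( ) , : ;`` are rejected.
    """

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence id must be non-empty")
        if any(ch.isspace() or ch in _NEWICK_RESERVED for ch in self.id):
            raise AlignmentError(
                f"sequence id {self.id!r} contains whitespace or a "
                "Newick-reserved character ( ) , : ;"
            )
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise AlignmentError(f"sequence {self.id!r} has no residues")
        legal = state_sets(self.alphabet)
        for pos, ch in enumerate(residues):
            if ch not in legal:
                raise AlignmentError(
                    f"sequence {self.id!r}: invalid character {ch!r} at "
                    f"position {pos + 1} for alphabet {self.alphabet.value}"
                )

    def __len__(self) -> int:
        return len(self.residues)


class DatasetRole(enum.Enum):
    """Role of an alignment within the canary classification pipeline."""

    FULL = "full"
    BASE = "base"
    INTEREST = "interest"
    CHECKING = "checking"
    CANARY = "canary"
    CANARY_CHECKING = "canary_checking"
    MINIMAL = "minimal"


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple sequence alignment over one alphabet."""

    records: tuple[SequenceRecord, ...]
    role: DatasetRole | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise AlignmentError("alignment must contain at least one sequence")
        ncols = len(records[0])
        seen: set[str] = set()
        alphabet = records[0].alphabet
        for rec in records:
            if rec.id in seen:
                raise AlignmentError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if rec.alphabet is not alphabet:
                raise AlignmentError(
                    f"sequence {rec.id!r} has alphabet {rec.alphabet.value}, "
                    f"expected {alphabet.value}"
                )
            if len(rec) != ncols:
                raise AlignmentError(
                    f"sequence {rec.id!r} has length {len(rec)}, "
                    f"expected {ncols} (ragged alignment)"
                )

    @property
    def ncols(self) -> int:
        return len(self.records[0])

    @property
    def alphabet(self) -> Alphabet:
        return self.records[0].alphabet

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def __contains__(self, seq_id: str) -> bool:
        return any(rec.id == seq_id for rec in self.records)

    def with_role(self, role: DatasetRole) -> "Alignment":
        return Alignment(self.records, role=role)

    def subset(self, ids: Iterable[str], role: DatasetRole | None = None) -> "Alignment":
        """Alignment restricted to *ids*, preserving current record order."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise AlignmentError(f"unknown sequence ids: {sorted(unknown)}")
        return Alignment(
            tuple(rec for rec in self.records if rec.id in wanted), role=role
        )


#: kept id -> ids of exact duplicates removed in its favour.
DedupMap = dict[str, list[str]]


def make_alignment(
    pairs: Sequence[tuple[str, str]],
    alphabet: Alphabet = Alphabet.NUCLEOTIDE,
    role: DatasetRole | None = None,
) -> Alignment:
    """Convenience constructor from (id, residues) pairs."""
    return Alignment(
        tuple(SequenceRecord(i, r, alphabet) for i, r in pairs), role=role
    )


def read_alignment(
    path: str | Path, format: str = "fasta",
    alphabet: Alphabet = Alphabet.NUCLEOTIDE,
) -> Alignment:
    """Read an aligned FASTA or relaxed PHYLIP file.

    The id of a FASTA record is the header token up to the first whitespace.
    Residues are upper-cased; record order is preserved. Raises
    :class:`AlignmentError` on ragged rows (naming the offending id),
    duplicate ids, or characters illegal for *alphabet*.
    """
    path = Path(path)
    if format == "fasta":
        bio_records = list(SeqIO.parse(str(path), "fasta"))
    elif format == "phylip":
        try:
            with open(path) as handle:
                bio_records = list(AlignIO.read(handle, "phylip-relaxed"))
        except ValueError as exc:
            raise AlignmentError(f"cannot parse {path} as relaxed PHYLIP: {exc}") from exc
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not bio_records:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment(
        tuple(SequenceRecord(rec.id, str(rec.seq), alphabet) for rec in bio_records)
    )


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write *aln* to *path*; round-trips ids, order and residues exactly."""
    bio_records = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description="")
        for rec in aln.records
    ]
    if format == "fasta":
        SeqIO.write(bio_records, str(path), "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(bio_records), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def deduplicate(aln: Alignment) -> tuple[Alignment, DedupMap]:
    """Collapse exact residue-string duplicates (gaps included).

    The first occurrence in input order is kept; the returned map sends each
    kept id to the ids removed in its favour (empty lists omitted).
    """
    first_by_residues: dict[str, str] = {}
    kept: list[SequenceRecord] = []
    dedup: DedupMap = {}
    for rec in aln.records:
        owner = first_by_residues.get(rec.residues)
        if owner is None:
            first_by_residues[rec.residues] = rec.id
            kept.append(rec)
        else:
            dedup.setdefault(owner, []).append(rec.id)
    return Alignment(tuple(kept), role=aln.role), dedup


def partition_roles(
    aln: Alignment, interest_ids: Iterable[str]
) -> tuple[Alignment, list[SequenceRecord]]:
    """Split a full alignment into the base alignment and interest records.

    The base alignment is the full alignment minus the sequences of
    interest, preserving order; it must retain at least four sequences for
    unrooted tree comparisons to be defined.
    """
    interest = set(interest_ids)
    unknown = interest - set(aln.ids)
    if unknown:
        raise AlignmentError(
            f"interest ids not present in alignment: {sorted(unknown)}"
        )
    base_records = tuple(rec for rec in aln.records if rec.id not in interest)
    interest_records = [rec for rec in aln.records if rec.id in interest]
    if len(base_records) < 4:
        raise AlignmentError(
            f"base dataset would retain only {len(base_records)} sequences; "
            "at least 4 are required for unrooted comparisons"
        )
    return Alignment(base_records, role=DatasetRole.BASE), interest_records
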