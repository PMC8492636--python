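"""Sequence data model, FASTA I/O and elementary nucleotide transforms.

Sequences are stored uppercase over the strict DNA alphabet ``{A,C,G,T,N}``
or RNA alphabet ``{A,C,G,U,N}``; the alphabet of each record is auto-detected
on input (presence of ``U`` marks RNA, presence of ``T`` marks DNA; a
sequence with neither is treated as DNA).  Internal coordinates throughout
the package are 0-based half-open; every user-facing report is 1-based
inclusive (MISA-style).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Alphabet(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


class Arm(str, enum.Enum):
    """Arm of the pre-miRNA hairpin a mature miRNA derives from."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA content."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified nucleotide sequence (DNA or RNA).

    Residues are normalised to uppercase at construction and validated
    against the declared alphabet.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise SequenceError(f"sequence {self.id!r}: residues must be non-empty")
        allowed = DNA_ALPHABET if self.alphabet is Alphabet.DNA else RNA_ALPHABET
        for pos, ch in enumerate(residues):
            if ch not in allowed:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal {self.alphabet.value} "
                    f"character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MatureMiRNA:
    """An annotated mature miRNA with its arm of origin.

    The arm matters because the primer rule differs between 5p and 3p
    products.  Sequences shorter than 15 nt are rejected; 15–17 nt is
    accepted with a warning (mature plant miRNAs are typically 18–24 nt).
    """

    name: str
    sequence: str
    arm: Arm
    precursor_id: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SequenceError("miRNA name must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= (DNA_ALPHABET | RNA_ALPHABET):
            raise SequenceError(f"miRNA {self.name!r}: illegal characters in sequence")
        if len(seq) < 15:
            raise SequenceError(
                f"miRNA {self.name!r}: length {len(seq)} < 15, too short for a primer"
            )
        if len(seq) < 18:
            warnings.warn(
                f"miRNA {self.name!r} is only {len(seq)} nt (typical mature "
                f"miRNAs are 18-24 nt)",
                stacklevel=2,
            )
        if not isinstance(self.arm, Arm):
            raise SequenceError(f"miRNA {self.name!r}: arm must be an Arm value")


def detect_alphabet(residues: str) -> Alphabet:
    """DNA unless the sequence contains U (U and T together is an error)."""
    upper = set(residues.upper())
    has_u = "U" in upper
    has_t = "T" in upper
    if has_u and has_t:
        raise SequenceError("sequence mixes U and T")
    return Alphabet.RNA if has_u else Alphabet.DNA


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into :class:`NucleotideSequence` objects.

    Residues are uppercased; the alphabet is auto-detected per record.
    Duplicate record ids and illegal characters raise :class:`SequenceError`.
    """
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: record with empty id")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        try:
            alphabet = detect_alphabet(residues)
            records.append(
                NucleotideSequence(
                    id=rec.id,
                    residues=residues,
                    description=rec.description[len(rec.id):].strip(),
                    alphabet=alphabet,
                )
            )
        except SequenceError as exc:
            raise SequenceError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def reverse_complement(residues: str) -> str:
    """Watson–Crick reverse complement of a DNA string; N maps to N."""
    upper = residues.upper()
    if not set(upper) <= DNA_ALPHABET:
        bad = sorted(set(upper) - DNA_ALPHABET)
        raise SequenceError(f"reverse_complement requires DNA; illegal characters {bad}")
    return upper.translate(_COMPLEMENT)[::-1]


def rna_to_dna(residues: str) -> str:
    """Back-transcribe RNA to DNA (U→T); DNA passes through unchanged."""
    upper = residues.upper()
    if not set(upper) <= (DNA_ALPHABET | RNA_ALPHABET):
        bad = sorted(set(upper) - (DNA_ALPHABET | RNA_ALPHABET))
        raise SequenceError(f"illegal nucleotide characters {bad}")
    if "U" in upper and "T" in upper:
        raise SequenceError("sequence mixes U and T")
    return upper.replace("U", "T")


def parse_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA with the arm encoded in the header.

    Header dialect: ``>name|arm=5p`` or ``>name|arm=3p`` (an optional
    ``|precursor=<id>`` field is honoured).  Example::

        >mir171g|arm=5p|precursor=MIR171G
        UGAUUGAGCCGUGCCAAUAUC
    """
    out: list[MatureMiRNA] = []
    for rec in read_fasta(path):
        fields = rec.id.split("|")
        name = fields[0]
        arm: Arm | None = None
        precursor = None
        for fld in fields[1:]:
            if fld.startswith("arm="):
                value = fld[4:]
                try:
                    arm = {"5p": Arm.FIVE_PRIME, "3p": Arm.THREE_PRIME}[value]
                except KeyError:
                    raise SequenceError(
                        f"{path}: record {rec.id!r}: arm must be 5p or 3p, got {value!r}"
                    ) from None
            elif fld.startswith("precursor="):
                precursor = fld[10:]
        if arm is None:
            raise SequenceError(
                f"{path}: record {rec.id!r}: missing |arm=5p / |arm=3p header field"
            )
        out.append(MatureMiRNA(name=name, sequence=rec.residues, arm=arm, precursor_id=precursor))
    return out


def write_mirna_fasta(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    """Write mature miRNAs using the ``|arm=`` header dialect."""
    seqs = []
    for m in mirnas:
        header = f"{m.name}|arm={m.arm.value}"
        if m.precursor_id:
            header += f"|precursor={m.precursor_id}"
        seqs.append(NucleotideSequence(id=header, residues=m.sequence,
                                       alphabet=detect_alphabet(m.sequence)))
    write_fasta(seqs, path)
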