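"""Core sequence domain types and FASTA I/O shared by all pipeline stages.

Conventions used throughout the package:

* All internal scanning is done on the RNA alphabet; DNA inputs are
  transcribed (T -> U) on read, so there is a single scoring code path.
* Coordinates are 1-based, fully closed intervals on the sense strand of
  the transcript they refer to.
* Sequence identifiers are unique within a collection and stored verbatim;
  residues are stored uppercase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VARIANT_SUFFIX = re.compile(r"(-[35]p)?$")
_TRAILING_LETTER = re.compile(r"([a-z])$")


@dataclass(frozen=True)
class Sequence:
    """A named nucleotide sequence over {A, C, G, U/T, N}.

    Parameters
    ----------
    id : str
        Nonempty identifier, unique within a collection.
    seq : str
        Nonempty residue string; case-insensitive on input, stored uppercase.
    moltype : {"rna", "dna"}
        Declared alphabet. RNA uses U, DNA uses T.
    """

    id: str
    seq: str
    moltype: str = "rna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("rna", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        upper = self.seq.upper()
        object.__setattr__(self, "seq", upper)
        alphabet = RNA_ALPHABET if self.moltype == "rna" else DNA_ALPHABET
        bad = set(upper) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


def transcribe(s: Sequence) -> Sequence:
    """Return the RNA version of a sequence (T -> U); RNA passes through."""
    if s.moltype == "rna":
        return s
    return Sequence(s.id, s.seq.replace("T", "U"), "rna")


def reverse_transcribe(s: Sequence) -> Sequence:
    """Return the DNA version of a sequence (U -> T); DNA passes through."""
    if s.moltype == "dna":
        return s
    return Sequence(s.id, s.seq.replace("U", "T"), "dna")


def reverse_complement(s: Sequence) -> Sequence:
    """Antiparallel complement in the same moltype. N is self-complementary.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    table = _RNA_COMPLEMENT if s.moltype == "rna" else _DNA_COMPLEMENT
    return Sequence(s.id, s.seq.translate(table)[::-1], s.moltype)


def mirna_family(mirna_id: str, collapse: bool = True) -> str:
    """Family key for a miRNA name.

    Strips a single "-3p"/"-5p" arm suffix and then a single trailing
    lowercase letter variant, so e.g. ``ath-miR842a-5p -> ath-miR842``.
    With ``collapse=False`` the id is returned unchanged.
    """
    if not collapse:
        return mirna_id
    stripped = _VARIANT_SUFFIX.sub("", mirna_id, count=1)
    return _TRAILING_LETTER.sub("", stripped, count=1)


@dataclass(frozen=True)
class MiRNA:
    """A mature microRNA: id, grouping family, sequence and age class.

    ``family`` defaults to :func:`mirna_family` applied to the id; ``age``
    distinguishes genus-restricted ("young") from widespread ("ancient")
    miRNAs, with "unknown" when no homology evidence has been supplied.
    """

    id: str
    mature: Sequence
    family: str = ""
    age: str = "unknown"

    def __post_init__(self) -> None:
        if self.mature.moltype != "rna":
            object.__setattr__(self, "mature", transcribe(self.mature))
        if not (15 <= len(self.mature) <= 30):
            raise ValueError(
                f"miRNA {self.id!r}: mature length {len(self.mature)} "
                "outside [15, 30]"
            )
        if self.age not in ("young", "ancient", "unknown"):
            raise ValueError(f"miRNA {self.id!r}: bad age {self.age!r}")
        if not self.family:
            object.__setattr__(self, "family", mirna_family(self.id))


@dataclass(frozen=True)
class Transcript:
    """A target transcript with a region annotation tag (cds/cdna/utr)."""

    gene_id: str
    seq: Sequence
    region: str = "cdna"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("transcript gene_id must be nonempty")
        if self.region not in ("cds", "cdna", "utr"):
            raise ValueError(
                f"transcript {self.gene_id!r}: bad region {self.region!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, moltype: str = "rna") -> list[Sequence]:
    """Read a FASTA file into an order-preserving list of :class:`Sequence`.

    T/U is normalised to the declared ``moltype``. Duplicate ids and illegal
    characters are rejected with an error naming the offending record.
    """
    if moltype not in ("rna", "dna"):
        raise ValueError(f"unknown moltype {moltype!r}")
    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        raw = raw.replace("T", "U") if moltype == "rna" else raw.replace("U", "T")
        try:
            out.append(Sequence(rec.id, raw, moltype))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[Sequence], path: str | Path, wrap: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), wrap):
                fh.write(s.seq[i : i + wrap] + "\n")


def read_transcripts(
    path: str | Path, region: str = "cdna"
) -> list[Transcript]:
    """Read transcripts from FASTA, transcribing to RNA for scanning."""
    return [
        Transcript(s.id, s, region)
        for s in read_fasta(path, moltype="rna")
    ]


def read_mirnas(path: str | Path, ages: dict[str, str] | None = None) -> list[MiRNA]:
    """Read mature miRNAs from FASTA; ``ages`` optionally maps id -> age."""
    ages = ages or {}
    return [
        MiRNA(s.id, s, age=ages.get(s.id, "unknown"))
        for s in read_fasta(path, moltype="rna")
    ]
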