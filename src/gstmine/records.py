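"""Core sequence types, FASTA I/O, translation and reverse complement.

Transcripts are contigs from a de novo transcriptome assembly; proteins are
either deduced translations or labelled reference-panel members.  All
sequences are stored upper-case; RNA ``U`` is mapped to ``T`` on read.
Coordinates everywhere in this package are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: amino-acid alphabet allowed in raw frame translations
AA_EXTENDED = AA_ALPHABET | {"X", "*"}

FRAMES = (1, 2, 3, -1, -2, -3)


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


@dataclass
class TranscriptRecord:
    """A contig/transcript nucleotide sequence with its assembly of origin."""

    id: str
    seq: str
    assembly: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid nucleotide(s) {sorted(bad)}"
            )

    @property
    def length_bp(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally carrying a class/subclass label.

    Reference-panel members carry ``label`` of the form ``"class|subclass"``
    (e.g. ``"cytosolic|Delta"``), parsed from the FASTA description.
    """

    id: str
    seq: str
    label: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        body, terminal = self.seq[:-1], self.seq[-1]
        if "*" in body:
            raise ValueError(f"protein {self.id!r}: internal stop codon")
        allowed = AA_ALPHABET | {"X"}
        bad = (set(body) - allowed) | ({terminal} - (allowed | {"*"}))
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid residue(s) {sorted(bad)}")

    @property
    def length_aa(self) -> int:
        return len(self.seq.rstrip("*"))

    @property
    def gst_class(self) -> str:
        return self.label.split("|")[0] if self.label else ""

    @property
    def subclass(self) -> str:
        parts = self.label.split("|")
        return parts[1] if len(parts) > 1 else ""


def _parse_header(rec: SeqRecord) -> tuple[str, str]:
    ident = rec.id
    desc = rec.description
    if desc.startswith(ident):
        desc = desc[len(ident):].strip()
    return ident, desc


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list:
    """Read a FASTA file into transcript or protein records.

    Parameters
    ----------
    path : file path
    kind : ``"nucleotide"`` or ``"protein"``

    Records are returned in file order.  The id is the first
    whitespace-delimited header token; the remainder is kept as description
    (and, for proteins, as the class/subclass label when it looks like one).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out = []
    for rec in records:
        ident, desc = _parse_header(rec)
        if ident in seen:
            raise FastaError(f"{path}: duplicate record id {ident!r}")
        seen.add(ident)
        if kind == "nucleotide":
            out.append(TranscriptRecord(ident, str(rec.seq), description=desc))
        elif kind == "protein":
            label = desc.split()[0] if desc and "|" in desc.split()[0] else ""
            out.append(ProteinRecord(ident, str(rec.seq), label=label, description=desc))
        else:
            raise ValueError(f"unknown kind {kind!r}")
    return out


def write_fasta(records: Iterable[TranscriptRecord | ProteinRecord],
                path: str | Path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA (labels kept in the header)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            extra = getattr(rec, "label", "") or rec.description
            if extra:
                header += f" {extra}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str, frame: int = 1) -> str:
    """Translate one reading frame, standard genetic code.

    ``frame`` is one of +1/+2/+3 (forward) or -1/-2/-3 (reverse complement).
    Codons containing ``N`` translate to ``X``; stops are ``*``; trailing
    1-2 nt that do not fill a codon are dropped.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq.upper().replace("U", "T")
    if frame < 0:
        s = revcomp(s)
    offset = abs(frame) - 1
    s = s[offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        raise ValueError("sequence shorter than one codon after frame offset")
    return str(Seq(s).translate(table=1))


def six_frame_translations(t: TranscriptRecord | str) -> dict[int, str]:
    """All six frame translations of a transcript, keyed by frame."""
    seq = t.seq if isinstance(t, TranscriptRecord) else t
    out: dict[int, str] = {}
    for f in FRAMES:
        try:
            out[f] = translate(seq, f)
        except ValueError:  # too short for this frame offset
            out[f] = ""
    return out
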