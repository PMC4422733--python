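"""Six-frame ORF extraction and completeness classification.

Every maximal stop-free stretch of at least ``min_orf_len`` residues in each
of the six frame translations is reported, in up to two resolutions: the full
stretch and, when it contains a methionine, the Met-initiated form.
Completeness follows from the flanking context:

===================  ============  =========  ===============
completeness         upstream stop  start Met  downstream stop
===================  ============  =========  ===============
full_length          yes           yes        yes
putative_full_length no            yes        yes
c_terminal_partial   -             no         yes
n_terminal_partial   -             yes        no
internal_fragment    -             no         no
===================  ============  =========  ===============

An "upstream stop" is an in-frame stop codon observed 5' of the start Met;
a full-length call therefore certifies that the deduced protein cannot
extend further upstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gstmine.align as _align
from .records import ProteinRecord, TranscriptRecord, translate

DEFAULT_MIN_ORF_LEN = 40


class Completeness(str, enum.Enum):
    FULL_LENGTH = "full_length"
    PUTATIVE_FULL_LENGTH = "putative_full_length"
    C_TERMINAL_PARTIAL = "c_terminal_partial"
    N_TERMINAL_PARTIAL = "n_terminal_partial"
    INTERNAL_FRAGMENT = "internal_fragment"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify(has_upstream_stop: bool, has_start_met: bool,
             has_downstream_stop: bool) -> Completeness:
    """Completeness as a pure function of the three flanking booleans."""
    if has_start_met and has_downstream_stop:
        return (Completeness.FULL_LENGTH if has_upstream_stop
                else Completeness.PUTATIVE_FULL_LENGTH)
    if has_downstream_stop:
        return Completeness.C_TERMINAL_PARTIAL
    if has_start_met:
        return Completeness.N_TERMINAL_PARTIAL
    return Completeness.INTERNAL_FRAGMENT


@dataclass
class DeducedProtein:
    """A translated ORF with completeness status and provenance coordinates.

    ``aa_start``/``aa_end`` are 1-based inclusive positions within the frame
    translation; ``nt_start``/``nt_end`` are 1-based inclusive transcript
    coordinates of the codons spanned (on the forward strand regardless of
    frame sign).
    """

    id: str
    transcript_id: str
    frame: int
    aa_seq: str
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    has_upstream_stop: bool
    has_start_met: bool
    has_downstream_stop: bool
    completeness: Completeness
    assembly: str = ""

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)

    def to_protein_record(self, label: str = "") -> ProteinRecord:
        return ProteinRecord(self.id, self.aa_seq, label=label)


def _nt_span(length_bp: int, frame: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Transcript nt coordinates (1-based, forward strand) of an aa interval."""
    offset = abs(frame) - 1
    # 0-based half-open interval on the read strand
    s = offset + 3 * (aa_start - 1)
    e = offset + 3 * aa_end
    if frame > 0:
        return s + 1, e
    # read strand is the reverse complement: map back
    return length_bp - e + 1, length_bp - s


def extract_orfs(t: TranscriptRecord, min_orf_len: int = DEFAULT_MIN_ORF_LEN) -> list[DeducedProtein]:
    """All candidate ORFs (>= ``min_orf_len`` aa) in the six frames of *t*."""
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    out: list[DeducedProtein] = []
    for frame in (1, 2, 3, -1, -2, -3):
        try:
            aa = translate(t.seq, frame)
        except ValueError:
            continue
        # maximal stop-free stretches with their 0-based [start, end) positions
        pos = 0
        for chunk in aa.split("*"):
            start, end = pos, pos + len(chunk)
            pos = end + 1
            if not chunk:
                continue
            upstream = start > 0                   # preceded by an in-frame stop
            downstream = end < len(aa)             # followed by an in-frame stop
            met_off = chunk.find("M")
            forms = []                             # aa start offsets within the stretch
            if len(chunk) >= min_orf_len:
                forms.append(0)
            if met_off > 0 and len(chunk) - met_off >= min_orf_len:
                forms.append(met_off)
            for off in forms:
                aa_start, aa_end = start + off + 1, end  # 1-based inclusive
                seq = chunk[off:]
                has_met = seq[0] == "M"
                nt_start, nt_end = _nt_span(t.length_bp, frame, aa_start, aa_end)
                out.append(DeducedProtein(
                    id=f"{t.id}|f{frame:+d}|{aa_start}-{aa_end}",
                    transcript_id=t.id,
                    frame=frame,
                    aa_seq=seq,
                    aa_start=aa_start,
                    aa_end=aa_end,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    has_upstream_stop=upstream,
                    has_start_met=has_met,
                    has_downstream_stop=downstream,
                    completeness=classify(upstream, has_met, downstream),
                    assembly=t.assembly,
                ))
    return out


_FRAME_ORDER = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}


def _met_matches_query_start(orf: DeducedProtein, query: ProteinRecord,
                             config: _align.AlignerConfig) -> bool:
    """True when the ORF's start Met aligns to the query's initial Met."""
    if not orf.has_start_met or not query.seq.startswith("M"):
        return False
    aln = _align.align(orf.aa_seq, query.seq, "local", config)
    # first aligned column pairs ORF residue 1 with query residue 1?
    a_used = len(aln.row_a) - len(aln.row_a.lstrip("-"))
    b_used = len(aln.row_b) - len(aln.row_b.lstrip("-"))
    if a_used or b_used:
        return False
    a_start = orf.aa_seq.find(aln.row_a.replace("-", ""))
    b_start = query.seq.find(aln.row_b.replace("-", ""))
    return a_start == 0 and b_start == 0


def pick_protein_for_hit(orfs: Sequence[DeducedProtein], query: ProteinRecord,
                         config: _align.AlignerConfig = _align.DEFAULT_CONFIG) -> DeducedProtein:
    """The ORF best supported by the query that retrieved the transcript.

    Highest local-alignment score wins.  Exact ties are resolved in favour of
    a Met-initiated form whose Met matches the query's initial Met (the
    full-length criterion used when a protein is deduced from its query),
    then the longer ORF, then frame order +1,+2,+3,-1,-2,-3.  A
    putative-full-length pick whose Met matches the query start is promoted
    to full length.
    """
    if not orfs:
        raise ValueError("no candidate ORFs")
    scored = [(_align.score(o.aa_seq, query.seq, "local", config), o) for o in orfs]
    best_score = max(s for s, _ in scored)
    tied = [o for s, o in scored if s == best_score]
    if len(tied) > 1:
        met_tied = [o for o in tied if _met_matches_query_start(o, query, config)]
        if met_tied:
            tied = met_tied
        tied.sort(key=lambda o: (-o.length_aa, _FRAME_ORDER[o.frame]))
    chosen = tied[0]
    if (chosen.completeness is Completeness.PUTATIVE_FULL_LENGTH
            and _met_matches_query_start(chosen, query, config)):
        chosen = replace(chosen, completeness=Completeness.FULL_LENGTH)
    return chosen


def orf_report(orfs: Iterable[DeducedProtein], path: str | Path) -> None:
    """TSV report: transcript, frame, nt span, aa length, completeness."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tnt_start\tnt_end\taa_len\tcompleteness\n")
        for o in orfs:
            fh.write(f"{o.transcript_id}\t{o.frame:+d}\t{o.nt_start}\t{o.nt_end}"
                     f"\t{o.length_aa}\t{o.completeness.value}\n")
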