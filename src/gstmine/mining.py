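"""Translated homology search and reciprocal best-hit annotation.

``mine_assembly`` emulates a tblastn-style search: each protein query is
aligned locally (Smith-Waterman) against all six frame translations of every
contig, the best frame per (query, transcript) is kept, and significance is
judged by a Karlin-Altschul E-value

    E = K * m * n * exp(-lambda * S)

with *m* the query length and *n* the total translated residue count of the
searched assembly.  Lambda and K default to the ungapped BLOSUM62 values;
only the relative ordering of E-values is treated as meaningful.

``annotate_reciprocal`` assigns a deduced protein the class/subclass label of
its best local hit in a labelled reference panel, with identity/similarity
computed on the global alignment against that hit (region-of-overlap rule for
partial proteins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gstmine.align as _align
from .domains import DomainCall, ProfileSet, scan_domains
from .orf import Completeness, DeducedProtein
from .records import ProteinRecord, TranscriptRecord, six_frame_translations

#: ungapped BLOSUM62 Karlin-Altschul parameters
LAMBDA = 0.3176
KAPPA = 0.134

DEFAULT_EVALUE_CUTOFF = 1e-5

#: raw-score floor below which a reciprocal annotation is refused; calibrated
#: against a shuffled-protein score null (see docs/methods.md).
DEFAULT_SCORE_FLOOR = 120.0


@dataclass
class SearchHit:
    query_id: str
    transcript_id: str
    frame: int
    score: float
    bitscore: float
    evalue: float
    aln: Optional[_align.AlignmentResult] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class AnnotationRecord:
    protein_id: str
    assigned_class: str        # cytosolic / mitochondrial / microsomal / unassigned
    assigned_subclass: str
    top_hit_id: str
    top_hit_label: str
    score: float
    identity_pct: float
    similarity_pct: float
    domains: list[DomainCall] = field(default_factory=list)

    @property
    def assigned(self) -> bool:
        return self.assigned_class != "unassigned"


def karlin_altschul_evalue(score: float, m: int, n: int,
                           lam: float = LAMBDA, k: float = KAPPA) -> float:
    return k * m * n * math.exp(-lam * score)


def bitscore(score: float, lam: float = LAMBDA, k: float = KAPPA) -> float:
    return (lam * score - math.log(k)) / math.log(2.0)


def database_size(assembly: Sequence[TranscriptRecord]) -> int:
    """Total residue count over the six frame translations of an assembly."""
    return sum(len(aa) for t in assembly
               for aa in six_frame_translations(t).values())


def mine_assembly(queries: Sequence[ProteinRecord],
                  assembly: Sequence[TranscriptRecord],
                  evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                  config: _align.AlignerConfig = _align.DEFAULT_CONFIG,
                  keep_alignments: bool = False) -> list[SearchHit]:
    """Search an assembly's six-frame translations with protein queries.

    Returns hits with E-value <= cutoff, sorted by ascending E-value then
    descending bitscore.  With ``keep_alignments`` the best local alignment
    (query vs frame translation) is attached to each hit.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    if not queries or not assembly:
        raise ValueError("queries and assembly must be non-empty")
    n_db = database_size(assembly)
    aligner = config.make("local")
    frames_cache = [(t, six_frame_translations(t)) for t in assembly]
    hits: list[SearchHit] = []
    for q in queries:
        m = len(q.seq)
        for t, frames in frames_cache:
            best_score, best_frame = -math.inf, 0
            for f, aa in frames.items():
                if not aa:
                    continue
                s = float(aligner.score(q.seq, aa))
                if s > best_score:
                    best_score, best_frame = s, f
            if best_frame == 0:
                continue
            ev = karlin_altschul_evalue(best_score, m, n_db)
            if ev <= evalue_cutoff:
                aln = None
                if keep_alignments:
                    aln = _align.align(q.seq, frames[best_frame], "local",
                                       config, allow_stops=True)
                hits.append(SearchHit(q.id, t.id, best_frame, best_score,
                                      bitscore(best_score), ev, aln))
    hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.query_id, h.transcript_id))
    return hits


def collapse_hits(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """One entry per transcript, keeping its best supporting hit.

    Output is ordered by the best E-value per transcript (distinct queries
    retrieving the same contig collapse to a single entry, as in a
    deduplicated mining list).
    """
    best: dict[str, SearchHit] = {}
    for h in hits:
        cur = best.get(h.transcript_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[h.transcript_id] = h
    return sorted(best.values(), key=lambda h: (h.evalue, -h.bitscore, h.transcript_id))


def annotate_reciprocal(p: DeducedProtein | ProteinRecord,
                        panel: Sequence[ProteinRecord],
                        config: _align.AlignerConfig = _align.DEFAULT_CONFIG,
                        score_floor: float = DEFAULT_SCORE_FLOOR,
                        profiles: Optional[ProfileSet] = None) -> AnnotationRecord:
    """Assign class/subclass from the best local hit in a labelled panel.

    Ties on score are resolved by higher identity percentage, then
    lexicographic hit id.  Below ``score_floor`` the protein is left
    unassigned.  When a profile set is supplied the annotation also carries
    the protein's domain calls.
    """
    if not panel:
        raise ValueError("empty reference panel")
    seq = p.aa_seq if isinstance(p, DeducedProtein) else p.seq
    pid = p.id
    completeness = getattr(p, "completeness", Completeness.FULL_LENGTH)
    partial = completeness is not Completeness.FULL_LENGTH

    scored = [(float(_align.score(seq, ref.seq, "local", config)), ref)
              for ref in panel]
    best_score = max(s for s, _ in scored)
    domains = list(scan_domains(p, profiles)) if profiles is not None else []
    if best_score < score_floor:
        return AnnotationRecord(pid, "unassigned", "", "", "", best_score,
                                0.0, 0.0, domains)
    tied = [ref for s, ref in scored if s == best_score]
    reports = {ref.id: _align.pairwise_identity(seq, ref.seq, partial_mode=partial,
                                                config=config)
               for ref in tied}
    tied.sort(key=lambda ref: (-reports[ref.id].pct_identity, ref.id))
    top = tied[0]
    rep = reports[top.id]
    return AnnotationRecord(
        protein_id=pid,
        assigned_class=top.gst_class or "unassigned",
        assigned_subclass=top.subclass,
        top_hit_id=top.id,
        top_hit_label=top.label,
        score=best_score,
        identity_pct=rep.pct_identity,
        similarity_pct=rep.pct_similarity,
        domains=domains,
    )


def hits_to_tsv(hits: Iterable[SearchHit], path: str | Path) -> None:
    """BLAST outfmt-6-like hit table."""
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tframe\tscore\tbitscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.transcript_id}\t{h.frame:+d}"
                     f"\t{h.score:.1f}\t{h.bitscore:.1f}\t{h.evalue:.2e}\n")
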