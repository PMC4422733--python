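"""Cross-assembly correspondence of deduced proteins between two populations.

Proteins annotated to the same subclass are paired by bidirectional best hit
on overlap identity; each pair receives a verdict:

* ``same_gene``          — overlap identity >= ``t_same`` (default 90%): good
  one-to-one correspondence, the two assemblies captured the same gene;
* ``distinct_gene``      — overlap identity < ``t_distinct`` (default 50%):
  the level seen among within-subclass paralogs, so the partner is likely the
  product of a different gene;
* ``divergent_ortholog`` — between the two thresholds: more alike than
  paralogs but short of one-to-one correspondence (reported without
  asserting gene identity);
* ``unmatched``          — no reciprocal partner.

Unmatched proteins that are also unlike every same-assembly subclass member
(< ``t_distinct``) are candidate population-private ("additional") genes; a
targeted re-search of the other assembly can upgrade them when a nearly
identical partial transcript turns out to have been missed by the primary
mining step.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gstmine.align as _align
from .mining import AnnotationRecord, mine_assembly
from .orf import Completeness, DeducedProtein, extract_orfs, pick_protein_for_hit
from .records import TranscriptRecord

DEFAULT_T_SAME = 90.0
DEFAULT_T_DISTINCT = 50.0


class Verdict(str, enum.Enum):
    SAME_GENE = "same_gene"
    DIVERGENT_ORTHOLOG = "divergent_ortholog"
    DISTINCT_GENE = "distinct_gene"
    UNMATCHED = "unmatched"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: a deduced protein together with its annotation
AnnotatedProtein = tuple[DeducedProtein, AnnotationRecord]


@dataclass
class CorrespondencePair:
    protein_a_id: Optional[str]
    protein_b_id: Optional[str]
    subclass: str
    gst_class: str
    overlap_identity_pct: Optional[float]
    completeness_a: Optional[Completeness]
    completeness_b: Optional[Completeness]
    verdict: Verdict
    note: str = ""


def verdict_for_identity(identity_pct: float,
                         t_same: float = DEFAULT_T_SAME,
                         t_distinct: float = DEFAULT_T_DISTINCT) -> Verdict:
    if identity_pct >= t_same:
        return Verdict.SAME_GENE
    if identity_pct < t_distinct:
        return Verdict.DISTINCT_GENE
    return Verdict.DIVERGENT_ORTHOLOG


def _overlap_identity(a: DeducedProtein, b: DeducedProtein,
                      config: _align.AlignerConfig) -> float:
    partial = (a.completeness is not Completeness.FULL_LENGTH
               or b.completeness is not Completeness.FULL_LENGTH)
    rep = _align.pairwise_identity(a.aa_seq, b.aa_seq, partial_mode=partial,
                                   config=config)
    return rep.pct_identity


def match_assemblies(set_a: Sequence[AnnotatedProtein],
                     set_b: Sequence[AnnotatedProtein],
                     t_same: float = DEFAULT_T_SAME,
                     t_distinct: float = DEFAULT_T_DISTINCT,
                     config: _align.AlignerConfig = _align.DEFAULT_CONFIG
                     ) -> list[CorrespondencePair]:
    """Bidirectional best-hit pairing within each assigned subclass.

    Overlap identity (region-of-overlap rule whenever either partner is
    partial) is the pairing criterion; ties break to lexicographic partner
    id.  Unpaired proteins are reported as unmatched.  Pairing is symmetric
    in its arguments.
    """
    by_sub_a: dict[str, list[AnnotatedProtein]] = {}
    by_sub_b: dict[str, list[AnnotatedProtein]] = {}
    for p, ann in set_a:
        by_sub_a.setdefault(ann.assigned_subclass, []).append((p, ann))
    for p, ann in set_b:
        by_sub_b.setdefault(ann.assigned_subclass, []).append((p, ann))

    pairs: list[CorrespondencePair] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for sub in sorted(set(by_sub_a) | set(by_sub_b)):
        group_a = by_sub_a.get(sub, [])
        group_b = by_sub_b.get(sub, [])
        ident: dict[tuple[str, str], float] = {}
        for pa, _ in group_a:
            for pb, _ in group_b:
                ident[(pa.id, pb.id)] = _overlap_identity(pa, pb, config)
        for pa, ann_a in group_a:
            if not group_b:
                break
            best_b = max(group_b,
                         key=lambda x: (ident[(pa.id, x[0].id)], x[0].id))
            pb, ann_b = best_b
            best_a = max(group_a,
                         key=lambda x: (ident[(x[0].id, pb.id)], x[0].id))
            if best_a[0].id != pa.id:
                continue  # not reciprocal
            pct = ident[(pa.id, pb.id)]
            pairs.append(CorrespondencePair(
                protein_a_id=pa.id, protein_b_id=pb.id,
                subclass=sub, gst_class=ann_a.assigned_class,
                overlap_identity_pct=pct,
                completeness_a=pa.completeness, completeness_b=pb.completeness,
                verdict=verdict_for_identity(pct, t_same, t_distinct),
            ))
            matched_a.add(pa.id)
            matched_b.add(pb.id)
    for p, ann in set_a:
        if p.id not in matched_a:
            pairs.append(CorrespondencePair(p.id, None, ann.assigned_subclass,
                                            ann.assigned_class, None,
                                            p.completeness, None, Verdict.UNMATCHED))
    for p, ann in set_b:
        if p.id not in matched_b:
            pairs.append(CorrespondencePair(None, p.id, ann.assigned_subclass,
                                            ann.assigned_class, None, None,
                                            p.completeness, Verdict.UNMATCHED))
    return pairs


def detect_additional_genes(pairs: Sequence[CorrespondencePair],
                            set_a: Sequence[AnnotatedProtein],
                            set_b: Sequence[AnnotatedProtein],
                            assembly_a: Optional[Sequence[TranscriptRecord]] = None,
                            assembly_b: Optional[Sequence[TranscriptRecord]] = None,
                            t_same: float = DEFAULT_T_SAME,
                            t_distinct: float = DEFAULT_T_DISTINCT,
                            config: _align.AlignerConfig = _align.DEFAULT_CONFIG,
                            min_orf_len: int = 40,
                            ) -> tuple[list[str], list[CorrespondencePair]]:
    """Population-private gene candidates among the unmatched proteins.

    A candidate must be below ``t_distinct`` overlap identity to *every*
    same-assembly member of its subclass (otherwise it could be an
    assembly-split paralog).  When the other population's assembly is
    supplied, each candidate triggers a targeted re-search of it; a partner
    at >= ``t_same`` overlap identity (typically a short partial transcript
    missed by primary mining) upgrades the record to ``same_gene`` with a
    "present in both" note.

    Returns the candidate ids that remain additional, plus the updated pair
    list.
    """
    proteins = {p.id: (p, ann) for p, ann in list(set_a) + list(set_b)}
    side_of = {p.id: "a" for p, _ in set_a}
    side_of.update({p.id: "b" for p, _ in set_b})

    out_pairs = list(pairs)
    additional: list[str] = []
    for i, pair in enumerate(out_pairs):
        if pair.verdict is not Verdict.UNMATCHED:
            continue
        pid = pair.protein_a_id or pair.protein_b_id
        p, ann = proteins[pid]
        side = side_of[pid]
        same_side = set_a if side == "a" else set_b
        mates = [q for q, qann in same_side
                 if q.id != pid and qann.assigned_subclass == ann.assigned_subclass]
        if any(_overlap_identity(p, q, config) >= t_distinct for q in mates):
            continue
        other_assembly = assembly_b if side == "a" else assembly_a
        upgraded = False
        if other_assembly:
            query = p.to_protein_record()
            rescue_hits = mine_assembly([query], other_assembly, evalue_cutoff=1e-3,
                                        config=config)
            for h in rescue_hits:
                transcript = next(t for t in other_assembly
                                  if t.id == h.transcript_id)
                orfs = extract_orfs(transcript, min_orf_len)
                if not orfs:
                    continue
                partner = pick_protein_for_hit(orfs, query, config)
                pct = _overlap_identity(p, partner, config)
                if pct >= t_same:
                    a_id, b_id = (pid, partner.id) if side == "a" else (partner.id, pid)
                    comp_a, comp_b = ((p.completeness, partner.completeness)
                                      if side == "a"
                                      else (partner.completeness, p.completeness))
                    out_pairs[i] = CorrespondencePair(
                        a_id, b_id, ann.assigned_subclass, ann.assigned_class,
                        pct, comp_a, comp_b, Verdict.SAME_GENE,
                        note="present in both (recovered by targeted re-search)")
                    upgraded = True
                    break
        if not upgraded:
            additional.append(pid)
    return additional, out_pairs


_COMPLETENESS_RANK = {
    Completeness.FULL_LENGTH: 4,
    Completeness.PUTATIVE_FULL_LENGTH: 3,
    Completeness.C_TERMINAL_PARTIAL: 2,
    Completeness.N_TERMINAL_PARTIAL: 2,
    Completeness.INTERNAL_FRAGMENT: 1,
}


@dataclass
class GeneEntry:
    gene_index: int
    gst_class: str
    subclass: str
    protein_a_id: Optional[str]
    protein_b_id: Optional[str]
    completeness: Completeness
    verdict: Verdict
    note: str = ""


@dataclass
class GeneCatalog:
    entries: list[GeneEntry]

    @property
    def total(self) -> int:
        return len(self.entries)

    def subclass_counts(self) -> dict[str, int]:
        return dict(Counter(e.subclass for e in self.entries))

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(e.gst_class for e in self.entries))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tclass\tsubclass\tprotein_a\tprotein_b"
                     "\tcompleteness\tverdict\tnote\n")
            for e in self.entries:
                fh.write(f"{e.gene_index}\t{e.gst_class}\t{e.subclass}"
                         f"\t{e.protein_a_id or '-'}\t{e.protein_b_id or '-'}"
                         f"\t{e.completeness.value}\t{e.verdict.value}\t{e.note}\n")


def merge_catalogs(pairs: Sequence[CorrespondencePair],
                   set_a: Sequence[AnnotatedProtein],
                   set_b: Sequence[AnnotatedProtein]) -> GeneCatalog:
    """Merge two assemblies' annotations into one inferred gene catalog.

    A reciprocal pair above the distinct-gene threshold is one gene whose
    completeness is the best evidence across the two assemblies (full beats
    partial); a distinct-gene pair contributes two genes; every unmatched
    protein contributes one.
    """
    entries: list[GeneEntry] = []

    def add(gst_class, subclass, a_id, b_id, comp, verdict, note=""):
        entries.append(GeneEntry(len(entries) + 1, gst_class, subclass,
                                 a_id, b_id, comp, verdict, note))

    for pair in pairs:
        if pair.verdict in (Verdict.SAME_GENE, Verdict.DIVERGENT_ORTHOLOG):
            comp = max((c for c in (pair.completeness_a, pair.completeness_b)
                        if c is not None),
                       key=lambda c: _COMPLETENESS_RANK[c])
            add(pair.gst_class, pair.subclass, pair.protein_a_id,
                pair.protein_b_id, comp, pair.verdict, pair.note)
        elif pair.verdict is Verdict.DISTINCT_GENE:
            add(pair.gst_class, pair.subclass, pair.protein_a_id, None,
                pair.completeness_a, pair.verdict, "population A form")
            add(pair.gst_class, pair.subclass, None, pair.protein_b_id,
                pair.completeness_b, pair.verdict, "population B form")
        else:  # unmatched
            comp = pair.completeness_a or pair.completeness_b
            add(pair.gst_class, pair.subclass, pair.protein_a_id,
                pair.protein_b_id, comp, pair.verdict, pair.note)
    return GeneCatalog(entries)


def pairs_to_tsv(pairs: Sequence[CorrespondencePair], path: str | Path,
                 names: Optional[dict[str, str]] = None) -> None:
    """Correspondence table: name, accession/type per assembly, identity, verdict."""
    names = names or {}

    def fmt_type(c: Optional[Completeness]) -> str:
        if c is None:
            return "-"
        return "F" if c in (Completeness.FULL_LENGTH,
                            Completeness.PUTATIVE_FULL_LENGTH) else "P"

    with open(path, "w") as fh:
        fh.write("protein_name\tclass\tsubclass\taccession_a\ttype_a"
                 "\taccession_b\ttype_b\tpct_identity\tverdict\tnote\n")
        for p in pairs:
            name = names.get(p.protein_a_id or "", "") or names.get(p.protein_b_id or "", "") or "-"
            pct = f"{round(p.overlap_identity_pct)}" if p.overlap_identity_pct is not None else "-"
            fh.write(f"{name}\t{p.gst_class}\t{p.subclass}"
                     f"\t{p.protein_a_id or '-'}\t{fmt_type(p.completeness_a)}"
                     f"\t{p.protein_b_id or '-'}\t{fmt_type(p.completeness_b)}"
                     f"\t{pct}\t{p.verdict.value}\t{p.note}\n")
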