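"""End-to-end orchestration: mine -> deduce -> vet -> annotate -> compare -> quantify.

The single-assembly analysis mirrors a transcriptome-mining study design:
labelled panel proteins are used as translated-search queries; retrieved
contigs are six-frame translated; the ORF best supported by the retrieving
query is kept and annotated by reciprocal best hit against the panel
(proteins whose best panel score stays below the calibrated floor are
discarded as non-family); domain calls and the diagnostic microsomal motif
scan are attached as vetting evidence.  Annotated proteins are named
``<prefix>-<Subclass>-<RomanNumeral>`` in descending annotation-score order.

The two-assembly comparison pairs annotated proteins across populations,
detects population-private genes (with targeted re-search rescue) and merges
everything into a gene catalog with per-subclass counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

import gstmine.align as _align
from . import __version__
from .correspond import (CorrespondencePair, GeneCatalog, Verdict,
                         detect_additional_genes, match_assemblies,
                         merge_catalogs, pairs_to_tsv)
from .domains import (MGST1_MOTIF, MotifMatch, ProfileSet,
                      expected_complement_ok, load_profiles, scan_motif)
from .expression import CountTable, ExpressionTable, summarize_stages
from .mining import (DEFAULT_EVALUE_CUTOFF, DEFAULT_SCORE_FLOOR,
                     AnnotationRecord, SearchHit, annotate_reciprocal,
                     collapse_hits, hits_to_tsv, mine_assembly)
from .orf import (DEFAULT_MIN_ORF_LEN, DeducedProtein,
                  extract_orfs, pick_protein_for_hit)
from .records import ProteinRecord, TranscriptRecord, read_fasta

logger = logging.getLogger("gstmine")


class ConfigError(Exception):
    """Invalid or incomplete pipeline configuration."""


class DataError(Exception):
    """Malformed input data or a stage failure on valid configuration."""


@dataclass
class PipelineConfig:
    assembly_a: Optional[str] = None
    assembly_b: Optional[str] = None
    panel: Optional[str] = None
    profiles_dir: Optional[str] = None      # default: built-in profile set
    counts: Optional[str] = None
    library_sizes: Optional[str] = None
    outdir: str = "gstmine_out"
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    min_orf_len: int = DEFAULT_MIN_ORF_LEN
    t_same: float = 90.0
    t_distinct: float = 50.0
    score_floor: float = DEFAULT_SCORE_FLOOR
    motif_pattern: str = MGST1_MOTIF
    motif_max_mismatches: int = 2
    pseudocount: float = 1.0
    name_prefix: str = "GST"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self, need_b: bool = False) -> None:
        if self.panel is None or self.assembly_a is None:
            raise ConfigError("assembly_a and panel paths are required")
        paths = [self.assembly_a, self.panel]
        if need_b:
            if self.assembly_b is None:
                raise ConfigError("assembly_b path is required for comparison")
            paths.append(self.assembly_b)
        for extra in (self.profiles_dir, self.counts, self.library_sizes):
            if extra is not None:
                paths.append(extra)
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")
        if self.evalue_cutoff <= 0:
            raise ConfigError("evalue_cutoff must be > 0")
        if self.min_orf_len < 1:
            raise ConfigError("min_orf_len must be >= 1")
        if not (0 < self.t_distinct <= self.t_same <= 100):
            raise ConfigError("need 0 < t_distinct <= t_same <= 100")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _roman(n: int) -> str:
    pairs = ((1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
             (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
             (5, "V"), (4, "IV"), (1, "I"))
    out = []
    for value, sym in pairs:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


@dataclass
class MinedProtein:
    """One vetted family member from a single assembly."""

    protein: DeducedProtein
    annotation: AnnotationRecord
    supporting_hit: SearchHit
    name: str = ""
    motif_matches: list[MotifMatch] = field(default_factory=list)
    complement_ok: bool = False


@dataclass
class SingleAssemblyResult:
    assembly_label: str
    hits: list[SearchHit]
    collapsed: list[SearchHit]
    members: list[MinedProtein]
    n_transcripts_searched: int

    @property
    def annotated_pairs(self) -> list[tuple[DeducedProtein, AnnotationRecord]]:
        return [(m.protein, m.annotation) for m in self.members]

    def subclass_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            sub = m.annotation.assigned_subclass
            out[sub] = out.get(sub, 0) + 1
        return out


def analyze_assembly(assembly: Sequence[TranscriptRecord],
                     panel: Sequence[ProteinRecord],
                     profiles: Optional[ProfileSet] = None,
                     evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
                     min_orf_len: int = DEFAULT_MIN_ORF_LEN,
                     score_floor: float = DEFAULT_SCORE_FLOOR,
                     motif_pattern: str = MGST1_MOTIF,
                     motif_max_mismatches: int = 2,
                     name_prefix: str = "GST",
                     config: _align.AlignerConfig = _align.DEFAULT_CONFIG,
                     ) -> SingleAssemblyResult:
    """Mine one assembly with the panel queries and annotate every candidate.

    Retention is decided by the reciprocal annotation score floor; domain
    complement and motif evidence are attached for vetting reports but do not
    veto a member on their own.
    """
    if profiles is None:
        profiles = load_profiles()
    label = assembly[0].assembly if assembly else ""
    if not assembly:
        return SingleAssemblyResult(label, [], [], [], 0)
    hits = mine_assembly(panel, assembly, evalue_cutoff, config)
    collapsed = collapse_hits(hits)
    logger.info("assembly %s: %d transcripts searched, %d hits on %d transcripts",
                label, len(assembly), len(hits), len(collapsed))
    by_id = {t.id: t for t in assembly}
    queries = {q.id: q for q in panel}
    members: list[MinedProtein] = []
    for hit in collapsed:
        transcript = by_id[hit.transcript_id]
        orfs = extract_orfs(transcript, min_orf_len)
        if not orfs:
            continue
        picked = pick_protein_for_hit(orfs, queries[hit.query_id], config)
        ann = annotate_reciprocal(picked, panel, config, score_floor, profiles)
        if not ann.assigned:
            continue
        motif = []
        if ann.assigned_subclass == "mGST-1":
            motif = scan_motif(picked.aa_seq, motif_pattern, motif_max_mismatches)
        members.append(MinedProtein(
            protein=picked, annotation=ann, supporting_hit=hit,
            motif_matches=motif,
            complement_ok=expected_complement_ok(
                ann.assigned_class, picked.completeness, ann.domains)))
    # stable protein naming: per subclass, descending annotation score
    by_sub: dict[str, list[MinedProtein]] = {}
    for m in members:
        by_sub.setdefault(m.annotation.assigned_subclass, []).append(m)
    for sub, group in by_sub.items():
        group.sort(key=lambda m: (-m.annotation.score, m.protein.id))
        for i, m in enumerate(group):
            m.name = f"{name_prefix}-{sub}-{_roman(i + 1)}"
    logger.info("assembly %s: %d vetted family members", label, len(members))
    return SingleAssemblyResult(label, hits, collapsed, members, len(assembly))


@dataclass
class ComparisonResult:
    pairs: list[CorrespondencePair]
    additional: list[str]
    catalog: GeneCatalog


def compare_assemblies(result_a: SingleAssemblyResult,
                       result_b: SingleAssemblyResult,
                       assembly_a: Optional[Sequence[TranscriptRecord]] = None,
                       assembly_b: Optional[Sequence[TranscriptRecord]] = None,
                       t_same: float = 90.0, t_distinct: float = 50.0,
                       min_orf_len: int = DEFAULT_MIN_ORF_LEN,
                       config: _align.AlignerConfig = _align.DEFAULT_CONFIG,
                       ) -> ComparisonResult:
    """Correspondence, additional-gene detection and the merged catalog."""
    set_a, set_b = result_a.annotated_pairs, result_b.annotated_pairs
    pairs = match_assemblies(set_a, set_b, t_same, t_distinct, config)
    additional, pairs = detect_additional_genes(
        pairs, set_a, set_b, assembly_a, assembly_b, t_same, t_distinct,
        config, min_orf_len)
    catalog = merge_catalogs(pairs, set_a, set_b)
    logger.info("comparison: %d pairs, %d additional genes, catalog of %d",
                sum(p.verdict is not Verdict.UNMATCHED for p in pairs),
                len(additional), catalog.total)
    return ComparisonResult(pairs, additional, catalog)


# ---------------------------------------------------------------------------
# report tables


def write_transcript_table(result: SingleAssemblyResult, assembly:
                           Sequence[TranscriptRecord], path: str | Path) -> None:
    """Mining summary: class, subclass, transcript accession, length (bp)."""
    lengths = {t.id: t.length_bp for t in assembly}
    rows = sorted(result.members,
                  key=lambda m: (m.annotation.assigned_class,
                                 m.annotation.assigned_subclass, m.name))
    with open(path, "w") as fh:
        fh.write("class\tsubclass\ttranscript\tlength_bp\n")
        for m in rows:
            tid = m.protein.transcript_id
            fh.write(f"{m.annotation.assigned_class}"
                     f"\t{m.annotation.assigned_subclass}"
                     f"\t{tid}\t{lengths[tid]}\n")


def write_annotation_table(result: SingleAssemblyResult, path: str | Path) -> None:
    """Annotation summary per deduced protein (reciprocal hit + domains)."""
    rows = sorted(result.members, key=lambda m: m.name)
    with open(path, "w") as fh:
        fh.write("protein_name\ttranscript\tdeduced_len_aa\tcompleteness"
                 "\tdomains\ttop_hit\ttop_hit_label\tscore"
                 "\tpct_identity\tpct_similarity\tcomplement_ok\n")
        for m in rows:
            doms = ",".join(d.domain_name for d in m.annotation.domains
                            if d.present) or "-"
            fh.write(f"{m.name}\t{m.protein.transcript_id}"
                     f"\t{m.protein.length_aa}\t{m.protein.completeness.value}"
                     f"\t{doms}\t{m.annotation.top_hit_id}"
                     f"\t{m.annotation.top_hit_label}\t{m.annotation.score:.0f}"
                     f"\t{round(m.annotation.identity_pct)}"
                     f"\t{round(m.annotation.similarity_pct)}"
                     f"\t{'yes' if m.complement_ok else 'no'}\n")


def write_count_table(counts: dict[str, int], path: str | Path,
                      title: str = "subclass") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\tn_genes\n")
        for sub in sorted(counts):
            fh.write(f"{sub}\t{counts[sub]}\n")
        fh.write(f"total\t{sum(counts.values())}\n")


def write_run_log(config: PipelineConfig, path: str | Path,
                  extra: Optional[dict] = None) -> None:
    payload = {
        "gstmine_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.__dict__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


# ---------------------------------------------------------------------------
# file-level entry points


def _load_inputs(config: PipelineConfig, need_b: bool = False):
    config.validate(need_b)
    try:
        assembly_a = read_fasta(config.assembly_a, "nucleotide")
    except ValueError as e:
        raise DataError(f"assembly_a: {e}") from e
    for t in assembly_a:
        t.assembly = t.assembly or "assembly_a"
    panel = read_fasta(config.panel, "protein")
    if not any(p.label for p in panel):
        raise DataError("panel FASTA carries no class|subclass labels")
    profiles = load_profiles(config.profiles_dir)
    assembly_b = None
    if need_b:
        assembly_b = read_fasta(config.assembly_b, "nucleotide")
        for t in assembly_b:
            t.assembly = t.assembly or "assembly_b"
    return assembly_a, assembly_b, panel, profiles


def _analyze(config: PipelineConfig, assembly, panel, profiles,
             prefix_suffix: str = "") -> SingleAssemblyResult:
    return analyze_assembly(
        assembly, panel, profiles,
        evalue_cutoff=config.evalue_cutoff, min_orf_len=config.min_orf_len,
        score_floor=config.score_floor, motif_pattern=config.motif_pattern,
        motif_max_mismatches=config.motif_max_mismatches,
        name_prefix=config.name_prefix + prefix_suffix)


def run_single(config: PipelineConfig) -> SingleAssemblyResult:
    """Mine and annotate one assembly; write the three report tables."""
    assembly_a, _, panel, profiles = _load_inputs(config, need_b=False)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = _analyze(config, assembly_a, panel, profiles)
    if not result.members:
        logger.warning("no family members retained from %s", config.assembly_a)
    hits_to_tsv(result.hits, outdir / "hits.tsv")
    write_transcript_table(result, assembly_a, outdir / "transcripts.tsv")
    write_annotation_table(result, outdir / "annotations.tsv")
    write_count_table(result.subclass_counts(), outdir / "subclass_counts.tsv")
    write_run_log(config, outdir / "run_log.json", {
        "stage_counts": {
            "transcripts_searched": result.n_transcripts_searched,
            "hits": len(result.hits),
            "transcripts_hit": len(result.collapsed),
            "members_vetted": len(result.members),
        }})
    if config.counts and config.library_sizes:
        run_expression(config, outdir)
    return result


def run_compare(config: PipelineConfig) -> tuple[SingleAssemblyResult,
                                                 SingleAssemblyResult,
                                                 ComparisonResult]:
    """Mine both assemblies, compare, and write correspondence reports."""
    assembly_a, assembly_b, panel, profiles = _load_inputs(config, need_b=True)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result_a = _analyze(config, assembly_a, panel, profiles)
    result_b = _analyze(config, assembly_b, panel, profiles)
    comparison = compare_assemblies(result_a, result_b, assembly_a, assembly_b,
                                    config.t_same, config.t_distinct,
                                    config.min_orf_len)
    names = {m.protein.id: m.name for m in result_a.members + result_b.members}
    pairs_to_tsv(comparison.pairs, outdir / "correspondence.tsv", names)
    variation = [p for p in comparison.pairs
                 if p.verdict in (Verdict.DIVERGENT_ORTHOLOG, Verdict.DISTINCT_GENE)]
    pairs_to_tsv(variation, outdir / "variation.tsv", names)
    comparison.catalog.to_tsv(outdir / "merged_catalog.tsv")
    write_count_table(comparison.catalog.subclass_counts(),
                      outdir / "merged_subclass_counts.tsv")
    write_transcript_table(result_a, assembly_a, outdir / "transcripts_a.tsv")
    write_transcript_table(result_b, assembly_b, outdir / "transcripts_b.tsv")
    write_annotation_table(result_a, outdir / "annotations_a.tsv")
    write_annotation_table(result_b, outdir / "annotations_b.tsv")
    write_run_log(config, outdir / "run_log.json", {
        "stage_counts": {
            "members_a": len(result_a.members),
            "members_b": len(result_b.members),
            "pairs": len(comparison.pairs),
            "additional_genes": len(comparison.additional),
            "merged_catalog_total": comparison.catalog.total,
        }})
    return result_a, result_b, comparison


def run_expression(config: PipelineConfig,
                   outdir: Optional[Path] = None) -> ExpressionTable:
    """RPKM + per-stage summaries from the configured count tables."""
    if not (config.counts and config.library_sizes):
        raise ConfigError("counts and library_sizes paths are required")
    for p in (config.counts, config.library_sizes):
        if not Path(p).exists():
            raise ConfigError(f"path does not exist: {p}")
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        ct = CountTable.from_tsv(config.counts, config.library_sizes)
    except ValueError as e:
        raise DataError(f"count table: {e}") from e
    expr = summarize_stages(ct, config.pseudocount)
    expr.to_tsv(outdir / "expression.tsv")
    return expr
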