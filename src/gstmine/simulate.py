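"""Ground-truthed synthetic transcriptome assemblies for two populations.

The generator plants gene families with the divergence structure typical of
a duplicated detoxification-enzyme superfamily in a zooplankter: several
subclasses, each with paralogs at 30-60% within-subclass protein identity,
orthologs at 88-100% identity between two mostly isolated populations,
partial transcripts (missing start and/or stop context), population-private
genes, decoy contigs, and stage-structured read counts.

Proteins are built from the same domain consensus sequences the vetting
profiles are trained on (synthetic seeds shipped with the package), so the
generated families carry detectable domain architecture.  Divergence is
produced by iterated point substitution with accept/reject against the
measured identity, drawing replacement residues from the current residue's
strong conservation group 70% of the time — so percent similarity stays
above percent identity, as in real protein families.

Everything is deterministic given the seed: the same seed yields
byte-identical FASTA outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import _STRONG_SETS
from .domains import MGST1_MOTIF, consensus_sequence
from .expression import DEFAULT_STAGES, CountTable
from .orf import Completeness
from .records import ProteinRecord, TranscriptRecord, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: class and domain architecture per subclass
SUBCLASS_ARCH: dict[str, tuple[str, tuple[str, ...]]] = {
    "Delta": ("cytosolic", ("GSTN", "GSTC")),
    "Theta": ("cytosolic", ("GSTN", "GSTC")),
    "Mu": ("cytosolic", ("GSTN", "GSTC")),
    "Omega": ("cytosolic", ("GSTN", "GSTC")),
    "Sigma": ("cytosolic", ("GSTN", "GSTC")),
    "Zeta": ("cytosolic", ("GSTN", "GSTC")),
    "Kappa": ("mitochondrial", ("THX",)),
    "mGST-1": ("microsomal", ("MAPEG",)),
    "mGST-3": ("microsomal", ("MAPEG",)),
}

#: identity of each subclass ancestor to the shared domain consensus (%)
ANCESTOR_IDENTITY = 50.0
#: identity range of reference-panel members to their subclass ancestor (%)
PANEL_IDENTITY_RANGE = (60.0, 70.0)

# truncation policy per class: (front-cut codon range for C-terminal cuts,
# minimum kept fraction for N-terminal cuts) chosen so that at least one
# complete-enough domain window survives every truncation
_TRUNCATION = {
    "cytosolic": ((5, 55), 0.55),
    "mitochondrial": ((5, 35), 0.55),
    "microsomal": ((5, 30), 0.78),
}

_PARTIAL_CLASSES = (Completeness.C_TERMINAL_PARTIAL,
                    Completeness.N_TERMINAL_PARTIAL,
                    Completeness.INTERNAL_FRAGMENT)

_STOP_CODONS = ("TAA", "TGA", "TAG")

# codon choices per amino acid (standard code), fixed order for determinism
_CODONS: dict[str, list[str]] = {}
for _c in ("".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"):
    from Bio.Seq import Seq as _Seq
    _aa = str(_Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)


@dataclass
class FamilySpec:
    """Planted composition of one subclass family."""

    subclass_name: str
    n_genes: int
    within_identity_range: tuple[float, float] = (30.0, 60.0)
    cross_population_identity_range: tuple[float, float] = (88.0, 100.0)
    #: per-gene overrides of the cross-population identity target (e.g. a
    #: 48% outlier emulating a population-specific paralog), keyed by gene
    #: index within the subclass
    cross_population_outliers: dict[int, float] = field(default_factory=dict)
    fraction_partial: float = 0.15
    #: population-private genes: (private to A, private to B)
    private_genes: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        lo, hi = self.within_identity_range
        if not (0 < lo <= hi <= 100):
            raise ValueError("invalid within_identity_range")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.subclass_name not in SUBCLASS_ARCH:
            raise ValueError(f"unknown subclass {self.subclass_name!r}")


@dataclass
class GeneTruth:
    """Ground truth for one planted gene."""

    gene_id: str
    subclass: str
    gst_class: str
    present_in: str                      # "both", "a" or "b"
    protein_a: Optional[str] = None      # full planted protein sequences
    protein_b: Optional[str] = None
    deduced_a: Optional[str] = None      # expected deduced protein after truncation
    deduced_b: Optional[str] = None
    transcript_a: Optional[str] = None
    transcript_b: Optional[str] = None
    completeness_a: Optional[Completeness] = None
    completeness_b: Optional[Completeness] = None
    cross_identity_target: Optional[float] = None
    cross_identity_realized: Optional[float] = None
    ancestor_identity_realized: Optional[float] = None
    expression_level: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    genes: list[GeneTruth]
    panel: list[ProteinRecord]
    seed: int
    decoys_a: list[str] = field(default_factory=list)
    decoys_b: list[str] = field(default_factory=list)

    def gene_by_transcript(self, transcript_id: str) -> Optional[GeneTruth]:
        for g in self.genes:
            if transcript_id in (g.transcript_a, g.transcript_b):
                return g
        return None

    def expected_subclass_counts(self, population: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            if g.present_in in ("both", population):
                out[g.subclass] = out.get(g.subclass, 0) + 1
        return out

    def merged_subclass_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[g.subclass] = out.get(g.subclass, 0) + 1
        return out

    @property
    def merged_total(self) -> int:
        return len(self.genes)

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, Completeness):
                return v.value
            return v
        payload = {
            "seed": self.seed,
            "genes": [{k: enc(v) for k, v in asdict(g).items()}
                      for g in self.genes],
            "panel": [{"id": p.id, "label": p.label} for p in self.panel],
            "decoys_a": self.decoys_a,
            "decoys_b": self.decoys_b,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def hamming_identity(a: str, b: str) -> float:
    """Percent identical positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _substitute(rng: np.random.Generator, residue: str,
                group_bias: float = 0.7) -> str:
    """Replacement residue, preferring the current strong conservation group."""
    groups = [g for g in _STRONG_SETS if residue in g]
    if groups and rng.random() < group_bias:
        group = groups[int(rng.integers(len(groups)))]
        options = sorted(group - {residue})
    else:
        options = [a for a in AA20 if a != residue]
    return options[int(rng.integers(len(options)))]


def mutate_to_identity(rng: np.random.Generator, seq: str, target_pct: float,
                       protected: frozenset[int] = frozenset()) -> str:
    """Iterated point substitution until identity to *seq* reaches the target.

    Accept/reject on the measured identity: the loop stops at the first state
    whose identity to the input is <= target, so the realized identity is
    within one substitution (100/len %) of the target.
    """
    n = len(seq)
    floor = 100.0 * (len(protected) + 1) / n
    if target_pct < floor:
        raise ValueError(
            f"identity target {target_pct}% infeasible: >= {floor:.1f}% of "
            f"positions are protected or fixed")
    cur = list(seq)
    mutable = [i for i in range(n) if i not in protected]
    max_iter = 80 * n
    for _ in range(max_iter):
        if hamming_identity("".join(cur), seq) <= target_pct:
            return "".join(cur)
        i = mutable[int(rng.integers(len(mutable)))]
        cur[i] = _substitute(rng, cur[i])
    raise RuntimeError(f"identity target {target_pct}% not reached "
                       f"in {max_iter} substitutions")


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def _subclass_base(rng: np.random.Generator, subclass: str,
                   consensus: dict[str, str]) -> tuple[str, frozenset[int]]:
    """Architecture template and protected positions for one subclass."""
    gst_class, domains = SUBCLASS_ARCH[subclass]
    if gst_class == "cytosolic":
        parts = ["M", _random_aa(rng, 9), consensus["GSTN"],
                 _random_aa(rng, 12), consensus["GSTC"], _random_aa(rng, 8)]
    elif gst_class == "mitochondrial":
        parts = ["M", _random_aa(rng, 9), consensus["THX"], _random_aa(rng, 160)]
    else:  # microsomal
        parts = ["M", _random_aa(rng, 5), consensus["MAPEG"], _random_aa(rng, 5)]
    base = "".join(parts)
    protected = {0}
    if subclass == "mGST-1":
        # the diagnostic 16-mer stays intact, with the species-specific
        # L -> Q substitution at motif position 9
        motif_core = MGST1_MOTIF.replace("x", "")
        offset = base.find(motif_core[:6])
        if offset < 0:
            raise RuntimeError("MAPEG consensus lacks the mGST-1 motif")
        motif_len = len(MGST1_MOTIF)
        l9 = offset + 8  # 0-based position of motif residue 9
        base = base[:l9] + "Q" + base[l9 + 1:]
        protected |= set(range(offset, offset + motif_len))
    return base, frozenset(protected)


_PROFILE_TYPES = {
    # stage profiles, in relative expression units; the developmental ramp
    # emulates low embryo and high late-copepodite/adult expression
    "ramp": {"embryo": 1.0, "NI-II": 4.0, "NV-VI": 6.0, "CI-II": 8.0,
             "CV": 24.0, "adult_female": 24.0},
    "flat": {s: 4.0 for s in DEFAULT_STAGES},
}


def generate_families(specs: Sequence[FamilySpec], seed: int
                      ) -> tuple[list[ProteinRecord], GroundTruth]:
    """Plant per-subclass gene families and a labelled reference panel.

    Returns the planted proteins (population-tagged ProteinRecords) and the
    ground truth.  Each subclass gets an ancestor derived from the shared
    domain consensus; paralogs descend from the ancestor at a per-gene
    identity chosen so that realized pairwise within-subclass identity falls
    in the requested range; population-B orthologs descend from the
    population-A protein at the per-gene cross-population identity target.
    """
    rng = np.random.default_rng(seed)
    consensus = {d: consensus_sequence(None, d)
                 for d in ("GSTN", "GSTC", "THX", "MAPEG")}
    genes: list[GeneTruth] = []
    panel: list[ProteinRecord] = []
    proteins: list[ProteinRecord] = []

    for spec in specs:
        sub = spec.subclass_name
        gst_class, _ = SUBCLASS_ARCH[sub]
        base, protected = _subclass_base(rng, sub, consensus)
        ancestor = mutate_to_identity(rng, base, ANCESTOR_IDENTITY, protected)
        for k in range(2):
            pid = f"REF-{sub}-{k + 1}"
            target = rng.uniform(*PANEL_IDENTITY_RANGE)
            panel.append(ProteinRecord(
                pid, mutate_to_identity(rng, ancestor, target, protected),
                label=f"{gst_class}|{sub}"))

        lo, hi = spec.within_identity_range
        # per-gene identity u to the ancestor such that pairwise identity
        # between two genes (~ u_i * u_j plus coincidental matches) lands in
        # the requested within-subclass band
        def draw_gene(target_band: tuple[float, float]) -> tuple[str, float]:
            t = rng.uniform(*target_band)
            u = 100.0 * math.sqrt(t / 100.0)
            prot = mutate_to_identity(rng, ancestor, u, protected)
            return prot, hamming_identity(prot, ancestor)

        existing_b: list[str] = []
        for g in range(spec.n_genes):
            prot_a, anc_id = draw_gene((lo, hi))
            cross = spec.cross_population_outliers.get(
                g, rng.uniform(*spec.cross_population_identity_range))
            prot_b = mutate_to_identity(rng, prot_a, cross, protected)
            profile = _PROFILE_TYPES["ramp" if sub in ("Delta", "Sigma") else "flat"]
            scale = float(rng.uniform(0.5, 4.0))
            gene = GeneTruth(
                gene_id=f"{sub}-{g + 1}", subclass=sub, gst_class=gst_class,
                present_in="both", protein_a=prot_a, protein_b=prot_b,
                cross_identity_target=float(cross),
                cross_identity_realized=hamming_identity(prot_a, prot_b),
                ancestor_identity_realized=anc_id,
                expression_level={s: v * scale for s, v in profile.items()},
            )
            genes.append(gene)
            existing_b.append(prot_b)
            proteins.append(ProteinRecord(f"{gene.gene_id}|a", prot_a,
                                          label=f"{gst_class}|{sub}"))
            proteins.append(ProteinRecord(f"{gene.gene_id}|b", prot_b,
                                          label=f"{gst_class}|{sub}"))

        for pop, count in zip(("a", "b"), spec.private_genes):
            for j in range(count):
                # private genes sit at the low end of the paralog band;
                # accept/reject directly on the measured pairwise identity so
                # every same-subclass mate stays safely below the
                # distinct-gene threshold
                mates = [g for g in genes if g.subclass == sub]
                for _ in range(40):
                    u = rng.uniform(46.0, 56.0)
                    prot = mutate_to_identity(rng, ancestor, u, protected)
                    anc_id = hamming_identity(prot, ancestor)
                    worst = max(
                        (hamming_identity(prot, m.protein_a or m.protein_b)
                         for m in mates), default=0.0)
                    if worst < 44.0:
                        break
                else:
                    raise RuntimeError("could not place a private gene below "
                                       "the distinct-gene threshold")
                gene = GeneTruth(
                    gene_id=f"{sub}-private-{pop}{j + 1}", subclass=sub,
                    gst_class=gst_class, present_in=pop,
                    protein_a=prot if pop == "a" else None,
                    protein_b=prot if pop == "b" else None,
                    ancestor_identity_realized=anc_id,
                    expression_level={s: v for s, v in
                                      _PROFILE_TYPES["flat"].items()},
                )
                genes.append(gene)
                proteins.append(ProteinRecord(f"{gene.gene_id}|{pop}", prot,
                                              label=f"{gst_class}|{sub}"))

    return proteins, GroundTruth(genes=genes, panel=panel, seed=seed)


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """Nucleotide CDS with uniform synonymous-codon choice (no stop)."""
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))]
                   for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _build_contig(rng: np.random.Generator, protein: str,
                  completeness: Completeness, gst_class: str,
                  utr_range: tuple[int, int]) -> tuple[str, str, Completeness]:
    """Contig sequence and the protein expected to be deduced from it."""
    cds = back_translate(rng, protein)
    u5, u3 = (int(rng.integers(utr_range[0], utr_range[1] + 1)) for _ in range(2))
    stop = _STOP_CODONS[int(rng.integers(3))]
    stop2 = _STOP_CODONS[int(rng.integers(3))]
    (cut_lo, cut_hi), min_keep = _TRUNCATION[gst_class]

    if completeness is Completeness.FULL_LENGTH:
        seq = _random_nt(rng, max(u5 - 3, 0)) + stop + cds + stop2 + _random_nt(rng, u3)
        return seq, protein, completeness
    if completeness is Completeness.N_TERMINAL_PARTIAL:
        keep = int(math.ceil(len(protein) * rng.uniform(min_keep, 0.85)))
        seq = _random_nt(rng, max(u5 - 3, 0)) + stop + cds[:3 * keep]
        return seq, protein[:keep], completeness
    if completeness is Completeness.C_TERMINAL_PARTIAL:
        for _ in range(50):
            cut = int(rng.integers(cut_lo, cut_hi + 1))
            if protein[cut] != "M":
                break
        seq = cds[3 * cut:] + stop2 + _random_nt(rng, u3)
        return seq, protein[cut:], completeness
    if completeness is Completeness.INTERNAL_FRAGMENT:
        for _ in range(50):
            cut = int(rng.integers(cut_lo, cut_hi + 1))
            if protein[cut] != "M":
                break
        keep = int(math.ceil(len(protein) * rng.uniform(min_keep, 0.9)))
        keep = max(keep, cut + 60)
        seq = cds[3 * cut:3 * keep]
        return seq, protein[cut:keep], completeness
    raise ValueError(f"generator does not plant {completeness}")


def embed_in_contigs(truth: GroundTruth, seed: int,
                     utr_range: tuple[int, int] = (30, 90),
                     n_decoys: int = 100,
                     fraction_partial: float = 0.15,
                     ) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Back-translate planted proteins into two decoy-laden assemblies.

    Full-length genes get random UTRs with an in-frame stop immediately
    upstream of the start codon; a ``fraction_partial`` subset of
    (gene, population) slots is truncated to one of the partial completeness
    classes.  Decoys are an even mix of random nucleotide contigs and
    back-translations of shuffled planted proteins.  Updates the truth with
    transcript ids, planted completeness and expected deduced proteins.
    """
    if not (utr_range[0] >= 4 and utr_range[1] <= 120):
        # UTRs above ~120 nt could harbour spurious ORFs at the default
        # minimum ORF length; below 4 nt there is no room for the upstream stop
        raise ValueError("utr_range must lie within [4, 120]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7919)))
    assemblies: dict[str, list[TranscriptRecord]] = {"a": [], "b": []}
    labels = {"a": "population_A", "b": "population_B"}

    for gene in truth.genes:
        for pop in ("a", "b"):
            protein = gene.protein_a if pop == "a" else gene.protein_b
            if protein is None:
                continue
            if rng.random() < fraction_partial:
                completeness = _PARTIAL_CLASSES[int(rng.integers(3))]
            else:
                completeness = Completeness.FULL_LENGTH
            seq, deduced, completeness = _build_contig(
                rng, protein, completeness, gene.gst_class, utr_range)
            rec = TranscriptRecord(f"tmp-{gene.gene_id}-{pop}", seq,
                                   assembly=labels[pop])
            assemblies[pop].append(rec)
            if pop == "a":
                gene.completeness_a, gene.deduced_a = completeness, deduced
            else:
                gene.completeness_b, gene.deduced_b = completeness, deduced

    planted_proteins = [g.protein_a or g.protein_b for g in truth.genes]
    decoy_keys: dict[str, list[str]] = {"a": [], "b": []}
    for pop in ("a", "b"):
        for d in range(n_decoys):
            if d % 2 == 0:
                seq = _random_nt(rng, int(rng.integers(400, 1200)))
            else:
                src = planted_proteins[int(rng.integers(len(planted_proteins)))]
                shuffled = "".join(np.array(list(src))[
                    rng.permutation(len(src))])
                seq = back_translate(rng, shuffled)
            rec = TranscriptRecord(f"tmp-decoy-{pop}-{d}", seq,
                                   assembly=labels[pop])
            assemblies[pop].append(rec)
            decoy_keys[pop].append(rec.id)

    # accession-style ids over a shuffled contig order
    prefix = {"a": "SYNA01", "b": "SYNB01"}
    final: dict[str, list[TranscriptRecord]] = {}
    for pop in ("a", "b"):
        contigs = assemblies[pop]
        order = rng.permutation(len(contigs))
        renamed = {}
        out = []
        for new_idx, old_idx in enumerate(order):
            rec = contigs[int(old_idx)]
            new_id = f"{prefix[pop]}{new_idx + 1:06d}"
            renamed[rec.id] = new_id
            out.append(TranscriptRecord(new_id, rec.seq, assembly=rec.assembly))
        final[pop] = out
        for gene in truth.genes:
            tmp = f"tmp-{gene.gene_id}-{pop}"
            if tmp in renamed:
                if pop == "a":
                    gene.transcript_a = renamed[tmp]
                else:
                    gene.transcript_b = renamed[tmp]
        decoys = [renamed[k] for k in decoy_keys[pop]]
        if pop == "a":
            truth.decoys_a = decoys
        else:
            truth.decoys_b = decoys
    return final["a"], final["b"]


def simulate_counts(truth: GroundTruth,
                    stages: Sequence[str] = DEFAULT_STAGES,
                    replicates: int = 3,
                    depth: int = 2_000_000,
                    seed: int = 0,
                    sigma: float = 0.25,
                    background_weight: float = 25.0,
                    population: str = "a",
                    assembly: Optional[Sequence[TranscriptRecord]] = None,
                    ) -> CountTable:
    """Multinomial read counts over the planted transcripts of one population.

    Per library, each transcript's sampling weight is its planted stage level
    times its length (kb) times log-normal replicate noise (sd ``sigma`` in
    natural log units).  A background mass — ``background_weight`` times the
    stage-averaged catalog weight, identical for every library — absorbs the
    reads mapping to the rest of the transcriptome, so the catalog is a small
    slice of each library (as for a single gene family in a whole
    transcriptome) and RPKM stays comparable across stages.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 104729)))
    genes = [g for g in truth.genes if g.present_in in ("both", population)]
    tids = [(g.transcript_a if population == "a" else g.transcript_b)
            for g in genes]
    if any(t is None for t in tids):
        raise ValueError("run embed_in_contigs before simulate_counts")
    if assembly is not None:
        lengths = pd.Series({t.id: t.length_bp for t in assembly}).reindex(tids)
    else:
        # transcript length approximated by CDS length of the deduced protein
        lengths = pd.Series(
            [3 * len(g.deduced_a if population == "a" else g.deduced_b) + 60
             for g in genes], index=tids, dtype=float)
    len_kb = lengths.to_numpy() / 1e3

    cols = pd.MultiIndex.from_tuples(
        [(s, str(r + 1)) for s in stages for r in range(replicates)],
        names=["stage", "replicate"])
    counts = pd.DataFrame(0, index=tids, columns=cols, dtype=int)
    mean_levels = np.array([np.mean([g.expression_level.get(s, 0.0)
                                     for s in stages]) for g in genes])
    bg = background_weight * float((mean_levels * len_kb).sum())
    for s in stages:
        levels = np.array([g.expression_level.get(s, 0.0) for g in genes])
        for r in range(replicates):
            noise = np.exp(rng.normal(0.0, sigma, size=len(genes)))
            w = levels * noise * len_kb
            p = np.append(w, bg)
            p = p / p.sum()
            draw = rng.multinomial(depth, p)
            counts[(s, str(r + 1))] = draw[:-1]
    total = pd.Series(depth, index=cols)
    return CountTable(counts, total, lengths)


def default_specs() -> list[FamilySpec]:
    """The default two-population scenario composition.

    Population A carries 39 genes (Delta 11, Theta 1, Mu 5, Omega 3,
    Sigma 10, Zeta 2, Kappa 1, mGST-1 2, mGST-3 4); population B additionally
    carries one private Omega and one private Delta gene, so the merged
    catalog holds 41 genes.
    """
    n = {"Delta": 11, "Theta": 1, "Mu": 5, "Omega": 3, "Sigma": 10,
         "Zeta": 2, "Kappa": 1, "mGST-1": 2, "mGST-3": 4}
    specs = []
    for sub, count in n.items():
        private = (0, 1) if sub in ("Omega", "Delta") else (0, 0)
        specs.append(FamilySpec(subclass_name=sub, n_genes=count,
                                private_genes=private))
    return specs


@dataclass
class SyntheticDataset:
    assembly_a: list[TranscriptRecord]
    assembly_b: list[TranscriptRecord]
    panel: list[ProteinRecord]
    truth: GroundTruth
    counts: CountTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.assembly_a, outdir / "assembly_population_A.fasta")
        write_fasta(self.assembly_b, outdir / "assembly_population_B.fasta")
        write_fasta(self.panel, outdir / "reference_panel.fasta")
        self.truth.to_json(outdir / "ground_truth.json")
        self.counts.to_tsv(outdir / "counts.tsv", outdir / "library_sizes.tsv")


def default_scenario(seed: int, n_decoys: int = 100,
                     specs: Optional[Sequence[FamilySpec]] = None,
                     replicates: int = 3,
                     depth: int = 2_000_000) -> SyntheticDataset:
    """Generate the full default two-population dataset for one seed."""
    specs = list(specs) if specs is not None else default_specs()
    _, truth = generate_families(specs, seed)
    asm_a, asm_b = embed_in_contigs(truth, seed, n_decoys=n_decoys)
    counts = simulate_counts(truth, replicates=replicates, depth=depth,
                             seed=seed, assembly=asm_a)
    return SyntheticDataset(asm_a, asm_b, truth.panel, truth, counts)
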