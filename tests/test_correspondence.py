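import numpy as np
import pytest

from gstmine.correspond import (Verdict, detect_additional_genes,
                                match_assemblies, merge_catalogs,
                                verdict_for_identity)
from gstmine.mining import AnnotationRecord
from gstmine.orf import Completeness, DeducedProtein
from gstmine.records import TranscriptRecord
from gstmine.simulate import back_translate, mutate_to_identity

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_protein(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, size=n))


def annotated(pid, seq, subclass="Delta",
              completeness=Completeness.FULL_LENGTH):
    p = DeducedProtein(id=pid, transcript_id=pid, frame=1, aa_seq=seq,
                       aa_start=1, aa_end=len(seq), nt_start=1,
                       nt_end=3 * len(seq), has_upstream_stop=True,
                       has_start_met=True, has_downstream_stop=True,
                       completeness=completeness)
    ann = AnnotationRecord(pid, "cytosolic", subclass, "ref", f"cytosolic|{subclass}",
                           500.0, 0.0, 0.0)
    return (p, ann)


@pytest.mark.parametrize("identity,expected", [
    (99, Verdict.SAME_GENE), (95, Verdict.SAME_GENE), (90, Verdict.SAME_GENE),
    (88, Verdict.DIVERGENT_ORTHOLOG), (60, Verdict.DIVERGENT_ORTHOLOG),
    (50, Verdict.DIVERGENT_ORTHOLOG), (48, Verdict.DISTINCT_GENE),
    (30, Verdict.DISTINCT_GENE),
])
def test_verdict_thresholds(identity, expected):
    assert verdict_for_identity(identity) is expected


def test_planted_identities_map_to_verdicts():
    rng = np.random.default_rng(0)
    base = {t: "M" + rand_protein(rng, 219) for t in (99, 95, 88, 48)}
    set_a = [annotated(f"a{t}", seq) for t, seq in base.items()]
    set_b = [annotated(f"b{t}", mutate_to_identity(rng, seq, float(t)))
             for t, seq in base.items()]
    # distinct base proteins: cross identities are ~5%, so BBH pairs each
    # a-protein with its own planted variant
    pairs = {p.protein_a_id: p for p in match_assemblies(set_a, set_b)}
    assert pairs["a99"].verdict is Verdict.SAME_GENE
    assert pairs["a95"].verdict is Verdict.SAME_GENE
    assert pairs["a88"].verdict is Verdict.DIVERGENT_ORTHOLOG
    assert pairs["a48"].verdict is Verdict.DISTINCT_GENE


def test_pairing_symmetric():
    rng = np.random.default_rng(1)
    base = ["M" + rand_protein(rng, 199) for _ in range(4)]
    set_a = [annotated(f"a{i}", s) for i, s in enumerate(base)]
    set_b = [annotated(f"b{i}", mutate_to_identity(rng, s, 93.0))
             for i, s in enumerate(base)]
    ab = {(p.protein_a_id, p.protein_b_id, p.verdict)
          for p in match_assemblies(set_a, set_b)}
    ba = {(p.protein_b_id, p.protein_a_id, p.verdict)
          for p in match_assemblies(set_b, set_a)}
    assert ab == ba


def test_partial_partner_scored_on_overlap():
    rng = np.random.default_rng(2)
    full = "M" + rand_protein(rng, 219)
    variant = mutate_to_identity(rng, full, 95.0)
    set_a = [annotated("a", full)]
    set_b = [annotated("b", variant[60:180],
                       completeness=Completeness.INTERNAL_FRAGMENT)]
    (pair,) = match_assemblies(set_a, set_b)
    assert pair.verdict is Verdict.SAME_GENE
    assert pair.overlap_identity_pct >= 90


class TestAdditionalGenes:
    def test_private_gene_reported_additional(self):
        rng = np.random.default_rng(3)
        shared = "M" + rand_protein(rng, 209)
        private = "M" + rand_protein(rng, 209)  # unrelated: ~5% identity
        set_a = [annotated("a1", shared)]
        set_b = [annotated("b1", mutate_to_identity(rng, shared, 97.0)),
                 annotated("b_priv", private)]
        pairs = match_assemblies(set_a, set_b)
        additional, pairs = detect_additional_genes(pairs, set_a, set_b)
        assert additional == ["b_priv"]

    def test_candidate_with_near_identical_fragment_upgraded(self):
        rng = np.random.default_rng(4)
        shared = "M" + rand_protein(rng, 209)
        candidate = "M" + rand_protein(rng, 209)
        set_a = [annotated("a1", shared)]
        set_b = [annotated("b1", mutate_to_identity(rng, shared, 97.0)),
                 annotated("b_cand", candidate)]
        # assembly A contains an unannotated contig encoding a 99%-identical
        # fragment of the candidate (missed by primary mining)
        fragment = mutate_to_identity(rng, candidate, 99.0)[50:190]
        rescue_contig = TranscriptRecord(
            "rescue", back_translate(rng, fragment) + "TAA")
        pairs = match_assemblies(set_a, set_b)
        additional, pairs = detect_additional_genes(
            pairs, set_a, set_b, assembly_a=[rescue_contig], assembly_b=None)
        assert additional == []
        upgraded = [p for p in pairs if p.protein_b_id == "b_cand"]
        assert upgraded[0].verdict is Verdict.SAME_GENE
        assert "present in both" in upgraded[0].note

    def test_no_unmatched_means_no_candidates(self):
        rng = np.random.default_rng(5)
        s = "M" + rand_protein(rng, 199)
        set_a = [annotated("a1", s)]
        set_b = [annotated("b1", s)]
        pairs = match_assemblies(set_a, set_b)
        additional, _ = detect_additional_genes(pairs, set_a, set_b)
        assert additional == []


class TestMergeCatalogs:
    def test_identical_assemblies_merge_one_to_one(self):
        rng = np.random.default_rng(6)
        seqs = ["M" + rand_protein(rng, 199) for _ in range(3)]
        set_a = [annotated(f"a{i}", s) for i, s in enumerate(seqs)]
        set_b = [annotated(f"b{i}", s) for i, s in enumerate(seqs)]
        pairs = match_assemblies(set_a, set_b)
        catalog = merge_catalogs(pairs, set_a, set_b)
        assert catalog.total == 3
        assert all(e.verdict is Verdict.SAME_GENE for e in catalog.entries)

    def test_distinct_gene_pair_counts_two(self):
        rng = np.random.default_rng(7)
        s = "M" + rand_protein(rng, 199)
        set_a = [annotated("a1", s)]
        set_b = [annotated("b1", mutate_to_identity(rng, s, 45.0))]
        pairs = match_assemblies(set_a, set_b)
        assert pairs[0].verdict is Verdict.DISTINCT_GENE
        catalog = merge_catalogs(pairs, set_a, set_b)
        assert catalog.total == 2

    def test_completeness_upgraded_to_best_evidence(self):
        rng = np.random.default_rng(8)
        s = "M" + rand_protein(rng, 199)
        set_a = [annotated("a1", s[:120],
                           completeness=Completeness.N_TERMINAL_PARTIAL)]
        set_b = [annotated("b1", s)]
        pairs = match_assemblies(set_a, set_b)
        catalog = merge_catalogs(pairs, set_a, set_b)
        assert catalog.entries[0].completeness is Completeness.FULL_LENGTH

    def test_unmatched_contributes_one_gene(self):
        rng = np.random.default_rng(9)
        set_a = [annotated("a1", "M" + rand_protein(rng, 199))]
        set_b = []
        pairs = match_assemblies(set_a, set_b)
        catalog = merge_catalogs(pairs, set_a, set_b)
        assert catalog.total == 1
        assert catalog.entries[0].verdict is Verdict.UNMATCHED
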