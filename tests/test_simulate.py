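import filecmp

import numpy as np
import pytest

from gstmine.mining import mine_assembly
from gstmine.orf import Completeness, extract_orfs
from gstmine.records import write_fasta
from gstmine.simulate import (FamilySpec, default_scenario, default_specs,
                              embed_in_contigs, generate_families,
                              hamming_identity, mutate_to_identity,
                              simulate_counts)


class TestFamilySpec:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            FamilySpec("Delta", 0)
        with pytest.raises(ValueError):
            FamilySpec("Delta", 1, within_identity_range=(0, 50))
        with pytest.raises(ValueError):
            FamilySpec("NotASubclass", 1)

    def test_default_scenario_composition(self):
        counts = {s.subclass_name: s.n_genes for s in default_specs()}
        assert counts == {"Delta": 11, "Theta": 1, "Mu": 5, "Omega": 3,
                          "Sigma": 10, "Zeta": 2, "Kappa": 1, "mGST-1": 2,
                          "mGST-3": 4}
        privates = sum(sum(s.private_genes) for s in default_specs())
        assert privates == 2


class TestMutation:
    def test_identity_target_reached_within_tolerance(self):
        rng = np.random.default_rng(0)
        seq = "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                            for i in rng.integers(0, 20, size=200))
        for target in (95.0, 70.0, 40.0):
            mut = mutate_to_identity(rng, seq, target)
            assert abs(hamming_identity(mut, seq) - target) <= 1.0

    def test_identity_100_is_a_copy(self):
        rng = np.random.default_rng(1)
        (prots, truth) = generate_families(
            [FamilySpec("Delta", 1, within_identity_range=(100, 100),
                        cross_population_identity_range=(100, 100))], seed=3)
        g = truth.genes[0]
        assert g.protein_a == g.protein_b

    def test_infeasible_target_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="infeasible"):
            mutate_to_identity(rng, "MKVLF", 10.0, frozenset({0, 1, 2, 3}))

    def test_similarity_exceeds_identity(self):
        # group-biased substitution keeps similarity above identity
        from gstmine.align import pairwise_identity
        rng = np.random.default_rng(3)
        seq = "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                            for i in rng.integers(0, 20, size=150))
        mut = mutate_to_identity(rng, seq, 50.0)
        rep = pairwise_identity(seq, mut)
        assert rep.pct_similarity >= rep.pct_identity + 15


class TestGenerateFamilies:
    def test_realized_identities_recorded_and_in_band(self):
        _, truth = generate_families(
            [FamilySpec("Sigma", 4,
                        cross_population_identity_range=(88.0, 100.0))], seed=7)
        for g in truth.genes:
            assert 88.0 - 1.0 <= g.cross_identity_realized <= 100.0
            assert abs(g.cross_identity_realized - g.cross_identity_target) <= 1.0

    def test_within_subclass_pairwise_identity_in_paralog_band(self):
        _, truth = generate_families([FamilySpec("Delta", 6)], seed=8)
        prots = [g.protein_a for g in truth.genes]
        pairwise = [hamming_identity(a, b)
                    for i, a in enumerate(prots) for b in prots[i + 1:]]
        assert all(20.0 <= p <= 70.0 for p in pairwise)

    def test_private_genes_below_distinct_threshold(self):
        _, truth = generate_families(
            [FamilySpec("Omega", 3, private_genes=(0, 1))], seed=9)
        private = [g for g in truth.genes if g.present_in == "b"]
        assert len(private) == 1
        others = [g.protein_b for g in truth.genes if g.present_in == "both"]
        assert all(hamming_identity(private[0].protein_b, o) < 46 for o in others)

    def test_panel_labelled_per_subclass(self):
        _, truth = generate_families([FamilySpec("Kappa", 1)], seed=10)
        assert {p.label for p in truth.panel} == {"mitochondrial|Kappa"}
        assert len(truth.panel) == 2


@pytest.fixture(scope="module")
def embedded():
    specs = [FamilySpec("Delta", 3, fraction_partial=0.5),
             FamilySpec("mGST-1", 2, fraction_partial=0.5)]
    _, truth = generate_families(specs, seed=11)
    asm_a, asm_b = embed_in_contigs(truth, seed=11, n_decoys=6)
    return truth, asm_a, asm_b


class TestEmbedding:
    def test_planted_completeness_recovered_by_orf_finder(self, embedded):
        truth, asm_a, asm_b = embedded
        by_id = {t.id: t for t in asm_a + asm_b}
        for g in truth.genes:
            for tid, comp, planted in ((g.transcript_a, g.completeness_a, g.deduced_a),
                                       (g.transcript_b, g.completeness_b, g.deduced_b)):
                orfs = extract_orfs(by_id[tid], 40)
                match = [o for o in orfs if o.aa_seq == planted]
                assert match, f"planted protein not recovered from {tid}"
                assert match[0].completeness is comp

    def test_decoys_yield_no_hits(self, embedded):
        truth, asm_a, _ = embedded
        decoys = [t for t in asm_a if t.id in set(truth.decoys_a)]
        assert len(decoys) == 6
        hits = mine_assembly(truth.panel, decoys, evalue_cutoff=1e-5)
        assert hits == []

    def test_truth_maps_transcripts(self, embedded):
        truth, asm_a, asm_b = embedded
        ids_a = {t.id for t in asm_a}
        for g in truth.genes:
            assert g.transcript_a in ids_a
            assert truth.gene_by_transcript(g.transcript_a) is g


def test_generator_deterministic_byte_identical(tmp_path):
    for run in ("r1", "r2"):
        ds = default_scenario(13, n_decoys=5,
                              specs=[FamilySpec("Zeta", 2)], depth=100_000)
        d = tmp_path / run
        d.mkdir()
        write_fasta(ds.assembly_a, d / "a.fasta")
        write_fasta(ds.assembly_b, d / "b.fasta")
        write_fasta(ds.panel, d / "panel.fasta")
    for name in ("a.fasta", "b.fasta", "panel.fasta"):
        assert filecmp.cmp(tmp_path / "r1" / name, tmp_path / "r2" / name,
                           shallow=False)


class TestCounts:
    def test_doubling_depth_doubles_counts(self):
        _, truth = generate_families([FamilySpec("Mu", 3)], seed=14)
        embed_in_contigs(truth, seed=14, n_decoys=0)
        c1 = simulate_counts(truth, depth=500_000, seed=14)
        c2 = simulate_counts(truth, depth=1_000_000, seed=14)
        ratio = c2.counts.values.sum() / c1.counts.values.sum()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_library_totals_exceed_catalog(self):
        _, truth = generate_families([FamilySpec("Mu", 2)], seed=15)
        embed_in_contigs(truth, seed=15, n_decoys=0)
        ct = simulate_counts(truth, depth=200_000, seed=15)
        assert (ct.counts.sum(axis=0) < ct.total_mapped).all()

    def test_depth_must_be_positive(self):
        _, truth = generate_families([FamilySpec("Mu", 1)], seed=16)
        embed_in_contigs(truth, seed=16, n_decoys=0)
        with pytest.raises(ValueError):
            simulate_counts(truth, depth=0, seed=16)


def test_dataset_write_layout(tmp_path, small_scenario):
    small_scenario.write(tmp_path / "out")
    names = {p.name for p in (tmp_path / "out").iterdir()}
    assert {"assembly_population_A.fasta", "assembly_population_B.fasta",
            "reference_panel.fasta", "ground_truth.json", "counts.tsv",
            "library_sizes.tsv"} <= names
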