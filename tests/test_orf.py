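import numpy as np
import pytest

from gstmine.orf import (Completeness, classify, extract_orfs,
                         pick_protein_for_hit)
from gstmine.records import ProteinRecord, TranscriptRecord, revcomp, translate
from gstmine.simulate import back_translate

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein(rng, n, start_met=True):
    seq = "".join(AA[i] for i in rng.integers(0, 20, size=n))
    return ("M" + seq[1:]) if start_met else seq.replace("M", "L")


def cds_for(rng, prot):
    return back_translate(rng, prot)


@pytest.mark.parametrize("upstream,met,downstream,expected", [
    (True, True, True, Completeness.FULL_LENGTH),
    (False, True, True, Completeness.PUTATIVE_FULL_LENGTH),
    (True, False, True, Completeness.C_TERMINAL_PARTIAL),
    (False, False, True, Completeness.C_TERMINAL_PARTIAL),
    (True, True, False, Completeness.N_TERMINAL_PARTIAL),
    (False, True, False, Completeness.N_TERMINAL_PARTIAL),
    (False, False, False, Completeness.INTERNAL_FRAGMENT),
])
def test_classification_truth_table(upstream, met, downstream, expected):
    assert classify(upstream, met, downstream) is expected


class TestExtraction:
    rng = np.random.default_rng(10)

    def test_full_length_orf(self):
        prot = protein(self.rng, 61)
        t = TranscriptRecord("t", "ACGTAC" + "TAA" + cds_for(self.rng, prot)
                             + "TGA" + "GGCC")
        orfs = extract_orfs(t, min_orf_len=40)
        full = [o for o in orfs if o.completeness is Completeness.FULL_LENGTH]
        assert len(full) == 1
        assert full[0].aa_seq == prot
        assert full[0].aa_seq.startswith("M")

    def test_c_terminal_partial_when_no_start_met(self):
        prot = protein(self.rng, 60, start_met=False)
        t = TranscriptRecord("t", cds_for(self.rng, prot) + "TAA" + "ACGT")
        orfs = extract_orfs(t, 40)
        assert any(o.completeness is Completeness.C_TERMINAL_PARTIAL
                   and o.aa_seq == prot for o in orfs)

    def test_n_terminal_partial_on_stop_free_end(self):
        prot = protein(self.rng, 60)
        t = TranscriptRecord("t", "TGA" + cds_for(self.rng, prot))
        orfs = extract_orfs(t, 40)
        assert any(o.completeness is Completeness.N_TERMINAL_PARTIAL
                   and o.aa_seq == prot for o in orfs)

    def test_internal_fragment(self):
        prot = protein(self.rng, 60, start_met=False)
        t = TranscriptRecord("t", cds_for(self.rng, prot))
        orfs = extract_orfs(t, 40)
        assert any(o.completeness is Completeness.INTERNAL_FRAGMENT
                   and o.aa_seq == prot for o in orfs)

    def test_putative_full_length_without_upstream_stop(self):
        prot = protein(self.rng, 60)
        t = TranscriptRecord("t", cds_for(self.rng, prot) + "TAA")
        orfs = extract_orfs(t, 40)
        assert any(o.completeness is Completeness.PUTATIVE_FULL_LENGTH
                   and o.aa_seq == prot for o in orfs)

    def test_met_form_and_full_stretch_both_reported(self):
        lead = protein(self.rng, 45, start_met=False)
        prot = protein(self.rng, 60)
        t = TranscriptRecord("t", cds_for(self.rng, lead + prot) + "TAA")
        orfs = extract_orfs(t, 40)
        seqs = {o.aa_seq for o in orfs if o.frame == 1}
        assert lead + prot in seqs       # full stretch (c-terminal partial)
        assert prot in seqs              # Met-initiated resolution

    def test_min_orf_len_filters(self):
        prot = protein(self.rng, 30)
        t = TranscriptRecord("t", "TAA" + cds_for(self.rng, prot) + "TGA")
        assert extract_orfs(t, 40) == []
        assert len(extract_orfs(t, 20)) >= 1
        with pytest.raises(ValueError):
            extract_orfs(t, 0)


def test_coordinates_roundtrip_to_protein():
    rng = np.random.default_rng(77)
    for _ in range(20):
        nt = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(150, 600))))
        t = TranscriptRecord("t", nt)
        for o in extract_orfs(t, min_orf_len=20):
            sub = t.seq[o.nt_start - 1:o.nt_end]
            if o.frame < 0:
                sub = revcomp(sub)
            assert translate(sub, 1) == o.aa_seq


class TestPickProtein:
    rng = np.random.default_rng(21)

    def test_single_orf_returned(self):
        prot = protein(self.rng, 50)
        t = TranscriptRecord("t", "TAA" + cds_for(self.rng, prot) + "TGA")
        orfs = [o for o in extract_orfs(t, 40) if o.aa_seq == prot]
        assert len(orfs) == 1
        query = ProteinRecord("q", prot)
        assert pick_protein_for_hit(orfs, query) is orfs[0]

    def test_higher_scoring_orf_wins(self):
        target = protein(self.rng, 60)
        other = protein(self.rng, 60)
        t = TranscriptRecord("t", "TAA" + cds_for(self.rng, target) + "TGA"
                             + "TAA" + cds_for(self.rng, other) + "TGA")
        orfs = extract_orfs(t, 40)  # forward ORFs plus incidental ones
        picked = pick_protein_for_hit(orfs, ProteinRecord("q", target))
        assert picked.aa_seq == target
        picked = pick_protein_for_hit(orfs, ProteinRecord("q", other))
        assert picked.aa_seq == other

    def test_tie_prefers_met_form_matching_query_start(self):
        # the full stretch and its Met form tie on local score; the Met form
        # whose Met matches the query start is the deduced protein
        lead = protein(self.rng, 45, start_met=False)
        prot = protein(self.rng, 60)
        t = TranscriptRecord("t", cds_for(self.rng, lead + prot) + "TAA")
        orfs = extract_orfs(t, 40)
        picked = pick_protein_for_hit(orfs, ProteinRecord("q", prot))
        assert picked.aa_seq == prot

    def test_tie_without_met_anchor_prefers_longer(self):
        # query unrelated to either ORF: all scores equal (likely 0-ish
        # positives); construct two ORFs sharing an identical segment
        seg = protein(self.rng, 50, start_met=False)
        t = TranscriptRecord(
            "t", cds_for(self.rng, seg) + "TAA"
            + cds_for(self.rng, seg + protein(self.rng, 10, start_met=False))
            + "TGA")
        orfs = [o for o in extract_orfs(t, 40) if o.frame == 1
                and o.aa_seq.startswith(seg[:10])]
        assert len(orfs) == 2
        picked = pick_protein_for_hit(orfs, ProteinRecord("q", seg))
        assert picked.length_aa == max(o.length_aa for o in orfs)

    def test_putative_promoted_when_met_matches_query_start(self):
        prot = protein(self.rng, 60)
        t = TranscriptRecord("t", cds_for(self.rng, prot) + "TAA")
        orfs = [o for o in extract_orfs(t, 40)
                if o.completeness is Completeness.PUTATIVE_FULL_LENGTH]
        picked = pick_protein_for_hit(orfs, ProteinRecord("q", prot))
        assert picked.completeness is Completeness.FULL_LENGTH

    def test_empty_orfs_raise(self):
        with pytest.raises(ValueError):
            pick_protein_for_hit([], ProteinRecord("q", "MKV"))
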