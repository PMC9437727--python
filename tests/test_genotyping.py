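"""Clone alignment, SNP masking, edit classification and trace deconvolution."""

import numpy as np
import pytest

from miredit import genotyping as gt
from miredit.simulate import (
    EditProfile,
    make_locus,
    simulate_amplicon_clones,
    simulate_edits,
    simulate_sanger_trace,
)
from miredit.types import MutationCall


@pytest.fixture(scope="module")
def nt_panel(locus):
    clones, _ = simulate_amplicon_clones(
        [(a, 0.25) for a in locus.allele_seqs], 20, seed=3
    )
    return gt.build_nt_panel(
        [gt.align_clone(c, locus, f"nt{i}", allele_index=0) for i, c in enumerate(clones)]
    )


class TestAlignClone:
    def test_identical_to_allele2(self, locus):
        aln = gt.align_clone(locus.allele_seqs[1], locus)
        assert aln.best_allele_index == 1
        assert aln.ops == []

    def test_constructed_deletion_recovered(self, locus):
        c1, _ = locus.cut_positions
        ref = locus.allele_seqs[0]
        clone = ref[: c1 - 1] + ref[c1 + 2 :]  # 3-nt deletion at the cut
        aln = gt.align_clone(clone, locus)
        assert aln.best_allele_index == 0
        dels = [op for op in aln.ops if op.kind == "del"]
        assert len(dels) == 1 and dels[0].length == 3
        # left-normalized span must cover the cut region
        assert abs(dels[0].pos - (c1 - 1)) <= 3

    def test_alphabet_validation(self, locus):
        with pytest.raises(ValueError):
            gt.align_clone("ACGU", locus)
        with pytest.raises(ValueError):
            gt.align_clone("", locus)

    def test_reconstruction_invariant_on_simulated_clones(self, locus):
        edits = simulate_edits(locus, EditProfile(seed=21), 30)
        for i, e in enumerate(edits):
            aln = gt.align_clone(e.edited_seq, locus, f"c{i}")
            assert gt.apply_ops(locus.allele_seqs[aln.best_allele_index], aln.ops) == e.edited_seq

    def test_ops_equal_simulated_truth_for_single_edit_clones(self, locus):
        """Alignment ops match simulator ground truth after left-normalization."""
        edits = simulate_edits(locus, EditProfile(seed=8), 200)
        for e in edits:
            if e.call.type == "none":
                continue
            src = locus.allele_seqs[e.allele_index]
            if e.call.type == "insertion":
                truth_op = gt.DiffOp(
                    "ins", e.call.span[0], 1, alt=e.call.inserted_base
                )
            else:
                lo, hi = e.call.span
                truth_op = gt.DiffOp("del", lo, hi - lo, ref=src[lo:hi])
            truth = gt._normalize_ops(src, [truth_op])
            aln = gt.align_clone(e.edited_seq, locus)
            indels = [op for op in aln.ops if op.kind != "sub"]
            assert indels == truth, (e.call, indels)


class TestMaskPolymorphism:
    def test_nt_snp_only_clone_has_no_candidates(self, locus, nt_panel):
        aln = gt.align_clone(locus.allele_seqs[2], locus, allele_index=0)
        assert all(op.kind == "sub" for op in aln.ops)
        assert gt.mask_polymorphism(aln, nt_panel) == []

    def test_deletion_survives_masking(self, locus, nt_panel):
        c1, _ = locus.cut_positions
        src = locus.allele_seqs[2]
        clone = src[:c1] + src[c1 + 2 :]
        aln = gt.align_clone(clone, locus, allele_index=0)
        kept = gt.mask_polymorphism(aln, nt_panel)
        assert all(op.kind == "del" for op in kept)
        assert sum(op.length for op in kept) == 2

    def test_empty_panel_warns_and_keeps_everything(self, locus):
        aln = gt.align_clone(locus.allele_seqs[1], locus, allele_index=0)
        with pytest.warns(UserWarning, match="empty NT panel"):
            kept = gt.mask_polymorphism(aln, set())
        assert kept == aln.ops

    def test_no_snp_leakage_across_simulated_clones(self, locus, nt_panel):
        """Natural SNPs are never classified as edits (500 unedited clones)."""
        clones, _ = simulate_amplicon_clones(
            [(a, 0.25) for a in locus.allele_seqs], 500, seed=17
        )
        for clone in clones:
            aln = gt.align_clone(clone, locus)
            ops = gt.mask_polymorphism(aln, nt_panel)
            calls = gt.classify_mutation(ops, locus.guides, locus)
            assert [c.type for c in calls] == ["none"]


class TestClassify:
    def test_short_deletion_distance(self, locus):
        c1, _ = locus.cut_positions
        ops = [gt.DiffOp("del", c1 - 3, 2, ref="NN")]
        (call,) = gt.classify_mutation(ops, locus.guides, locus)
        assert call.type == "short_deletion"
        assert call.distance_to_cut == 1

    def test_single_t_insertion(self, locus):
        c1, _ = locus.cut_positions
        ops = [gt.DiffOp("ins", c1, 1, alt="T")]
        (call,) = gt.classify_mutation(ops, locus.guides, locus)
        assert call.type == "insertion"
        assert call.inserted_base == "T"
        assert call.distance_to_cut == 0

    def test_deletion_spanning_both_cuts_is_excision(self, locus):
        c1, c2 = locus.cut_positions
        ops = [gt.DiffOp("del", c1 - 2, (c2 - c1) + 4)]
        (call,) = gt.classify_mutation(ops, locus.guides, locus)
        assert call.type == "inter_guide_excision"

    def test_long_one_sided_deletion_is_large(self, locus):
        c1, c2 = locus.cut_positions
        ops = [gt.DiffOp("del", c1 - 10, 9)]
        (call,) = gt.classify_mutation(ops, locus.guides, locus)
        assert call.type == "large_deletion"

    def test_empty_ops_is_none(self, locus):
        (call,) = gt.classify_mutation([], locus.guides, locus)
        assert call.type == "none"

    def test_multi_edit_clone_reports_every_call(self, locus):
        c1, c2 = locus.cut_positions
        ops = [gt.DiffOp("del", c1 - 1, 2), gt.DiffOp("ins", c2, 1, alt="G")]
        calls = gt.classify_mutation(ops, locus.guides, locus)
        assert sorted(c.type for c in calls) == ["insertion", "short_deletion"]

    def test_overlap_with_mature_mir(self, locus):
        m_lo, m_hi = locus.mir5p_amplicon_span()
        ops = [gt.DiffOp("del", m_lo + 2, 3)]
        (call,) = gt.classify_mutation(ops, locus.guides, locus)
        assert call.overlaps_mir5p


class TestSummarize:
    def _calls(self, *types):
        return [[MutationCall(type=t, span=(0, 3) if "del" in t else (0, 0))]
                if t != "none" else [MutationCall(type="none")] for t in types]

    def test_fully_mutated_line(self):
        g = gt.summarize_line("L", self._calls(*["short_deletion"] * 10))
        assert g.mutated_fraction == 1.0
        assert g.all_alleles_mutated

    def test_unmutated_line(self):
        g = gt.summarize_line("L", self._calls(*["none"] * 5))
        assert g.mutated_fraction == 0.0
        assert not g.all_alleles_mutated

    def test_fractional(self):
        g = gt.summarize_line(
            "L", self._calls("short_deletion", "short_deletion", "short_deletion",
                             *["none"] * 6)
        )
        assert g.n_clones == 9 and g.n_mutated == 3
        assert g.mutated_fraction == pytest.approx(1 / 3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gt.summarize_line("L", [])


class TestKoScore:
    def _trace(self, locus, mixture, noise=0.0, seed=0):
        c1, _ = locus.cut_positions
        return simulate_sanger_trace(mixture, (c1 - 20, c1 + 120), noise, seed)

    def test_pure_wt_scores_zero(self, locus):
        tr = self._trace(locus, [(locus.allele_seqs[0], 1.0)])
        assert gt.ko_score(tr, locus).editing_rate == pytest.approx(0.0, abs=1e-6)

    def test_pure_deletion_scores_one(self, locus):
        c1, _ = locus.cut_positions
        ref = locus.allele_seqs[0]
        tr = self._trace(locus, [(ref[: c1 - 1] + ref[c1 + 1 :], 1.0)])
        assert gt.ko_score(tr, locus).editing_rate == pytest.approx(1.0, abs=1e-6)

    def test_mixture_recovery_within_tolerance(self, locus):
        c1, _ = locus.cut_positions
        ref = locus.allele_seqs[0]
        del2 = ref[: c1 - 1] + ref[c1 + 1 :]
        tr = self._trace(locus, [(ref, 0.7), (del2, 0.3)], noise=0.02, seed=5)
        score = gt.ko_score(tr, locus)
        assert score.editing_rate == pytest.approx(0.30, abs=0.03)
        assert score.signature_spectrum.get("del2", 0.0) == pytest.approx(0.30, abs=0.05)

    def test_proportions_normalized(self, locus):
        tr = self._trace(locus, [(locus.allele_seqs[0], 1.0)], noise=0.01, seed=2)
        score = gt.ko_score(tr, locus)
        assert sum(score.proportions.values()) == pytest.approx(1.0, abs=1e-6)

    def test_rank_check_flags_overcomplete_candidate_sets(self, locus):
        tr = self._trace(locus, [(locus.allele_seqs[0], 1.0)])
        with pytest.raises(gt.WindowRankError):
            gt.ko_score(tr, locus, check_rank=True)

    def test_polymorphic_control_inflates_score(self, locus):
        """With SNP-carrying material deconvolved against allele-1 candidates
        only, part of the unedited signal is attributed to edits — the known
        upward bias of trace deconvolution under polymorphism."""
        tr = self._trace(locus, [(locus.allele_seqs[1], 1.0)])  # unedited allele 2
        ref_only = [
            c for c in gt.enumerate_candidates(locus) if c[0] != "allele2"
        ]
        biased = gt.ko_score(tr, locus, candidate_edits=ref_only)
        full = gt.ko_score(tr, locus)
        assert full.editing_rate == pytest.approx(0.0, abs=1e-6)
        assert biased.editing_rate > full.editing_rate
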