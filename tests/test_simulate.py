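"""Synthetic-data generators: determinism, invariants, distributional checks."""

import numpy as np
import pytest
from scipy import stats

from miredit.simulate import (
    CurveSpec,
    EditProfile,
    PrecursorSpec,
    ReadSimConfig,
    SampleSpec,
    make_locus,
    simulate_amplicon_clones,
    simulate_edits,
    simulate_qpcr,
    simulate_sanger_trace,
    simulate_srna_reads,
)
from miredit.types import revcomp


class TestMakeLocus:
    def test_zero_snp_rate_gives_identical_alleles(self):
        locus = make_locus(seed=1, n_alleles=4, snp_rate=0.0)
        assert len(set(locus.allele_seqs)) == 1
        assert locus.snp_truth == []

    def test_determinism(self):
        a = make_locus(seed=1, n_alleles=4, snp_rate=0.01)
        b = make_locus(seed=1, n_alleles=4, snp_rate=0.01)
        assert a.allele_seqs == b.allele_seqs
        assert a.guides == b.guides

    def test_snp_count_within_binomial_interval(self):
        """~8 SNPs expected per 800-nt non-reference allele at rate 0.01."""
        locus = make_locus(seed=2, n_alleles=4, snp_rate=0.01)
        lo, hi = stats.binom.interval(0.99, 800, 0.01)
        for allele_idx in (1, 2, 3):
            n = sum(1 for a, *_ in locus.snp_truth if a == allele_idx)
            assert lo <= n <= hi

    def test_bounds_errors(self):
        with pytest.raises(ValueError):
            make_locus(seed=1, n_alleles=5)
        with pytest.raises(ValueError):
            make_locus(seed=1, n_alleles=0)
        with pytest.raises(ValueError):
            make_locus(seed=1, snp_rate=0.2)

    def test_guides_match_allele1_with_pam(self, locus):
        ref = locus.allele_seqs[0]
        g1, g2 = locus.guides
        assert ref[g1.pam_span[0] + 1 : g1.pam_span[1]] == "GG"
        assert ref[g2.pam_span[0] : g2.pam_span[1] - 1] == "CC"
        # cut between protospacer positions 17/18 on the protospacer strand
        assert g1.cut_pos == g1.protospacer_span[0] + 17
        assert g2.cut_pos == g2.protospacer_span[0] + 3

    def test_mature_spans_inside_precursor_and_disjoint(self, locus):
        p_len = locus.precursor_span[1] - locus.precursor_span[0]
        for lo, hi in (locus.mir5p_span, locus.mir3p_span):
            assert 0 <= lo < hi <= p_len
        assert locus.mir5p_span[1] <= locus.mir3p_span[0]

    def test_star_arm_pairs_mature_mir(self, locus):
        """The 3' arm carries the near-complement of the mature miR."""
        prec = locus.precursor_seq
        mir = locus.mature_mir5p
        m3lo, m3hi = locus.mir3p_span
        star = prec[m3lo:m3hi]
        # star sits 2 nt 3' of the exact partner window (canonical overhang)
        expected = revcomp(mir)
        overlap = sum(a == b for a, b in zip(star[:-2], expected[2:]))
        assert overlap >= len(mir) - 6  # the 2 duplex mismatches + edge effects

    def test_template_mode_requires_span(self):
        from miredit.simulate import LocusConstructionError

        with pytest.raises(LocusConstructionError):
            make_locus(seed=1, locus_template="ACGT" * 200)

    def test_template_mode_demands_pams(self):
        # a template with no G anywhere cannot host an NGG PAM
        template = "AT" * 400
        from miredit.simulate import LocusConstructionError

        with pytest.raises(LocusConstructionError):
            make_locus(
                seed=1, locus_template=template, template_mir5p_span=(390, 411)
            )


class TestSimulateEdits:
    def test_all_none_profile_returns_source(self, locus):
        profile = EditProfile(probabilities={"none": 1.0}, seed=1)
        for e in simulate_edits(locus, profile, 5):
            assert e.edited_seq == locus.allele_seqs[e.allele_index]
            assert e.call.type == "none"

    def test_excision_length_arithmetic(self, locus):
        c1, c2 = locus.cut_positions
        profile = EditProfile(probabilities={"inter_guide_excision": 1.0}, seed=1)
        for e in simulate_edits(locus, profile, 5):
            src = locus.allele_seqs[e.allele_index]
            assert len(e.edited_seq) == len(src) - (c2 - c1)
            assert e.edited_seq == src[:c1] + src[c2:]

    def test_truth_reconstruction(self, locus):
        """Edited sequence differs from source exactly by the recorded call."""
        profile = EditProfile(seed=3)
        for e in simulate_edits(locus, profile, 50):
            src = locus.allele_seqs[e.allele_index]
            lo, hi = e.call.span
            if e.call.type == "none":
                assert e.edited_seq == src
            elif e.call.type == "insertion":
                assert e.edited_seq == src[:lo] + e.call.inserted_base + src[lo:]
            else:
                assert e.edited_seq == src[:lo] + src[hi:]

    def test_class_frequencies_within_multinomial_interval(self, locus):
        probs = {"short_deletion": 0.6, "insertion_T": 0.4}
        profile = EditProfile(probabilities=probs, seed=11)
        edits = simulate_edits(locus, profile, 1000)
        n_del = sum(e.drawn_class == "short_deletion" for e in edits)
        lo, hi = stats.binom.interval(0.99, 1000, 0.6)
        assert lo <= n_del <= hi

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            EditProfile(probabilities={"none": 0.5})
        with pytest.raises(ValueError):
            EditProfile(probabilities={"typo": 1.0})


class TestAmpliconClones:
    def test_single_source(self):
        clones, idx = simulate_amplicon_clones([("ACGT", 1.0)], 10, seed=1)
        assert clones == ["ACGT"] * 10 and idx == [0] * 10

    def test_zero_clones(self):
        assert simulate_amplicon_clones([("ACGT", 1.0)], 0, seed=1) == ([], [])

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            simulate_amplicon_clones([], 10, seed=1)

    def test_split_within_binomial_interval(self):
        clones, _ = simulate_amplicon_clones(
            [("AAAA", 0.5), ("CCCC", 0.5)], 10_000, seed=5
        )
        n_a = sum(c == "AAAA" for c in clones)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= n_a <= hi

    def test_determinism(self):
        a = simulate_amplicon_clones([("AA", 0.3), ("CC", 0.7)], 100, seed=9)
        b = simulate_amplicon_clones([("AA", 0.3), ("CC", 0.7)], 100, seed=9)
        assert a == b


class TestSangerTrace:
    def test_single_sequence_is_one_hot(self):
        tr = simulate_sanger_trace([("ACGTACGT", 1.0)], (0, 8), noise=0.0)
        assert np.all(np.isin(tr.matrix, [0.0, 1.0]))
        assert tr.matrix[0, 0] == 1.0  # A at position 0

    def test_mixture_blends_offset_bases(self):
        wt = "AAACCCGGGTTTAAACCCGGG"
        mut = wt[:6] + wt[8:]  # 2-nt deletion at position 6
        tr = simulate_sanger_trace([(wt, 0.7), (mut, 0.3)], (0, 18), noise=0.0)
        col = tr.matrix[:, 8]  # wt has G, mut has T (shifted)
        assert col[2] == pytest.approx(0.7)  # G row
        assert col[3] == pytest.approx(0.3)  # T row

    def test_noise_is_reproducible_and_columns_stochastic(self):
        mix = [("ACGTACGTACGT", 0.5), ("ACGAACGTACGT", 0.5)]
        a = simulate_sanger_trace(mix, (0, 12), noise=0.05, seed=3)
        b = simulate_sanger_trace(mix, (0, 12), noise=0.05, seed=3)
        assert np.array_equal(a.matrix, b.matrix)
        assert np.allclose(a.matrix.sum(axis=0), 1.0)

    def test_window_outside_sequences_raises(self):
        with pytest.raises(IndexError):
            simulate_sanger_trace([("ACGT", 1.0)], (10, 20))

    def test_tsv_roundtrip(self, tmp_path):
        tr = simulate_sanger_trace([("ACGTACGTAC", 1.0)], (2, 8), noise=0.05, seed=1)
        path = tmp_path / "trace.tsv"
        tr.to_tsv(path, header="seed=1")
        back = type(tr).from_tsv(path)
        assert back.window == tr.window
        assert np.allclose(back.matrix, tr.matrix, atol=1e-6)


def _sample(precursors):
    return SampleSpec(sample_id="s1", group="g", precursors=tuple(precursors))


class TestSrnaReads:
    PREC = PrecursorSpec(
        precursor_id="p1",
        sequence="GATTACAGATTACA" + "GCGGCTATCGATCGGCTAGCA" + "TTTTTGGGGGCCCCCAAAAA",
        mature_span=(14, 35),
    )

    def test_zero_tailing_reads_are_templated(self):
        cfg = ReadSimConfig(depth=300, tailing_prob=0.0)
        reads, truth = simulate_srna_reads([_sample([self.PREC])], cfg, seed=1)
        assert len(reads["s1"]) == 300
        assert truth["templated"].all()
        for variant in truth["variant"]:
            assert variant in self.PREC.sequence

    def test_impaired_with_zero_leak_yields_nothing(self):
        imp = PrecursorSpec("p2", self.PREC.sequence, (14, 35), impaired=True)
        cfg = ReadSimConfig(depth=200, impaired_leak=0.0)
        reads, truth = simulate_srna_reads([_sample([imp])], cfg, seed=1)
        assert reads["s1"] == []
        assert truth.empty

    def test_canonical_yield_within_binomial_interval(self):
        cfg = ReadSimConfig(depth=1000, tailing_prob=0.0, canonical_prob=0.7)
        _, truth = simulate_srna_reads([_sample([self.PREC])], cfg, seed=2)
        canonical = self.PREC.sequence[14:35]
        n = int(truth.loc[truth["variant"] == canonical, "count"].sum())
        assert n >= 1
        # canonical arises from the 70% draw plus degenerate offset draws;
        # lower-bound with the configured canonical probability alone
        lo, _ = stats.binom.interval(0.99, 1000, 0.7)
        assert n >= lo

    def test_tails_are_non_templated(self):
        cfg = ReadSimConfig(depth=500, tailing_prob=1.0)
        _, truth = simulate_srna_reads([_sample([self.PREC])], cfg, seed=3)
        tailed = truth[~truth["templated"]]
        assert len(tailed) > 0
        for v in tailed["variant"]:
            assert v not in self.PREC.sequence

    def test_bad_adapter_rejected(self):
        with pytest.raises(ValueError, match="adapter"):
            ReadSimConfig(adapter="ACGU")

    def test_fastq_written_with_seed(self, tmp_path):
        cfg = ReadSimConfig(depth=5)
        simulate_srna_reads([_sample([self.PREC])], cfg, seed=7, fastq_dir=tmp_path)
        content = (tmp_path / "s1.fastq").read_text()
        assert "seed=7" in content
        assert content.count("@") >= 5


class TestQpcr:
    def test_plug_in_arithmetic(self):
        """slope -3.3219, intercept 35, quantity 1 -> Cq exactly 35."""
        cq, _ = simulate_qpcr(
            {"s": {"a": 1.0}},
            [CurveSpec("a", slope=-3.3219, intercept=35.0)],
            dilutions=(1,),
            n_wells=1,
        )
        assert cq["cq"].iloc[0] == pytest.approx(35.0)

    def test_tenfold_quantity_shifts_cq_by_slope(self):
        cq, _ = simulate_qpcr(
            {"s": {"a": 1.0}, "t": {"a": 10.0}},
            [CurveSpec("a", slope=-3.3219, intercept=35.0)],
            dilutions=(1,),
            n_wells=1,
        )
        by = dict(zip(cq["sample"], cq["cq"]))
        assert by["s"] - by["t"] == pytest.approx(3.3219)

    def test_non_positive_quantity_raises(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"s": {"a": 0.0}}, [CurveSpec("a")])

    def test_reproducible_with_noise(self):
        args = ({"s": {"a": 2.0}}, [CurveSpec("a", noise_sd=0.2)])
        a1, s1 = simulate_qpcr(*args, seed=4)
        a2, s2 = simulate_qpcr(*args, seed=4)
        assert a1.equals(a2) and s1.equals(s2)

    def test_dilution_series_spans_four_logs(self):
        _, series = simulate_qpcr({"s": {"a": 1.0}}, [CurveSpec("a")])
        assert series["log10_quantity"].nunique() >= 4
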