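"""MFEI arithmetic, duplex features and the impaired-processing rule."""

import numpy as np
import pytest

from miredit.fold import FoldResult, fold
from miredit.pipeline import _truth_precursor
from miredit.simulate import EditProfile, make_locus, simulate_edits
from miredit.structure import (
    DegenerateDuplexError,
    DuplexFeatures,
    MfeiRecord,
    ProcessingCall,
    analyze_precursor,
    classify_processing,
    locate_duplex,
    mfei,
)
from miredit.types import revcomp


def _fr(seq, mfe, db=None):
    return FoldResult(seq, db or "." * len(seq), mfe)


class TestMfei:
    def test_hand_arithmetic(self):
        # |MFE| 40, L 100, GC 40% -> AMFE 40, MFEI 1.0
        seq = "G" * 20 + "C" * 20 + "A" * 30 + "U" * 30
        rec = mfei(_fr(seq, -40.0))
        assert rec.amfe == pytest.approx(40.0)
        assert rec.mfei == pytest.approx(1.0)

    def test_zero_mfe_gives_zero_mfei(self):
        assert mfei(_fr("GCAU" * 10, 0.0)).mfei == 0.0

    def test_threshold_case(self):
        # |MFE| 45.9, L 108, GC 50% -> MFEI exactly 0.85
        seq = ("GC" + "AU") * 27  # 108 nt, 50% GC
        rec = mfei(_fr(seq, -45.9))
        assert rec.gc_percent == pytest.approx(50.0)
        assert rec.mfei == pytest.approx(0.85)

    def test_gc_zero_is_an_error(self):
        with pytest.raises(ValueError, match="GC"):
            mfei(_fr("AUAUAUAUAUAU", -1.0))


def _rna_revcomp(seq: str) -> str:
    return revcomp(seq.replace("U", "T")).replace("T", "U")


class TestDuplex:
    def _hairpin(self, mir, loop_len=8):
        """mir + loop + perfect-complement star."""
        return mir + "A" * loop_len + _rna_revcomp(mir)

    def test_perfect_duplex_has_no_mismatches_or_loops(self):
        mir = "GCGGCUAUCGAUCGGCUAGCA"  # 21 nt
        seq = self._hairpin(mir)
        fr = fold(seq)
        feats = locate_duplex(fr, (0, 21))
        assert feats.n_mismatch_positions == 0
        assert feats.largest_internal_loop_nt == 0

    def test_constructed_internal_loop_is_measured(self):
        """A 3x3 star/mir bubble scores as a 6-nt two-strand loop."""
        mir = "GCGGCGAUCGAUCGGCGAGCG"
        star = list(_rna_revcomp(mir))
        # break pairing of mir positions 9-11 (star partners 21-1-11..21-1-9)
        for p in (9, 10, 11):
            sp = 20 - p
            comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[mir[p]]
            star[sp] = {"A": "C", "C": "A", "G": "A", "U": "C"}[comp]
        seq = mir + "AAAAAAAA" + "".join(star)
        fr = fold(seq)
        feats = locate_duplex(fr, (0, 21))
        # verify against an independent scan of the structure string
        partner = fr.pair_partners()
        paired = [i for i in range(0, 21) if partner[i] >= 0]
        gaps = [
            (paired[k + 1] - paired[k] - 1)
            + (partner[paired[k]] - partner[paired[k + 1]] - 1)
            for k in range(len(paired) - 1)
        ]
        assert feats.largest_internal_loop_nt == max(gaps)
        assert feats.largest_internal_loop_nt == 6

    def test_degenerate_duplex_raises(self):
        seq = "GCGCGCGCGCAAAAAAAAAAAAAAAAAAAAA"
        fr = FoldResult(seq, "." * len(seq), 0.0)
        with pytest.raises(DegenerateDuplexError):
            locate_duplex(fr, (0, 10))

    def test_annotated_star_span_takes_precedence(self):
        mir = "GCGGCUAUCGAUCGGCUAGCA"
        seq = self._hairpin(mir)
        fr = fold(seq)
        feats = locate_duplex(fr, (0, 21), mirstar_span=(29, 50))
        assert feats.mirstar_span == (29, 50)


class TestClassifier:
    @pytest.mark.parametrize(
        "mfei_val,loop,expect_impaired,expect_reasons",
        [
            (0.84, 5, True, {"low_mfei"}),
            (0.84, 6, True, {"low_mfei", "internal_loop"}),
            (0.85, 5, False, set()),
            (0.85, 6, True, {"internal_loop"}),
            (0.86, 5, False, set()),
            (0.86, 6, True, {"internal_loop"}),
        ],
    )
    def test_boundary_truth_table(self, mfei_val, loop, expect_impaired, expect_reasons):
        """'below 0.85' and '> 5 nt' are strict inequalities."""
        rec = MfeiRecord(length_nt=100, gc_percent=50.0, amfe=mfei_val * 50, mfei=mfei_val)
        feats = DuplexFeatures(
            mir5p_span=(0, 21),
            mirstar_span=(30, 53),
            n_mismatch_positions=0,
            largest_internal_loop_nt=loop,
            largest_loop_one_strand_nt=loop,
            has_2nt_3p_overhang_room=True,
        )
        call = classify_processing(rec, feats)
        assert call.impaired is expect_impaired
        assert set(call.reasons) == expect_reasons

    def test_low_mfei_only(self):
        rec = MfeiRecord(100, 50.0, 30.0, 0.60)
        feats = DuplexFeatures((0, 21), (30, 53), 0, 0, 0, True)
        call = classify_processing(rec, feats)
        assert call.impaired and set(call.reasons) == {"low_mfei"}

    def test_excised_precursor_is_impaired(self):
        call = classify_processing(None, None, precursor_excised=True)
        assert call.impaired and "precursor_excised" in call.reasons

    def test_degenerate_duplex_is_impaired(self):
        rec = MfeiRecord(100, 50.0, 50.0, 1.0)
        call = classify_processing(rec, DegenerateDuplexError("x"))
        assert call.impaired

    def test_monotone_in_mfei_and_loop(self):
        """Lowering MFEI or enlarging the loop never rescues a precursor."""
        feats0 = DuplexFeatures((0, 21), (30, 53), 0, 0, 0, True)
        grid = np.linspace(0.5, 1.2, 15)
        loops = range(0, 10)
        for loop in loops:
            impaired_seq = []
            for m in grid[::-1]:  # decreasing MFEI
                rec = MfeiRecord(100, 50.0, m * 50, m)
                feats = DuplexFeatures((0, 21), (30, 53), 0, loop, loop, True)
                impaired_seq.append(classify_processing(rec, feats).impaired)
            # once impaired while MFEI decreases, always impaired
            assert impaired_seq == sorted(impaired_seq)
        for m in grid:
            rec = MfeiRecord(100, 50.0, m * 50, m)
            impaired_seq = [
                classify_processing(
                    rec, DuplexFeatures((0, 21), (30, 53), 0, l, l, True)
                ).impaired
                for l in loops
            ]
            assert impaired_seq == sorted(impaired_seq)

    def test_invariant_impaired_iff_reasons(self):
        with pytest.raises(ValueError):
            ProcessingCall(impaired=True, reasons=frozenset())


class TestDeletionSeverity:
    def test_larger_deletions_destabilize_more(self):
        """Mean MFEI: precursors with >=4-nt deletions <= those with <=1-nt edits."""
        big, small = [], []
        for seed in range(1, 7):
            locus = make_locus(seed=seed, n_alleles=4, snp_rate=0.01)
            profile = EditProfile(
                probabilities={"short_deletion": 0.7, "insertion_T": 0.3},
                seed=seed + 50,
            )
            for edit in simulate_edits(locus, profile, 40):
                prec, mspan = _truth_precursor(edit, locus)
                fr, rec, _feats, _call = analyze_precursor(prec, mspan)
                if rec is None:
                    continue
                length = edit.call.span[1] - edit.call.span[0]
                if edit.call.type == "short_deletion" and length >= 4:
                    big.append(rec.mfei)
                elif length <= 1:
                    small.append(rec.mfei)
        assert len(big) > 20 and len(small) > 20
        assert np.mean(big) <= np.mean(small)
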