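"""Pre-miRNA structural triage: MFEI, duplex features, processing call.

A precursor is predicted to be processed inefficiently ("impaired") when its
minimal folding free energy index falls below 0.85 — the empirical threshold
separating genuine plant pre-miRNAs from tRNA/rRNA/mRNA backgrounds — or when
the miRNA/miRNA* duplex carries an internal loop of more than 5 unpaired
nucleotides, or when the precursor has been excised/degenerate altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import FoldResult


class DegenerateDuplexError(ValueError):
    """miR-5p region has no paired bases (e.g. excised precursor)."""


@dataclass(frozen=True)
class MfeiRecord:
    length_nt: int
    gc_percent: float  # 0-100 scale
    amfe: float  # |MFE| / L * 100
    mfei: float  # AMFE / GC%


@dataclass(frozen=True)
class DuplexFeatures:
    """Features of the miRNA/miRNA* duplex region of a folded precursor."""

    mir5p_span: tuple[int, int]
    mirstar_span: tuple[int, int]
    n_mismatch_positions: int
    largest_internal_loop_nt: int  # unpaired nt summed over both strands
    largest_loop_one_strand_nt: int  # same loops, max single-strand run
    has_2nt_3p_overhang_room: bool


@dataclass(frozen=True)
class ProcessingCall:
    impaired: bool
    reasons: frozenset[str] = field(default_factory=frozenset)
    mfei: float | None = None
    largest_internal_loop_nt: int | None = None

    def __post_init__(self) -> None:
        if self.impaired != bool(self.reasons):
            raise ValueError("impaired flag must match non-empty reasons")


MFEI_THRESHOLD = 0.85
MAX_DUPLEX_LOOP_NT = 5  # loops strictly larger are impairing


def mfei(fold_result: FoldResult) -> MfeiRecord:
    """Minimal folding free energy index of a folded precursor.

    AMFE = |MFE| / L * 100; MFEI = AMFE / GC% with GC on the 0-100 scale,
    so the conventional 0.85 cutoff applies directly.
    """
    seq = fold_result.sequence
    L = len(seq)
    gc = 100.0 * sum(1 for b in seq if b in "GC") / L
    if gc == 0:
        raise ValueError("MFEI undefined for GC content of zero")
    amfe = abs(fold_result.mfe_kcal_mol) / L * 100.0
    return MfeiRecord(length_nt=L, gc_percent=gc, amfe=amfe, mfei=amfe / gc)


def locate_duplex(
    fold_result: FoldResult,
    mir5p_span: tuple[int, int],
    mirstar_span: tuple[int, int] | None = None,
) -> DuplexFeatures:
    """miRNA/miRNA* duplex features from the predicted structure.

    The star span is inferred from the pairing partners of the miR-5p bases,
    extended by the canonical 2-nt 3' overhang; an annotated ``mirstar_span``
    (e.g. a known miR-3p) takes precedence.  Loop sizes count unpaired
    nucleotides between consecutive duplex pairs; the headline metric sums
    both strands, the per-strand maximum is reported alongside.
    """
    lo, hi = mir5p_span
    n = len(fold_result.sequence)
    if not (0 <= lo < hi <= n):
        raise ValueError("mir5p_span outside sequence")
    partner = fold_result.pair_partners()
    paired_positions = [i for i in range(lo, hi) if partner[i] >= 0]
    if not paired_positions:
        raise DegenerateDuplexError("no paired bases in miR-5p span")

    if mirstar_span is None:
        partners = [int(partner[i]) for i in paired_positions]
        star_lo, star_hi = min(partners), max(partners) + 1
        # canonical 2-nt 3' overhang of the star strand
        star_hi = min(n, star_hi + 2)
        mirstar_span = (star_lo, star_hi)
    s_lo, s_hi = mirstar_span

    n_mismatch = sum(
        1
        for i in range(lo, hi)
        if partner[i] < 0 or not (s_lo <= partner[i] < s_hi)
    )

    # duplex pairs: miR-5p positions paired into the star span, 5'->3'
    duplex_pairs = [
        (i, int(partner[i]))
        for i in range(lo, hi)
        if partner[i] >= 0 and s_lo <= partner[i] < s_hi
    ]
    largest_both = 0
    largest_one = 0
    for (i1, j1), (i2, j2) in zip(duplex_pairs, duplex_pairs[1:]):
        u_mir = i2 - i1 - 1
        u_star = j1 - j2 - 1
        if u_mir < 0 or u_star < 0:  # crossing partners: skip (not a loop)
            continue
        if u_mir + u_star > 0:
            largest_both = max(largest_both, u_mir + u_star)
            largest_one = max(largest_one, u_mir, u_star)

    overhang_room = s_hi - (max(p for _, p in duplex_pairs) + 1) >= 2

    return DuplexFeatures(
        mir5p_span=mir5p_span,
        mirstar_span=(s_lo, s_hi),
        n_mismatch_positions=n_mismatch,
        largest_internal_loop_nt=largest_both,
        largest_loop_one_strand_nt=largest_one,
        has_2nt_3p_overhang_room=overhang_room,
    )


def classify_processing(
    mfei_rec: MfeiRecord | None,
    duplex: DuplexFeatures | DegenerateDuplexError | None,
    precursor_excised: bool = False,
) -> ProcessingCall:
    """Impaired-processing call.

    Impaired iff MFEI < 0.85, or the duplex carries an internal loop > 5 nt,
    or the precursor was excised / folds with a degenerate duplex.  Reasons
    enumerate every trigger; strict inequalities, so MFEI exactly 0.85 and a
    5-nt loop both pass.
    """
    reasons: set[str] = set()
    loop = None
    if precursor_excised or mfei_rec is None:
        reasons.add("precursor_excised")
    else:
        if mfei_rec.mfei < MFEI_THRESHOLD:
            reasons.add("low_mfei")
        if isinstance(duplex, DegenerateDuplexError) or duplex is None:
            reasons.add("precursor_excised")
        else:
            loop = duplex.largest_internal_loop_nt
            if loop > MAX_DUPLEX_LOOP_NT:
                reasons.add("internal_loop")
    return ProcessingCall(
        impaired=bool(reasons),
        reasons=frozenset(reasons),
        mfei=None if mfei_rec is None else mfei_rec.mfei,
        largest_internal_loop_nt=loop,
    )


def analyze_precursor(
    seq: str,
    mir5p_span: tuple[int, int],
    mirstar_span: tuple[int, int] | None = None,
    fold_fn=None,
) -> tuple[FoldResult | None, MfeiRecord | None, DuplexFeatures | None, ProcessingCall]:
    """Fold + MFEI + duplex + processing call for one precursor sequence.

    A sequence too short to fold (e.g. after inter-guide excision) or with an
    empty miR-5p span is classified impaired with reason ``precursor_excised``.
    """
    from .fold import SequenceTooShortError, fold as _fold

    fold_fn = fold_fn or _fold
    lo, hi = mir5p_span
    if hi <= lo or hi > len(seq):
        return None, None, None, classify_processing(None, None, True)
    try:
        fr = fold_fn(seq)
    except SequenceTooShortError:
        return None, None, None, classify_processing(None, None, True)
    rec = mfei(fr)
    try:
        feats = locate_duplex(fr, mir5p_span, mirstar_span)
    except DegenerateDuplexError as err:
        return fr, rec, None, classify_processing(rec, err)
    return fr, rec, feats, classify_processing(rec, feats)
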