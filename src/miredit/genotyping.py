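"""Allele-aware CRISPR edit genotyping on amplicon clones.

Each sequenced clone is globally aligned (affine gaps) against every allele
of its tetraploid locus; differences against the best allele are reduced to
left-normalized substitution/insertion/deletion operations, natural SNPs seen
in non-transgenic control clones are masked, and the remaining operations are
classified into the edit spectrum (short deletion, 1-nt insertion,
inter-guide excision, large deletion).  A knock-out score deconvolves a mixed
Sanger trace into candidate-outcome proportions by non-negative least
squares.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from scipy.optimize import nnls

from .simulate.traces import TraceMatrix, profile_matrix
from .types import GuideSite, MutationCall, PremiRNALocus

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -6, -1


@dataclass(frozen=True)
class DiffOp:
    """One difference against the best allele, amplicon coordinates.

    ``pos`` is the 0-based reference position (for insertions, the position
    the inserted bases precede); deletions span ``[pos, pos + length)``.
    """

    kind: str  # 'sub' | 'del' | 'ins'
    pos: int
    length: int
    ref: str = ""
    alt: str = ""

    @property
    def span(self) -> tuple[int, int]:
        if self.kind == "del":
            return (self.pos, self.pos + self.length)
        return (self.pos, self.pos + (1 if self.kind == "sub" else 0))


@dataclass
class AlleleAlignment:
    clone_id: str
    best_allele_index: int
    aligned_ref: str
    aligned_clone: str
    ops: list[DiffOp]
    score: float


@dataclass(frozen=True)
class LineGenotype:
    line_id: str
    n_clones: int
    n_mutated: int
    mutated_fraction: float
    spectrum: dict[str, int]
    all_alleles_mutated: bool


@dataclass(frozen=True)
class KnockoutScore:
    editing_rate: float
    proportions: dict[str, float]  # per candidate-profile group
    signature_spectrum: dict[str, float]  # aggregated by indel signature
    residual: float


class WindowRankError(ValueError):
    """Candidate profiles are rank-deficient over the trace window."""


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def _extract_ops(ref: str, clone: str, alignment) -> list[DiffOp]:
    ops: list[DiffOp] = []
    ref_blocks, clone_blocks = alignment.aligned
    prev_r, prev_c = 0, 0
    for (r0, r1), (c0, c1) in zip(ref_blocks, clone_blocks):
        if r0 > prev_r:
            ops.append(DiffOp("del", prev_r, r0 - prev_r, ref=ref[prev_r:r0]))
        if c0 > prev_c:
            ops.append(DiffOp("ins", r0, c0 - prev_c, alt=clone[prev_c:c0]))
        for k in range(r1 - r0):
            if ref[r0 + k] != clone[c0 + k]:
                ops.append(
                    DiffOp("sub", r0 + k, 1, ref=ref[r0 + k], alt=clone[c0 + k])
                )
        prev_r, prev_c = r1, c1
    if prev_r < len(ref):
        ops.append(DiffOp("del", prev_r, len(ref) - prev_r, ref=ref[prev_r:]))
    if prev_c < len(clone):
        ops.append(DiffOp("ins", len(ref), len(clone) - prev_c, alt=clone[prev_c:]))
    return _normalize_ops(ref, ops)


def _normalize_ops(ref: str, ops: list[DiffOp]) -> list[DiffOp]:
    """Left-align indels (VCF convention) so equivalent placements agree."""
    out = []
    for op in ops:
        if op.kind == "del":
            pos, k = op.pos, op.length
            while pos > 0 and ref[pos - 1] == ref[pos + k - 1]:
                pos -= 1
            out.append(DiffOp("del", pos, k, ref=ref[pos : pos + k]))
        elif op.kind == "ins":
            pos, alt = op.pos, op.alt
            while pos > 0 and alt[-1] == ref[pos - 1]:
                alt = ref[pos - 1] + alt[:-1]
                pos -= 1
            out.append(DiffOp("ins", pos, len(alt), alt=alt))
        else:
            out.append(op)
    return sorted(out, key=lambda o: (o.pos, o.kind))


def apply_ops(ref: str, ops: list[DiffOp]) -> str:
    """Rebuild the clone from the reference and difference operations."""
    pieces = []
    cursor = 0
    for op in sorted(ops, key=lambda o: o.pos):
        pieces.append(ref[cursor : op.pos])
        if op.kind == "del":
            cursor = op.pos + op.length
        elif op.kind == "ins":
            pieces.append(op.alt)
            cursor = op.pos
        else:
            pieces.append(op.alt)
            cursor = op.pos + 1
    pieces.append(ref[cursor:])
    return "".join(pieces)


def align_clone(
    clone: str,
    locus: PremiRNALocus,
    clone_id: str = "clone",
    allele_index: int | None = None,
) -> AlleleAlignment:
    """Global affine-gap alignment of a clone against all alleles.

    The best allele maximizes the alignment score (ties break to the lowest
    allele index); an edit-distance prescreen narrows the candidates before
    the full affine alignment.  The reconstruction invariant (ops applied to
    the best allele reproduce the clone) is asserted on every call.  Passing
    ``allele_index`` forces alignment against one allele — used to express NT
    control clones against the reference allele when building an SNP panel.
    """
    clone = clone.upper()
    if not clone or set(clone) - set("ACGTN"):
        raise ValueError("clone must be non-empty over ACGTN")
    if allele_index is not None:
        candidates = [allele_index]
    else:
        dists = [
            edlib.align(clone, allele, mode="NW")["editDistance"]
            for allele in locus.allele_seqs
        ]
        best_d = min(dists)
        candidates = [i for i, d in enumerate(dists) if d == best_d]
    aligner = _aligner()
    best = None
    for i in candidates:
        aln = aligner.align(locus.allele_seqs[i], clone)[0]
        if best is None or aln.score > best[1].score:
            best = (i, aln)
    idx, aln = best
    ref = locus.allele_seqs[idx]
    ops = _extract_ops(ref, clone, aln)
    assert apply_ops(ref, ops) == clone, "op reconstruction failed"
    lines = str(aln).splitlines()
    return AlleleAlignment(
        clone_id=clone_id,
        best_allele_index=idx,
        aligned_ref=lines[0] if lines else ref,
        aligned_clone=lines[2] if len(lines) > 2 else clone,
        ops=ops,
        score=float(aln.score),
    )


def build_nt_panel(alignments: list[AlleleAlignment]) -> set[tuple[int, str]]:
    """Natural-SNP panel {(amplicon position, alt base)} from NT clones."""
    panel = set()
    for aln in alignments:
        for op in aln.ops:
            if op.kind == "sub":
                panel.add((op.pos, op.alt))
    return panel


def mask_polymorphism(
    aln: AlleleAlignment,
    nt_panel: set[tuple[int, str]] | list[AlleleAlignment],
) -> list[DiffOp]:
    """Drop substitutions explained by natural polymorphism.

    A substitution is masked when the same alternate base was seen at the
    same amplicon coordinate in any non-transgenic control clone or allele.
    Indels are never masked: NT material carries none by construction.
    """
    if isinstance(nt_panel, list):
        nt_panel = build_nt_panel(nt_panel)
    if not nt_panel:
        warnings.warn("empty NT panel: no polymorphism masking applied")
        return list(aln.ops)
    return [
        op
        for op in aln.ops
        if not (op.kind == "sub" and (op.pos, op.alt) in nt_panel)
    ]


def classify_mutation(
    ops: list[DiffOp], guides: tuple[GuideSite, GuideSite], locus: PremiRNALocus
) -> list[MutationCall]:
    """Map filtered difference operations to mutation calls.

    Deletions of 1-6 nt are short deletions; longer deletions containing both
    cut positions are inter-guide excisions, otherwise large deletions.
    Insertions are called with their inserted base.  Substitutions surviving
    the polymorphism mask are not CRISPR edit classes and are ignored here.
    An empty (or substitution-only) op list yields a single ``none`` call.
    """
    c1, c2 = sorted(g.cut_pos for g in guides)
    m_lo, m_hi = locus.mir5p_amplicon_span()
    calls: list[MutationCall] = []
    for op in ops:
        if op.kind == "sub":
            continue
        lo, hi = op.span
        if op.kind == "ins":
            lo, hi = op.pos, op.pos + 1
        dist = min(
            0 if lo <= c <= op.span[1] else min(abs(c - lo), abs(c - op.span[1]))
            for c in (c1, c2)
        )
        overlaps = lo < m_hi and m_lo < hi
        if op.kind == "ins":
            calls.append(
                MutationCall(
                    type="insertion",
                    span=(op.pos, op.pos + 1),
                    inserted_base=op.alt,
                    distance_to_cut=dist,
                    overlaps_mir5p=overlaps,
                )
            )
        else:
            length = op.length
            if length <= 6:
                kind = "short_deletion"
            elif op.pos <= c1 and c2 <= op.pos + length:
                kind = "inter_guide_excision"
            else:
                kind = "large_deletion"
            calls.append(
                MutationCall(
                    type=kind,
                    span=op.span,
                    distance_to_cut=dist,
                    overlaps_mir5p=overlaps,
                )
            )
    if not calls:
        calls.append(MutationCall(type="none"))
    return calls


def summarize_line(
    line_id: str, calls_per_clone: list[list[MutationCall]]
) -> LineGenotype:
    """Per-line genotype summary: mutated fraction and mutation spectrum."""
    if not calls_per_clone:
        raise ValueError("at least one clone required")
    n = len(calls_per_clone)
    mutated = sum(1 for calls in calls_per_clone if any(c.is_edit for c in calls))
    spectrum: Counter[str] = Counter()
    for calls in calls_per_clone:
        for c in calls:
            if c.is_edit:
                spectrum[c.type] += 1
    return LineGenotype(
        line_id=line_id,
        n_clones=n,
        n_mutated=mutated,
        mutated_fraction=mutated / n,
        spectrum=dict(spectrum),
        all_alleles_mutated=mutated == n,
    )


# ---------------------------------------------------------------------------
# ICE-like knock-out score
# ---------------------------------------------------------------------------


def enumerate_candidates(
    locus: PremiRNALocus,
    del_lengths: range = range(1, 16),
    offsets: range = range(-4, 5),
) -> list[tuple[str, str, str]]:
    """Candidate outcome set: (label, signature, sequence).

    All unedited alleles, deletions of 1-15 nt at offsets -4..+4 around each
    cut, single-base insertions at each cut, and the inter-guide excision —
    a superset of every edit class the genotyping stage reports.
    """
    c1, c2 = locus.cut_positions
    ref = locus.allele_seqs[0]
    out: list[tuple[str, str, str]] = []
    for i, allele in enumerate(locus.allele_seqs):
        out.append((f"allele{i + 1}", "wt", allele))
    for cut_name, cut in (("c1", c1), ("c2", c2)):
        for k in del_lengths:
            for off in offsets:
                start = cut + off - k // 2
                if start < 1 or start + k >= len(ref):
                    continue
                out.append(
                    (
                        f"del{k}@{cut_name}{off:+d}",
                        f"del{k}",
                        ref[:start] + ref[start + k :],
                    )
                )
        for base in "ACGT":
            out.append(
                (f"ins{base}@{cut_name}", "ins1", ref[:cut] + base + ref[cut:])
            )
    out.append(("excision", f"del{c2 - c1}", ref[:c1] + ref[c2:]))
    return out


def ko_score(
    trace: TraceMatrix,
    locus: PremiRNALocus,
    candidate_edits: list[tuple[str, str, str]] | None = None,
    check_rank: bool = False,
) -> KnockoutScore:
    """Deconvolve a mixed trace into candidate-outcome proportions.

    Solves non-negative least squares for the mixture of candidate one-hot
    trace profiles best approximating the observed matrix, then normalizes.
    Candidates whose profiles are identical over the window are merged (they
    are not separately identifiable); proportions are also aggregated by
    indel signature — individual placements of same-size deletions differ in
    only a handful of trace columns, so the size spectrum is the robust
    readout.  ``editing_rate`` is one minus the proportion assigned to groups
    containing an unedited allele.

    The exhaustive default candidate set is deliberately over-complete and
    therefore collinear; the active-set NNLS solve is well-defined regardless
    and returns a sparse mixture.  Pass ``check_rank=True`` to instead demand
    full column rank over the window (raises :class:`WindowRankError`), e.g.
    when supplying a small curated candidate list.
    """
    cands = candidate_edits if candidate_edits is not None else enumerate_candidates(locus)
    labels = [c[0] for c in cands]
    sigs = {c[0]: c[1] for c in cands}
    seqs = [c[2] for c in cands]

    profiles = profile_matrix(seqs, trace.window)  # (n_cand, 4, W)
    flat = profiles.reshape(len(seqs), -1)

    # merge candidates indistinguishable over the window
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(flat):
        groups.setdefault(row.tobytes(), []).append(i)
    group_members = list(groups.values())
    A = np.stack([flat[m[0]] for m in group_members], axis=1)  # (4W, G)

    if check_rank and np.linalg.matrix_rank(A) < A.shape[1]:
        raise WindowRankError(
            "candidate profiles are rank-deficient over the trace window; "
            "widen the window or prune candidates"
        )
    b = trace.matrix.reshape(-1)
    x, resid = nnls(A, b)
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate deconvolution: all proportions zero")
    x = x / total

    proportions: dict[str, float] = {}
    signature_spectrum: dict[str, float] = {}
    unedited = 0.0
    for members, prop in zip(group_members, x):
        label = "|".join(labels[i] for i in members)
        proportions[label] = float(prop)
        member_sigs = {sigs[labels[i]] for i in members}
        if "wt" in member_sigs:
            unedited += float(prop)
        # credit the signature of the first member (groups mixing wt with an
        # edit cannot occur: identical profiles imply identical sequences
        # over the window)
        sig = sorted(member_sigs)[0]
        signature_spectrum[sig] = signature_spectrum.get(sig, 0.0) + float(prop)

    return KnockoutScore(
        editing_rate=float(1.0 - unedited),
        proportions=proportions,
        signature_spectrum=signature_spectrum,
        residual=float(resid),
    )
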