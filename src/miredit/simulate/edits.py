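"""Simulated CRISPR edit outcomes and mosaic amplicon clone sampling.

Edit classes mirror the spectrum seen in dual-sgRNA editing of miRNA loci:
short deletions (1-6 nt) at either cut site, 1-nt T/G insertions, excision of
the interval between the two cuts, and larger deletions.  Edit positions
jitter uniformly within +/-4 nt of the cut, reflecting that repair outcomes
cluster at, but are not confined to, the expected cut site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import MutationCall, PremiRNALocus

EDIT_CLASSES = (
    "none",
    "short_deletion",
    "insertion_T",
    "insertion_G",
    "inter_guide_excision",
    "large_deletion",
)

JITTER_NT = 4


@dataclass(frozen=True)
class EditProfile:
    """Per-class edit probabilities and positional jitter for one construct."""

    probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.25,
            "short_deletion": 0.40,
            "insertion_T": 0.10,
            "insertion_G": 0.05,
            "inter_guide_excision": 0.05,
            "large_deletion": 0.15,
        }
    )
    jitter_nt: int = JITTER_NT
    large_deletion_max: int = 60
    mosaicism: int = 3  # distinct edit outcomes per regenerated line
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.probabilities) - set(EDIT_CLASSES)
        if unknown:
            raise ValueError(f"unknown edit classes: {sorted(unknown)}")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")
        if self.jitter_nt > JITTER_NT:
            raise ValueError(f"jitter support bounded at +/-{JITTER_NT} nt")


@dataclass(frozen=True)
class SimulatedEdit:
    """Ground truth for one simulated edit event."""

    allele_index: int  # 0-based into locus.allele_seqs
    call: MutationCall
    edited_seq: str
    drawn_class: str  # profile class the event was drawn from


def _left_normalize(src: str, start: int, length: int) -> tuple[int, int]:
    """Shift a deletion span to its leftmost equivalent placement."""
    while start > 0 and src[start - 1] == src[start + length - 1]:
        start -= 1
    return (start, start + length)


def _mutation_call(
    locus: PremiRNALocus, kind: str, span: tuple[int, int], base: str | None
) -> MutationCall:
    c1, c2 = locus.cut_positions
    lo, hi = span
    dist = min(
        0 if lo <= c <= hi else min(abs(c - lo), abs(c - hi)) for c in (c1, c2)
    )
    m_lo, m_hi = locus.mir5p_amplicon_span()
    overlaps = lo < m_hi and m_lo < hi if hi > lo else m_lo <= lo < m_hi
    return MutationCall(
        type=kind,
        span=span,
        inserted_base=base,
        distance_to_cut=dist,
        overlaps_mir5p=overlaps,
    )


def simulate_edits(
    locus: PremiRNALocus, profile: EditProfile, n_events: int
) -> list[SimulatedEdit]:
    """Draw ``n_events`` independent edit outcomes on random alleles.

    Each returned record carries the edited sequence and a MutationCall that
    is exact ground truth: applying the call to the source allele reproduces
    the edited sequence.  A drawn large deletion that happens to span both cut
    sites is labelled ``inter_guide_excision`` (it is one, by definition).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if len(locus.guides) != 2:
        raise ValueError("locus must carry a dual-guide pair")
    rng = np.random.default_rng(profile.seed)
    classes = list(profile.probabilities)
    probs = np.array([profile.probabilities[c] for c in classes])
    c1, c2 = locus.cut_positions

    out: list[SimulatedEdit] = []
    for _ in range(n_events):
        allele_idx = int(rng.integers(0, len(locus.allele_seqs)))
        src = locus.allele_seqs[allele_idx]
        kind = classes[int(rng.choice(len(classes), p=probs))]

        if kind == "none":
            call = MutationCall(type="none")
            edited = src
        elif kind in ("insertion_T", "insertion_G"):
            cut = int(rng.choice([c1, c2]))
            pos = cut + int(rng.integers(-profile.jitter_nt, profile.jitter_nt + 1))
            pos = max(1, min(len(src) - 1, pos))
            base = kind[-1]
            edited = src[:pos] + base + src[pos:]
            # canonical (left-normalized) placement, as an aligner reports it
            while pos > 0 and src[pos - 1] == base:
                pos -= 1
            call = _mutation_call(locus, "insertion", (pos, pos + 1), base)
        elif kind == "inter_guide_excision":
            edited = src[:c1] + src[c2:]
            span = _left_normalize(src, c1, c2 - c1)
            # an excision whose canonical placement slides off a cut site is
            # indistinguishable from a plain deletion of the same length
            label = (
                "inter_guide_excision"
                if span[0] <= c1 and c2 <= span[1]
                else "large_deletion"
            )
            call = _mutation_call(locus, label, span, None)
        else:
            if kind == "short_deletion":
                length = int(rng.integers(1, 7))
            else:
                length = int(rng.integers(7, profile.large_deletion_max + 1))
            cut = int(rng.choice([c1, c2]))
            jitter = int(rng.integers(-profile.jitter_nt, profile.jitter_nt + 1))
            start = cut + jitter - length // 2
            start = max(1, min(len(src) - length - 1, start))
            edited = src[:start] + src[start + length :]
            span = _left_normalize(src, start, length)
            label = kind
            if kind == "large_deletion" and span[0] <= c1 and c2 <= span[1]:
                label = "inter_guide_excision"
            call = _mutation_call(locus, label, span, None)

        out.append(SimulatedEdit(allele_idx, call, edited, kind))
    return out


def simulate_amplicon_clones(
    line_truth: list[tuple[str, float]], n_clones: int, seed: int
) -> tuple[list[str], list[int]]:
    """Sample sequenced clone inserts from a mosaic line.

    ``line_truth`` lists (sequence, proportion) for the distinct outcomes
    present in the line; clones are drawn with replacement.  Returns the clone
    sequences and the truth index each clone was drawn from.
    """
    if not line_truth:
        raise ValueError("line truth set is empty")
    props = np.array([p for _, p in line_truth], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n_clones == 0:
        return [], []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(line_truth), size=n_clones, p=props)
    return [line_truth[int(i)][0] for i in idx], [int(i) for i in idx]
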