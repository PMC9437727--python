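"""Plant miRNA target screening with an expectation (penalty) score.

Complementarity between a miRNA (5'->3') and a candidate transcript site
(read 3'->5') is scored per position: mismatch 1, G:U wobble 0.5, gap 2;
penalties at miRNA positions 2-13 (the seed-proximal region) are doubled.
The expectation score is the total penalty — 0 for a perfect complement,
lower is better — and hits above a cutoff (default 3, the stringent setting)
are discarded.  Independent of the score, three or more consecutive
mispaired positions overlapping miRNA positions 12-14 (the central region,
where pairing is required for cleavage) flag the hit as non-functional.
"""

from __future__ import annotations

from dataclasses import dataclass

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {("G", "U"), ("U", "G")}

SEED_START, SEED_END = 2, 13  # 1-based inclusive, double weight
CENTRAL = (12, 13, 14)  # 1-based central region
DEFAULT_CUTOFF = 3.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0
MAX_BULGE = 2


@dataclass(frozen=True)
class TargetHit:
    mirna: str
    transcript_id: str
    site_span: tuple[int, int]  # on transcript, 0-based half-open
    expectation: float
    mismatch_positions: tuple[int, ...]  # 1-based miRNA coordinates
    central_block: bool
    functional: bool


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _pair_penalty(mir_base: str, target_base: str) -> float:
    """Penalty for one aligned position (0 = Watson-Crick)."""
    if _RNA_COMPLEMENT.get(mir_base) == target_base:
        return 0.0
    if (mir_base, target_base) in _WOBBLE:
        return WOBBLE_PENALTY
    return MISMATCH_PENALTY


def _weight(pos1: int) -> float:
    return 2.0 if SEED_START <= pos1 <= SEED_END else 1.0


def _score_alignment(mir: str, site_rev: list[str | None]) -> tuple[float, list[int]]:
    """Score miRNA against a site with None marking miRNA-side gap partners."""
    total = 0.0
    mispaired: list[int] = []
    for i, (m, t) in enumerate(zip(mir, site_rev)):
        pos1 = i + 1
        if t is None:
            total += GAP_PENALTY * _weight(pos1)
            mispaired.append(pos1)
        else:
            p = _pair_penalty(m, t)
            total += p * _weight(pos1)
            if p >= MISMATCH_PENALTY:
                mispaired.append(pos1)
    return total, mispaired


def _central_block(mispaired: list[int]) -> bool:
    """>= 3 consecutive mispaired miRNA positions intersecting 12-14."""
    s = set(mispaired)
    for start in s:
        run = 0
        p = start
        while p in s:
            run += 1
            p += 1
        if run >= 3 and any(c in range(start, p) for c in CENTRAL):
            return True
    return False


def score_site(
    mirna: str, window: str, cutoff: float = DEFAULT_CUTOFF,
    transcript_id: str = "site", site_span: tuple[int, int] = (0, 0),
) -> TargetHit:
    """Expectation score of one miRNA : target-site pairing.

    The window is the transcript subsequence (5'->3'); it is reversed so the
    miRNA 5' end faces the target 3' end.  Equal lengths score ungapped; a
    length difference of up to 2 nt is absorbed by the best placement of a
    single bulge (each gapped position costs 2, seed-weighted).
    """
    mir = _to_rna(mirna)
    if not 18 <= len(mir) <= 26:
        raise ValueError("miRNA length must be 18-26 nt")
    site = _to_rna(window)[::-1]  # now aligned 5'->3' of the miRNA
    diff = len(site) - len(mir)
    if abs(diff) > MAX_BULGE:
        raise ValueError("window length must be within 2 nt of miRNA length")

    best: tuple[float, list[int]] | None = None
    if diff == 0:
        best = _score_alignment(mir, list(site))
    elif diff < 0:
        # target shorter: a bulge of |diff| nt on the miRNA side
        k = -diff
        for g in range(len(mir) - k + 1):
            aligned: list[str | None] = (
                list(site[:g]) + [None] * k + list(site[g:])
            )
            cand = _score_alignment(mir, aligned)
            if best is None or cand[0] < best[0]:
                best = cand
    else:
        # target longer: |diff| target nt bulged out (skipped), penalized
        k = diff
        for g in range(len(site) - k + 1):
            aligned = list(site[:g] + site[g + k :])
            score, mis = _score_alignment(mir, aligned)
            score += GAP_PENALTY * k
            if best is None or score < best[0]:
                best = (score, mis)

    expectation, mispaired = best
    central = _central_block(mispaired)
    return TargetHit(
        mirna=mir,
        transcript_id=transcript_id,
        site_span=site_span,
        expectation=expectation,
        mismatch_positions=tuple(mispaired),
        central_block=central,
        functional=expectation <= cutoff and not central,
    )


def screen(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[str, list[TargetHit]]:
    """Sliding-window target scan; best hit per (miRNA, transcript).

    Returns hits with expectation <= cutoff, keyed by miRNA name.  The
    "retained target binding" question is answered by whether any returned
    hit is functional.
    """
    results: dict[str, list[TargetHit]] = {name: [] for name in mirnas}
    for name, mir in mirnas.items():
        L = len(_to_rna(mir))
        for tid, tseq in transcripts.items():
            tseq_rna = _to_rna(tseq)
            best: TargetHit | None = None
            for w in range(L - MAX_BULGE, L + MAX_BULGE + 1):
                for s in range(0, len(tseq_rna) - w + 1):
                    hit = score_site(
                        mir,
                        tseq_rna[s : s + w],
                        cutoff=cutoff,
                        transcript_id=tid,
                        site_span=(s, s + w),
                    )
                    if best is None or hit.expectation < best.expectation:
                        best = hit
            if best is not None and best.expectation <= cutoff:
                results[name].append(best)
    return results


def retains_binding(hits: list[TargetHit]) -> bool:
    return any(h.functional for h in hits)
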