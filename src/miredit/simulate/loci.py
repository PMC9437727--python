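"""Synthetic tetraploid pre-miRNA loci.

A locus is built as an ~800-nt amplicon whose centre carries a stem-loop
precursor: a 5' arm (pad + 21-nt mature miR-5p + extension), a short terminal
loop, and a 3' arm that is the reverse complement of the 5' arm with a few
substitutions outside the miRNA/miRNA* duplex — enough imperfection to look
like a real hairpin while keeping the duplex clean.  Two SpCas9 guide sites
flank the mature miR-5p (sense guide cutting near its 5' end, antisense guide
near its 3' end); the required NGG/CCN PAM bases are written into allele 1
before the 3' arm is derived, so guides always match allele 1 exactly.
Additional alleles differ by Bernoulli(snp_rate) substitutions, recorded as
ground truth.
"""

from __future__ import annotations

import numpy as np

from ..types import GuideSite, PremiRNALocus, revcomp

BASES = np.array(list("ACGT"))

MIR_LEN = 21
PAD5 = 12
ARM_EXT = 20
LOOP_LEN = 8
ARM_MISMATCHES = 8  # imperfections outside the duplex
DUPLEX_MISMATCHES = 2  # isolated 1x1 loops inside the duplex
# RNA pairing on the DNA alphabet (T stands for U), incl. G:U wobble
_PAIRS_WITH = {
    "A": {"T"},
    "C": {"G"},
    "G": {"C", "T"},
    "T": {"A", "G"},
}


class LocusConstructionError(ValueError):
    """Template cannot host the dual-guide geometry."""


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(BASES, n))


def make_locus(
    seed: int,
    n_alleles: int = 4,
    snp_rate: float = 0.01,
    locus_template: str | None = None,
    template_mir5p_span: tuple[int, int] | None = None,
    amplicon_len: int = 800,
    locus_id: str | None = None,
) -> PremiRNALocus:
    """Generate a tetraploid pre-miRNA locus with dual guide sites.

    Parameters
    ----------
    seed
        All randomness derives from this; equal seeds give equal loci.
    n_alleles
        1-4 allele copies; alleles beyond the first carry natural SNPs.
    snp_rate
        Per-position substitution probability for non-reference alleles
        (0-0.05).
    locus_template, template_mir5p_span
        Optionally use an existing amplicon sequence; the mature miR-5p span
        (amplicon coordinates) must then be supplied and the template must
        offer NGG PAM placements flanking it.
    """
    if not 1 <= n_alleles <= 4:
        raise ValueError("n_alleles must be in 1..4")
    if not 0 <= snp_rate <= 0.05:
        raise ValueError("snp_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)

    if locus_template is not None:
        amp, prec_span, mir5p_amp = _from_template(
            locus_template, template_mir5p_span
        )
        amp = list(amp)
    else:
        amp, prec_span, mir5p_amp = _build_de_novo(rng, amplicon_len)

    mir_lo, mir_hi = mir5p_amp
    # sense guide: cut 1 nt inside the miR 5' end
    cut1 = mir_lo + 1
    g1 = GuideSite(
        strand="+",
        protospacer_span=(cut1 - 17, cut1 + 3),
        pam_span=(cut1 + 3, cut1 + 6),
        cut_pos=cut1,
    )
    # antisense guide: cut 2 nt inside the miR 3' end
    cut2 = mir_hi - 2
    g2 = GuideSite(
        strand="-",
        protospacer_span=(cut2 - 3, cut2 + 17),
        pam_span=(cut2 - 6, cut2 - 3),
        cut_pos=cut2,
    )

    if locus_template is None:
        # write PAM bases, then derive the 3' arm from the final 5' arm
        amp[cut1 + 4] = "G"
        amp[cut1 + 5] = "G"
        amp[cut2 - 6] = "C"
        amp[cut2 - 5] = "C"
        _write_3p_arm(rng, amp, prec_span, mir5p_amp)
    else:
        _check_template_pams(amp, g1, g2)

    allele1 = "".join(amp)
    alleles = [allele1]
    snp_truth: list[tuple[int, int, str, str]] = []
    for a_idx in range(1, n_alleles):
        allele = list(allele1)
        hits = np.nonzero(rng.random(len(allele)) < snp_rate)[0]
        for pos in hits:
            ref = allele[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            allele[pos] = alt
            snp_truth.append((a_idx, int(pos), ref, alt))
        alleles.append("".join(allele))

    p_lo, _ = prec_span
    mir5p = (mir_lo - p_lo, mir_hi - p_lo)
    prec_len = prec_span[1] - prec_span[0]
    # annotated miR-3p: pairing partners of miR-5p shifted by the canonical
    # 2-nt 3' overhang
    mir3p = (prec_len - mir5p[1] + 2, prec_len - mir5p[0] + 2)

    return PremiRNALocus(
        locus_id=locus_id or f"locus{seed}",
        allele_seqs=alleles,
        precursor_span=prec_span,
        mir5p_span=mir5p,
        mir3p_span=mir3p,
        guides=(g1, g2),
        snp_truth=snp_truth,
        seed=seed,
    )


def _build_de_novo(rng, amplicon_len):
    arm = PAD5 + MIR_LEN + ARM_EXT
    prec_len = 2 * arm + LOOP_LEN
    if amplicon_len < prec_len + 80:
        raise ValueError("amplicon too short for the precursor layout")
    amp = _rand_seq(rng, amplicon_len)
    p_lo = (amplicon_len - prec_len) // 2
    prec_span = (p_lo, p_lo + prec_len)
    mir_lo = p_lo + PAD5
    return amp, prec_span, (mir_lo, mir_lo + MIR_LEN)


def _write_3p_arm(rng, amp, prec_span, mir5p_amp):
    p_lo, p_hi = prec_span
    arm = PAD5 + MIR_LEN + ARM_EXT
    arm5 = "".join(amp[p_lo : p_lo + arm])
    arm3 = list(revcomp(arm5))
    # imperfections outside the positions pairing with miR-5p
    mir_rel = (mir5p_amp[0] - p_lo, mir5p_amp[1] - p_lo)
    pair_zone = set(range(arm - mir_rel[1], arm - mir_rel[0]))
    free = [i for i in range(arm) if i not in pair_zone]
    for i in rng.choice(free, size=min(ARM_MISMATCHES, len(free)), replace=False):
        cur = arm3[i]
        arm3[i] = str(rng.choice([b for b in "ACGT" if b != cur]))
    # a couple of true mismatches inside the duplex (small 1x1 loops, kept
    # >= 4 nt apart and away from the duplex ends so the wild-type largest
    # loop stays well under the impairment threshold)
    interior = sorted(pair_zone)[3:-3]
    chosen: list[int] = []
    for i in rng.permutation(interior):
        if all(abs(i - j) >= 4 for j in chosen):
            chosen.append(int(i))
        if len(chosen) == DUPLEX_MISMATCHES:
            break
    for i in chosen:
        mir_base = amp[p_lo + (arm - 1 - i)]  # the miR base this position pairs
        bad = [b for b in "ACGT" if b not in _PAIRS_WITH[mir_base]]
        arm3[i] = str(rng.choice(bad))
    amp[p_hi - arm : p_hi] = arm3


def _from_template(template, mir5p_span):
    template = template.upper()
    if set(template) - set("ACGT"):
        raise ValueError("template must be ACGT")
    if mir5p_span is None:
        raise LocusConstructionError(
            "template mode requires template_mir5p_span (amplicon coords)"
        )
    lo, hi = mir5p_span
    if not (60 <= lo and hi + 60 <= len(template)):
        raise LocusConstructionError("miR-5p span too close to template ends")
    # precursor context: symmetric window around the mature span
    p_lo, p_hi = lo - PAD5 - ARM_EXT, hi + PAD5 + ARM_EXT + LOOP_LEN
    return template, (max(0, p_lo), min(len(template), p_hi)), (lo, hi)


def _check_template_pams(amp, g1, g2):
    seq = "".join(amp)
    s, e = g1.pam_span
    if seq[s + 1 : e] != "GG":
        raise LocusConstructionError(
            "template lacks an NGG PAM for the sense guide flanking miR-5p"
        )
    s, e = g2.pam_span
    if seq[s : e - 1] != "CC":
        raise LocusConstructionError(
            "template lacks an NGG PAM for the antisense guide flanking miR-5p"
        )
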