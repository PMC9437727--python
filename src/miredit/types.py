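"""Shared domain types: loci, guide sites, mutation calls."""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSite:
    """One sgRNA site on the amplicon.

    The SpCas9 blunt cut falls between protospacer positions 17 and 18 on the
    protospacer strand (3 bp 5' of the NGG PAM); ``cut_pos`` is the amplicon
    index of the first base 3' of the cut on the plus strand.
    """

    strand: str  # '+' or '-'
    protospacer_span: tuple[int, int]  # 0-based half-open, amplicon coords
    pam_span: tuple[int, int]
    cut_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        s, e = self.protospacer_span
        if e - s != 20:
            raise ValueError("protospacer must be 20 nt")
        expected = s + 17 if self.strand == "+" else s + 3
        if self.cut_pos != expected:
            raise ValueError(
                "cut_pos must fall between protospacer positions 17 and 18"
            )


@dataclass
class PremiRNALocus:
    """A tetraploid miRNA locus in its ~800-nt amplicon context.

    Allele sequences differ from allele 1 by substitutions only (natural
    SNPs); ``precursor_span`` is on the amplicon, the mature spans are on the
    precursor.  Guides are recorded against allele 1.
    """

    locus_id: str
    allele_seqs: list[str]
    precursor_span: tuple[int, int]
    mir5p_span: tuple[int, int]
    mir3p_span: tuple[int, int]
    guides: tuple[GuideSite, GuideSite]
    snp_truth: list[tuple[int, int, str, str]] = field(default_factory=list)
    # (allele_index, amplicon_pos, ref_base, alt_base)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.allele_seqs) <= 4:
            raise ValueError("1-4 alleles required")
        ref = self.allele_seqs[0]
        if any(len(a) != len(ref) for a in self.allele_seqs):
            raise ValueError("alleles must align with substitutions only")
        p_lo, p_hi = self.precursor_span
        for span in (self.mir5p_span, self.mir3p_span):
            if not (0 <= span[0] < span[1] <= p_hi - p_lo):
                raise ValueError("mature span outside precursor")
        a, b = self.mir5p_span
        c, d = self.mir3p_span
        if a < d and c < b:
            raise ValueError("mir5p and mir3p spans overlap")
        for g in self.guides:
            s, e = g.protospacer_span
            ps, pe = g.pam_span
            if g.strand == "+":
                if ref[ps + 1 : pe] != "GG":
                    raise ValueError("plus-strand PAM is not NGG on allele 1")
            else:
                if ref[ps : pe - 1] != "CC":
                    raise ValueError("minus-strand PAM is not NGG on allele 1")

    @property
    def precursor_seq(self) -> str:
        lo, hi = self.precursor_span
        return self.allele_seqs[0][lo:hi]

    def precursor_of(self, allele_seq: str) -> str:
        lo, hi = self.precursor_span
        return allele_seq[lo:hi]

    def mir5p_amplicon_span(self) -> tuple[int, int]:
        lo = self.precursor_span[0]
        return (lo + self.mir5p_span[0], lo + self.mir5p_span[1])

    @property
    def mature_mir5p(self) -> str:
        a, b = self.mir5p_span
        return self.precursor_seq[a:b]

    @property
    def cut_positions(self) -> tuple[int, int]:
        c1, c2 = self.guides[0].cut_pos, self.guides[1].cut_pos
        return (min(c1, c2), max(c1, c2))


MUTATION_TYPES = (
    "none",
    "short_deletion",
    "insertion",
    "inter_guide_excision",
    "large_deletion",
)


@dataclass(frozen=True)
class MutationCall:
    """One classified edit on one amplicon/allele (amplicon coordinates)."""

    type: str
    span: tuple[int, int] = (0, 0)
    inserted_base: str | None = None
    distance_to_cut: int | None = None
    overlaps_mir5p: bool = False

    def __post_init__(self) -> None:
        if self.type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.type!r}")
        length = self.span[1] - self.span[0]
        if self.type == "short_deletion" and not 1 <= length <= 6:
            raise ValueError("short deletion must be 1-6 nt")
        if self.type == "large_deletion" and length <= 6:
            raise ValueError("large deletion must exceed 6 nt")

    @property
    def is_edit(self) -> bool:
        return self.type != "none"
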