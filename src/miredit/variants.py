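"""miRNA-variant discovery from small-RNA reads.

Reads are adapter-trimmed and quality-filtered, collapsed to unique
sequences, mapped to wild-type plus mutated precursors by exact substring
match (no mismatches), and classified: canonical mature miRNA, templated
length variant (shifted 5'/3' ends, perfectly matching a precursor), or
non-templated variant (terminal additions of up to 3 nt absent from the
precursor).  Line-specific variants are then isolated by an exclusion
filter — a variant counts for a test group only when entirely absent from
every control sample — and counts are normalized to counts per million
clean reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

MAX_TAIL_NT = 3


@dataclass(frozen=True)
class CleanRead:
    sequence: str
    sample_id: str
    count: int


@dataclass
class VariantCall:
    sequence: str
    var_class: str  # 'canonical' | 'templated' | 'non_templated'
    sources: tuple[str, ...]
    unambiguous: bool
    offset5: int | None = None  # vs canonical mature span (templated only)
    offset3: int | None = None
    tail: str = ""
    tail_end: str = ""  # '5p' | '3p' | ''
    counts: dict[str, int] = field(default_factory=dict)  # per sample
    cpm: dict[str, float] = field(default_factory=dict)
    low_abundance: bool = False  # total count <= 2


class FastqParseError(ValueError):
    pass


def _iter_fastq(source) -> list[tuple[str, str]]:
    """(sequence, quality) pairs from a FASTQ path or in-memory read list."""
    if isinstance(source, (str, Path)):
        try:
            with open(source) as fh:
                return [(seq, qual) for _, seq, qual in FastqGeneralIterator(fh)]
        except ValueError as exc:
            raise FastqParseError(str(exc)) from exc
    return list(source)


def preprocess(
    fastq,
    sample_id: str,
    adapter: str,
    min_phred: int = 20,
    len_range: tuple[int, int] = (18, 30),
    anchor: int = 6,
) -> list[CleanRead]:
    """Adapter-trim, quality-filter and collapse one sample's reads.

    The 3' adapter is located at the first position where at least ``anchor``
    nucleotides of its prefix match (or the read's remaining suffix matches an
    adapter prefix).  The insert is then truncated at the first base with
    phred <= ``min_phred`` ("phred > 20" retained), and inserts outside
    ``len_range`` are discarded.  Identical survivors collapse with counts.
    """
    counts: Counter[str] = Counter()
    lo, hi = len_range
    a_prefix = adapter[:anchor]
    for seq, qual in _iter_fastq(fastq):
        seq = seq.upper()
        cut = len(seq)
        for i in range(len(seq) - anchor + 1):
            if seq[i : i + anchor] != a_prefix:
                continue
            m = min(len(adapter), len(seq) - i)
            if seq[i : i + m] == adapter[:m]:
                cut = i
                break
        insert = seq[:cut]
        for i, q in enumerate(qual[: len(insert)]):
            if ord(q) - 33 <= min_phred:
                insert = insert[:i]
                break
        if lo <= len(insert) <= hi:
            counts[insert] += 1
    return [CleanRead(s, sample_id, c) for s, c in sorted(counts.items())]


def map_exact(
    reads: list[CleanRead], precursors: dict[str, str]
) -> dict[str, tuple[str, ...]]:
    """Exact-substring (sense strand, no mismatches) source lists per read."""
    cache: dict[str, tuple[str, ...]] = {}
    for r in reads:
        if r.sequence not in cache:
            cache[r.sequence] = tuple(
                pid for pid, pseq in precursors.items() if r.sequence in pseq
            )
    return cache


def _strip_tail(seq: str, precursors: dict[str, str]):
    """Best one-end tail strip (<= 3 nt) that makes the core map exactly.

    The end keeping the longest matched core wins; ties prefer the 3' end.
    Returns (core, tail, end, sources) or None.
    """
    for k in range(1, MAX_TAIL_NT + 1):
        for end in ("3p", "5p"):
            core = seq[:-k] if end == "3p" else seq[k:]
            if len(core) < 1:
                continue
            sources = tuple(
                pid for pid, pseq in precursors.items() if core in pseq
            )
            if sources:
                tail = seq[-k:] if end == "3p" else seq[:k]
                return core, tail, end, sources
    return None


def call_variants(
    reads_by_sample: dict[str, list[CleanRead]],
    precursors: dict[str, str],
    canonical: dict[str, tuple[int, int]],
    library_sizes: dict[str, int] | None = None,
) -> list[VariantCall]:
    """Classify collapsed reads into canonical / templated / non-templated.

    ``canonical`` maps precursor id to the mature-miRNA span on that
    precursor.  A mapped read overlapping the mature span of a source is
    templated (canonical when the ends coincide); an unmapped read whose core
    maps after stripping a <= 3 nt terminal addition is non-templated.
    Everything else is discarded.  Counts are tallied per sample and
    normalized to cpm using ``library_sizes`` (clean reads per sample;
    computed from the input when omitted).
    """
    if library_sizes is None:
        library_sizes = {
            s: sum(r.count for r in rs) for s, rs in reads_by_sample.items()
        }
    variants: dict[tuple, VariantCall] = {}

    all_seqs: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for r in reads:
            all_seqs.setdefault(r.sequence, {})[sample] = r.count

    source_cache: dict[str, tuple[str, ...]] = {}
    for seq, per_sample in all_seqs.items():
        sources = source_cache.get(seq)
        if sources is None:
            sources = tuple(p for p, ps in precursors.items() if seq in ps)
            source_cache[seq] = sources

        if sources:
            overlapping = []
            off5 = off3 = None
            for pid in sources:
                lo, hi = canonical[pid]
                pos = precursors[pid].find(seq)
                s_lo, s_hi = pos, pos + len(seq)
                if s_lo < hi and lo < s_hi:
                    overlapping.append(pid)
                    if off5 is None:
                        off5, off3 = s_lo - lo, s_hi - hi
            if not overlapping:
                continue  # maps outside any mature region: not a miRNA variant
            var_class = (
                "canonical" if (off5, off3) == (0, 0) else "templated"
            )
            call = VariantCall(
                sequence=seq,
                var_class=var_class,
                sources=tuple(overlapping),
                unambiguous=len(overlapping) == 1,
                offset5=off5,
                offset3=off3,
            )
        else:
            stripped = _strip_tail(seq, precursors)
            if stripped is None:
                continue
            core, tail, end, core_sources = stripped
            overlapping = []
            for pid in core_sources:
                lo, hi = canonical[pid]
                pos = precursors[pid].find(core)
                if pos < hi and lo < pos + len(core):
                    overlapping.append(pid)
            if not overlapping:
                continue
            call = VariantCall(
                sequence=seq,
                var_class="non_templated",
                sources=tuple(overlapping),
                unambiguous=len(overlapping) == 1,
                tail=tail,
                tail_end=end,
            )
        call.counts = dict(per_sample)
        call.cpm = {
            s: cpm(c, library_sizes[s]) for s, c in per_sample.items()
        }
        call.low_abundance = sum(per_sample.values()) <= 2
        variants[(seq,)] = call
    return sorted(variants.values(), key=lambda v: v.sequence)


def specificity_filter(
    variants: list[VariantCall],
    test_group: set[str],
    control_groups: list[set[str]],
) -> list[VariantCall]:
    """Exclusion filter: keep variants seen in the test group only.

    A variant passes iff it has count >= 1 in at least one test sample and
    count 0 in every sample of every control group.  Groups must be disjoint.
    """
    controls: set[str] = set()
    for g in control_groups:
        controls |= g
    if test_group & controls:
        raise ValueError("test and control groups overlap")
    kept = []
    for v in variants:
        in_test = any(v.counts.get(s, 0) >= 1 for s in test_group)
        in_control = any(v.counts.get(s, 0) >= 1 for s in controls)
        if in_test and not in_control:
            kept.append(v)
    return kept


def cpm(count: int, library_size: int) -> float:
    """Counts per million clean reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / library_size * 1e6
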