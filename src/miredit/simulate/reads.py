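"""Seeded sRNA-seq read simulator with per-read ground truth.

Reads emulate 50-nt single-end small-RNA sequencing of processed miRNA
precursors: a mature-miRNA insert (canonical, a templated length variant, or
a non-templated tailed variant), the 3' sequencing adapter, truncation to the
read length, and phred qualities drawn around a configurable mean.
Precursors classified as impaired yield reads only at the configured leak
rate (default 0 — impaired means no processing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter


@dataclass(frozen=True)
class ReadSimConfig:
    read_length: int = 50
    depth: int = 10_000  # reads per sample
    adapter: str = DEFAULT_ADAPTER
    phred_mean: float = 30.0
    phred_sd: float = 3.0
    tailing_prob: float = 0.1
    tail_length_probs: tuple[float, ...] = (0.7, 0.2, 0.1)  # P(len=1,2,3)
    canonical_prob: float = 0.7  # else a templated length variant
    max_end_offset: int = 1  # templated 5'/3' end shifts, uniform +/- this
    impaired_leak: float = 0.0  # relative yield of impaired precursors

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if set(self.adapter) - set("ACGT"):
            raise ValueError("adapter must contain only ACGT")
        longest = 21 + self.max_end_offset + len(self.tail_length_probs)
        if self.read_length < longest + 1:
            raise ValueError("read_length must exceed the longest sRNA")


@dataclass(frozen=True)
class PrecursorSpec:
    """One precursor contributing reads to a sample."""

    precursor_id: str
    sequence: str  # DNA alphabet
    mature_span: tuple[int, int]  # mature miRNA on this precursor
    impaired: bool = False
    weight: float = 1.0


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    precursors: tuple[PrecursorSpec, ...] = field(default_factory=tuple)


def _draw_insert(rng, prec: PrecursorSpec, cfg: ReadSimConfig):
    lo, hi = prec.mature_span
    seq = prec.sequence
    if rng.random() >= cfg.canonical_prob:
        d5 = int(rng.integers(-cfg.max_end_offset, cfg.max_end_offset + 1))
        d3 = int(rng.integers(-cfg.max_end_offset, cfg.max_end_offset + 1))
        lo = max(0, lo + d5)
        hi = min(len(seq), hi + d3)
        if hi - lo < 18:
            lo, hi = prec.mature_span
    insert = seq[lo:hi]
    tail = ""
    if rng.random() < cfg.tailing_prob:
        tail_len = 1 + int(rng.choice(len(cfg.tail_length_probs),
                                      p=np.array(cfg.tail_length_probs)))
        three_prime = rng.random() < 0.8
        bases = []
        for k in range(tail_len):
            if k == 0:
                # first tail base must break templating at the chosen end
                if three_prime:
                    nxt = seq[hi] if hi < len(seq) else None
                else:
                    nxt = seq[lo - 1] if lo > 0 else None
                choices = [b for b in "ACGT" if b != nxt]
            else:
                choices = list("ACGT")
            bases.append(str(rng.choice(choices)))
        tail = "".join(bases)
        if three_prime:
            insert = insert + tail
            tail_end = "3p"
        else:
            insert = tail[::-1] + insert
            tail = tail[::-1]
            tail_end = "5p"
    else:
        tail_end = ""
    return insert, (lo, hi), tail, tail_end


def simulate_srna_reads(
    samples: list[SampleSpec],
    cfg: ReadSimConfig,
    seed: int = 0,
    fastq_dir: str | Path | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate per-sample FASTQ reads and the matching truth table.

    Returns ``(reads, truth)`` where ``reads[sample_id]`` is a list of
    (sequence, phred33 quality) pairs and ``truth`` is a tidy table with one
    row per distinct simulated insert per sample: sample, group, precursor,
    variant sequence, templated flag, tail, tail end and count.  When
    ``fastq_dir`` is given, one ``<sample>.fastq`` per sample is written with
    the seed recorded in each header.
    """
    rng = np.random.default_rng(seed)
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: dict[tuple, int] = {}

    for sample in samples:
        weights = np.array(
            [
                p.weight * (cfg.impaired_leak if p.impaired else 1.0)
                for p in sample.precursors
            ],
            dtype=float,
        )
        out: list[tuple[str, str]] = []
        if weights.sum() > 0:
            probs = weights / weights.sum()
            for _ in range(cfg.depth):
                prec = sample.precursors[int(rng.choice(len(probs), p=probs))]
                insert, span, tail, tail_end = _draw_insert(rng, prec, cfg)
                full = (insert + cfg.adapter)[: cfg.read_length]
                quals = np.clip(
                    np.rint(rng.normal(cfg.phred_mean, cfg.phred_sd, len(full))),
                    2,
                    41,
                ).astype(int)
                out.append((full, "".join(chr(q + 33) for q in quals)))
                key = (
                    sample.sample_id,
                    sample.group,
                    prec.precursor_id,
                    insert,
                    tail == "",
                    tail,
                    tail_end,
                )
                truth_rows[key] = truth_rows.get(key, 0) + 1
        reads[sample.sample_id] = out

    truth = pd.DataFrame(
        [k + (v,) for k, v in truth_rows.items()],
        columns=[
            "sample",
            "group",
            "precursor",
            "variant",
            "templated",
            "tail",
            "tail_end",
            "count",
        ],
    )

    if fastq_dir is not None:
        fastq_dir = Path(fastq_dir)
        fastq_dir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            with open(fastq_dir / f"{sample.sample_id}.fastq", "w") as fh:
                for i, (seq, qual) in enumerate(reads[sample.sample_id]):
                    fh.write(
                        f"@{sample.sample_id}.{i} seed={seed}\n{seq}\n+\n{qual}\n"
                    )
    return reads, truth
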