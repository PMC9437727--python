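"""Mixed Sanger-trace surrogate: per-position base-proportion matrices.

A real mixed chromatogram downstream of a cut site shows superimposed peaks
from the co-amplified edited alleles.  The surrogate is the column-stochastic
4 x L matrix of expected base proportions (rows A,C,G,T) over an analysis
window, optionally perturbed by symmetric noise — a plain-text stand-in for
.ab1 files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_ROW = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class TraceMatrix:
    window: tuple[int, int]  # half-open, common reference coordinates
    matrix: np.ndarray  # shape (4, window length), columns sum to 1
    noise: float = 0.0

    def __post_init__(self) -> None:
        w = self.window[1] - self.window[0]
        if self.matrix.shape != (4, w):
            raise ValueError("matrix shape does not match window")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("entries must lie in [0, 1]")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("columns must sum to 1")

    def to_tsv(self, path: str | Path, header: str | None = None) -> None:
        lines = []
        if header:
            lines.append(f"# {header}")
        lines.append("pos\tA\tC\tG\tT")
        for k in range(self.matrix.shape[1]):
            col = "\t".join(f"{v:.10f}" for v in self.matrix[:, k])
            lines.append(f"{self.window[0] + k}\t{col}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraceMatrix":
        rows = []
        start = None
        for line in Path(path).read_text().splitlines():
            if line.startswith("#") or line.startswith("pos"):
                continue
            parts = line.split("\t")
            if start is None:
                start = int(parts[0])
            rows.append([float(x) for x in parts[1:5]])
        m = np.array(rows).T
        return cls(window=(start, start + m.shape[1]), matrix=m)


def profile_matrix(sequences: list[str], window: tuple[int, int]) -> np.ndarray:
    """Stacked one-hot profiles (len(sequences) rows of 4 x W) — unweighted."""
    lo, hi = window
    out = np.zeros((len(sequences), 4, hi - lo))
    for s_idx, seq in enumerate(sequences):
        for k, pos in enumerate(range(lo, hi)):
            if pos < len(seq):
                out[s_idx, _ROW[seq[pos]], k] = 1.0
            else:
                out[s_idx, :, k] = 0.25  # signal run-off: uninformative column
    return out


def simulate_sanger_trace(
    mixture: list[tuple[str, float]],
    window: tuple[int, int],
    noise: float = 0.0,
    seed: int = 0,
) -> TraceMatrix:
    """Expected mixed-trace matrix for pre-aligned sequences.

    Sequences must share a common reference start (position 0); proportions
    must sum to 1 and noise lies in [0, 0.2).  Columns are the
    mixture-weighted base indicators plus symmetric uniform noise,
    renormalized.
    """
    if not 0 <= noise < 0.2:
        raise ValueError("noise must be in [0, 0.2)")
    props = np.array([p for _, p in mixture], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    lo, hi = window
    if lo < 0 or all(lo >= len(seq) for seq, _ in mixture):
        raise IndexError("window outside all sequences")
    rng = np.random.default_rng(seed)
    profiles = profile_matrix([s for s, _ in mixture], window)
    m = np.einsum("s,sbk->bk", props, profiles)
    if noise > 0:
        m = m + rng.uniform(0.0, noise, size=m.shape)
    m = m / m.sum(axis=0, keepdims=True)
    return TraceMatrix(window=window, matrix=m, noise=noise)
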