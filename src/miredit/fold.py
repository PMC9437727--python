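"""Minimum-free-energy RNA secondary-structure prediction.

The internal engine is a Zuker-style dynamic program over the decomposable
nearest-neighbor model in :mod:`miredit.energy`: hairpins, stacks, bulges,
interior loops (<= 30 unpaired nt) and affine multiloops, no pseudoknots.
Three independent routes over the same parameter table are provided:

* :func:`fold` — the O(n^2 * L^2) dynamic program (numba-compiled kernel);
* :func:`score_structure` — re-scores any dot-bracket by loop decomposition;
* :func:`enumerate_structures` — exhaustive enumeration, feasible to ~14 nt,
  used as a brute-force oracle in tests.

An optional external backend (:func:`fold_external`) calls ViennaRNA's RNAfold
(python bindings or binary) for validation; its structures are never mixed
into internal results — the ``engine_tag`` field records provenance.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .energy import (
    BULGE_TABLE,
    HAIRPIN_TABLE,
    INF,
    INTERIOR_TABLE,
    MAXLOOP,
    MIN_HAIRPIN,
    ML_BRANCH,
    ML_CLOSING,
    NINIO_MAX,
    NINIO_SLOPE,
    PAIR_TABLE,
    STACK,
    encode,
    hairpin_energy,
    internal_energy,
)

MIN_FOLD_LEN = 10


class SequenceTooShortError(ValueError):
    """Raised for sequences below the minimum foldable length."""


@dataclass(frozen=True)
class FoldResult:
    """A predicted MFE structure for one sequence."""

    sequence: str  # normalized RNA (ACGU, uppercase)
    dot_bracket: str
    mfe_kcal_mol: float
    engine_tag: str = "internal"

    def pair_partners(self) -> np.ndarray:
        """Partner index per position, -1 when unpaired."""
        return pair_table(self.dot_bracket)


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject other symbols."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return s


def pair_table(dot_bracket: str) -> np.ndarray:
    """Parse a dot-bracket string into a partner array (checks balance)."""
    partner = np.full(len(dot_bracket), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return partner


# ---------------------------------------------------------------------------
# dynamic programming kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill(s, pair_tab, stack_tab, hp_tab, bulge_tab, int_tab):
    n = s.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            p = pair_tab[s[i], s[j]]
            if p >= 0:
                # hairpin
                best = hp_tab[j - i - 1]
                # stack / bulge / interior
                max_u1 = min(MAXLOOP, j - i - 2 - MIN_HAIRPIN)
                for u1 in range(0, max_u1 + 1):
                    k = i + 1 + u1
                    for u2 in range(0, MAXLOOP - u1 + 1):
                        l = j - 1 - u2
                        if l - k <= MIN_HAIRPIN:
                            break
                        q = pair_tab[s[k], s[l]]
                        if q < 0 or V[k, l] >= INF:
                            continue
                        if u1 == 0 and u2 == 0:
                            e = stack_tab[p, q]
                        elif u1 == 0 or u2 == 0:
                            e = bulge_tab[u1 + u2]
                            if u1 + u2 == 1:
                                e += stack_tab[p, q]
                        else:
                            asym = NINIO_SLOPE * abs(u1 - u2)
                            if asym > NINIO_MAX:
                                asym = NINIO_MAX
                            e = int_tab[u1 + u2] + asym
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop closing: >=2 branches inside
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        cand = (
                            ML_CLOSING
                            + ML_BRANCH
                            + WM[i + 1, k]
                            + WM[k + 1, j - 1]
                        )
                        if cand < best:
                            best = cand
                V[i, j] = best

            # WM: segment inside a multiloop carrying >= 1 branch
            best = INF
            if WM[i + 1, j] < best:
                best = WM[i + 1, j]
            if WM[i, j - 1] < best:
                best = WM[i, j - 1]
            if V[i, j] < INF and V[i, j] + ML_BRANCH < best:
                best = V[i, j] + ML_BRANCH
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    cand = WM[i, k - 1] + WM[k, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best

    # external loop
    W = np.zeros(n + 1, dtype=np.int64)  # W[t] = prefix [0, t)
    for t in range(1, n + 1):
        j = t - 1
        best = W[t - 1]
        for i in range(0, j):
            if V[i, j] < INF:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[t] = best
    return V, WM, W


def _traceback(s: np.ndarray, V: np.ndarray, WM: np.ndarray, W: np.ndarray) -> str:
    """Deterministic traceback; preference order fixed (pairing first,
    smallest interior offsets first) so results are reproducible."""
    n = s.shape[0]
    struct = ["."] * n
    tasks: list[tuple[str, int, int]] = []

    def pc(i: int, j: int) -> int:
        return int(PAIR_TABLE[s[i], s[j]])

    # external loop: peel branches off the right end
    t = n
    while t > 0:
        j = t - 1
        if W[t] == W[t - 1]:
            t -= 1
            continue
        placed = False
        for i in range(0, j):
            if V[i, j] < INF and int(W[i]) + int(V[i, j]) == int(W[t]):
                struct[i], struct[j] = "(", ")"
                tasks.append(("V", i, j))
                t = i
                placed = True
                break
        if not placed:  # pragma: no cover - internal consistency guard
            raise AssertionError("traceback failed in external loop")

    while tasks:
        mode, i, j = tasks.pop()
        if i >= j:
            continue
        if mode == "V":
            target = int(V[i, j])
            p = pc(i, j)
            if hairpin_energy(j - i - 1) == target:
                continue
            found = False
            max_u1 = min(MAXLOOP, j - i - 2 - MIN_HAIRPIN)
            for u1 in range(0, max_u1 + 1):
                k = i + 1 + u1
                for u2 in range(0, MAXLOOP - u1 + 1):
                    l = j - 1 - u2
                    if l - k <= MIN_HAIRPIN:
                        break
                    q = pc(k, l)
                    if q < 0 or V[k, l] >= INF:
                        continue
                    e = internal_energy(u1, u2, p, q)
                    if e < INF and e + int(V[k, l]) == target:
                        struct[k], struct[l] = "(", ")"
                        tasks.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                    if (
                        ML_CLOSING
                        + ML_BRANCH
                        + int(WM[i + 1, k])
                        + int(WM[k + 1, j - 1])
                        == target
                    ):
                        tasks.append(("WM", i + 1, k))
                        tasks.append(("WM", k + 1, j - 1))
                        found = True
                        break
            if not found:  # pragma: no cover - internal consistency guard
                raise AssertionError("traceback failed in V")
        else:  # WM
            target = int(WM[i, j])
            if V[i, j] < INF and int(V[i, j]) + ML_BRANCH == target:
                struct[i], struct[j] = "(", ")"
                tasks.append(("V", i, j))
                continue
            if WM[i + 1, j] < INF and int(WM[i + 1, j]) == target:
                tasks.append(("WM", i + 1, j))
                continue
            if WM[i, j - 1] < INF and int(WM[i, j - 1]) == target:
                tasks.append(("WM", i, j - 1))
                continue
            found = False
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    if int(WM[i, k - 1]) + int(WM[k, j]) == target:
                        tasks.append(("WM", i, k - 1))
                        tasks.append(("WM", k, j))
                        found = True
                        break
            if not found:  # pragma: no cover - internal consistency guard
                raise AssertionError("traceback failed in WM")
    return "".join(struct)


def fold(seq: str) -> FoldResult:
    """Predict the MFE structure of an RNA (or DNA; T converted) sequence.

    Raises
    ------
    SequenceTooShortError
        if the sequence is shorter than 10 nt.
    ValueError
        for non-nucleotide symbols.
    """
    rna = normalize_rna(seq)
    if len(rna) < MIN_FOLD_LEN:
        raise SequenceTooShortError(
            f"sequence length {len(rna)} < {MIN_FOLD_LEN}"
        )
    s = encode(rna)
    V, WM, W = _fill(s, PAIR_TABLE, STACK, HAIRPIN_TABLE, BULGE_TABLE, INTERIOR_TABLE)
    mfe_dcal = int(W[len(rna)])
    if mfe_dcal >= 0:
        return FoldResult(rna, "." * len(rna), 0.0, "internal")
    db = _traceback(s, V, WM, W)
    return FoldResult(rna, db, mfe_dcal / 100.0, "internal")


# ---------------------------------------------------------------------------
# independent re-scorer (loop decomposition of a given structure)
# ---------------------------------------------------------------------------


def score_structure(seq: str, dot_bracket: str) -> float:
    """Energy (kcal/mol) of a given structure under the same parameter table.

    Independent of the dynamic program: decomposes the structure into loops
    and sums their contributions.  Structures containing features outside the
    model space (interior loops > 30 unpaired nt, hairpins < 3 nt) score +inf.
    """
    rna = normalize_rna(seq)
    if len(rna) != len(dot_bracket):
        raise ValueError("sequence / structure length mismatch")
    partner = pair_table(dot_bracket)
    total = 0

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids = []
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                kids.append((k, int(partner[k])))
                k = int(partner[k]) + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    def loop_energy(i: int, j: int) -> int:
        p = int(PAIR_TABLE[encode(rna[i])[0], encode(rna[j])[0]])
        if p < 0:
            return INF
        kids, unpaired = children_of(i, j)
        if not kids:
            return hairpin_energy(j - i - 1)
        if len(kids) == 1:
            k, l = kids[0]
            q = int(PAIR_TABLE[encode(rna[k])[0], encode(rna[l])[0]])
            if q < 0:
                return INF
            return internal_energy(k - i - 1, j - l - 1, p, q)
        return ML_CLOSING + ML_BRANCH * (1 + len(kids))

    # walk every pair once
    stack_pairs = [
        (i, int(partner[i])) for i in range(len(rna)) if partner[i] > i
    ]
    for i, j in stack_pairs:
        e = loop_energy(i, j)
        if e >= INF:
            return float("inf")
        total += e
    return total / 100.0


# ---------------------------------------------------------------------------
# brute-force enumeration oracle (tiny sequences)
# ---------------------------------------------------------------------------


def enumerate_structures(seq: str, max_len: int = 16) -> list[str]:
    """All dot-bracket structures over canonical pairs with hairpins >= 3 nt.

    Exhaustive; guarded to short sequences (count grows exponentially).
    """
    rna = normalize_rna(seq)
    n = len(rna)
    if n > max_len:
        raise ValueError(f"enumeration limited to <= {max_len} nt")
    s = encode(rna)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i < MIN_HAIRPIN + 1:
            return ((),)
        out = list(structs(i, j - 1))
        for k in range(i, j - MIN_HAIRPIN):
            if PAIR_TABLE[s[k], s[j]] >= 0:
                for left in structs(i, k - 1) if k > i else ((),):
                    for inner in structs(k + 1, j - 1):
                        out.append(left + inner + ((k, j),))
        return tuple(out)

    results = []
    for pairing in structs(0, n - 1):
        db = ["."] * n
        for a, b in pairing:
            db[a], db[b] = "(", ")"
        results.append("".join(db))
    structs.cache_clear()
    return results


def brute_force_mfe(seq: str, max_len: int = 16) -> tuple[str, float]:
    """Exhaustive-minimum structure and energy; oracle for :func:`fold`."""
    best_db, best_e = "." * len(seq), 0.0
    for db in enumerate_structures(seq, max_len=max_len):
        e = score_structure(seq, db)
        if e < best_e:
            best_db, best_e = db, e
    return best_db, best_e


# ---------------------------------------------------------------------------
# external validation backend (ViennaRNA)
# ---------------------------------------------------------------------------


def fold_external(seq: str) -> FoldResult:
    """MFE structure from ViennaRNA (python bindings, else RNAfold binary).

    Validation backend only: results carry ``engine_tag='external-validation'``
    and are never mixed with internal results.
    """
    rna = normalize_rna(seq)
    try:
        import RNA  # type: ignore

        db, mfe = RNA.fold(rna)
        return FoldResult(rna, db, float(mfe), "external-validation")
    except ImportError:
        pass
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "no external folding backend available "
            "(neither ViennaRNA python bindings nor RNAfold binary)"
        )
    out = subprocess.run(
        [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True,
        check=True,
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split(None, 1)[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(rna, db, mfe, "external-validation")
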