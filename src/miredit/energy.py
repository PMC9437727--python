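"""Nearest-neighbor free-energy parameters for RNA secondary structure.

Turner-style 2004 parameter set at 37 degC, reduced to the terms needed for
minimum-free-energy hairpin evaluation: Watson-Crick + G:U stacking, loop
initiation penalties (hairpin / bulge / interior with Ninio asymmetry) and an
affine multiloop model.  Dangling ends, coaxial stacking, terminal-AU
penalties and the special small-loop / tetraloop tables are deliberately
omitted; the model is fully decomposable, so a structure's energy is the sum
of its loop contributions and an independent re-scorer can reproduce the
dynamic-programming optimum exactly.

All energies are stored as integers in dcal/mol (0.01 kcal/mol) and exposed
to callers in kcal/mol.
"""

from __future__ import annotations

import math

import numpy as np

INF = 10_000_000  # sentinel, dcal/mol

#: canonical pair codes; -1 = not pairable
_PAIR_CODE = {
    ("C", "G"): 0,
    ("G", "C"): 1,
    ("G", "U"): 2,
    ("U", "G"): 3,
    ("A", "U"): 4,
    ("U", "A"): 5,
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair code lookup indexed by (base_i, base_j); -1 if not a legal pair
PAIR_TABLE = np.full((4, 4), -1, dtype=np.int64)
for (x, y), code in _PAIR_CODE.items():
    PAIR_TABLE[_BASE_CODE[x], _BASE_CODE[y]] = code

# stack[p1][p2]: pair (i,j) with code p1 stacked on interior pair (i+1,j-1)
# with code p2.  Rows/cols ordered CG GC GU UG AU UA.
STACK = np.array(
    [
        [-240, -330, -210, -140, -210, -210],
        [-330, -340, -250, -150, -220, -240],
        [-210, -250, 130, -50, -140, -130],
        [-140, -150, -50, 30, -60, -100],
        [-210, -220, -140, -60, -110, -90],
        [-210, -240, -130, -100, -90, -130],
    ],
    dtype=np.int64,
)

# loop initiation energies by number of unpaired nucleotides
_HAIRPIN = [
    540, 560, 570, 540, 600, 550, 640, 650, 660, 670, 678, 686, 694, 701,
    707, 713, 719, 725, 730, 735, 740, 744, 749, 753, 757, 761, 765, 769,
]  # sizes 3..30
_BULGE = [
    380, 280, 320, 360, 400, 440, 459, 470, 480, 490, 500, 510, 519, 527,
    534, 541, 548, 554, 560, 565, 571, 576, 580, 585, 589, 594, 598, 602,
    605, 609,
]  # sizes 1..30
_INTERIOR = [
    90, 100, 110, 200, 200, 210, 230, 240, 250, 260, 270, 278, 286, 294,
    301, 307, 313, 319, 325, 330, 335, 340, 345, 349, 353, 357, 361, 365,
    369,
]  # sizes 2..30

MAXLOOP = 30  # max unpaired nucleotides in a bulge / interior loop
MIN_HAIRPIN = 3  # min unpaired nucleotides closing a hairpin

# Ninio interior-loop asymmetry: 60 dcal per unpaired-count difference, cap 300
NINIO_SLOPE = 60
NINIO_MAX = 300

# affine multiloop: closing penalty + per-branch (closing pair included) term;
# unpaired multiloop bases are free in this parameter set
ML_CLOSING = 340
ML_BRANCH = 40

# Jacobson-Stockmayer extrapolation coefficient (1.75 * RT at 37 degC)
_LXC = 107.856


def _extrapolate(base30: int, size: int) -> int:
    return int(base30 + _LXC * math.log(size / 30.0))


# precomputed dense loop tables up to a practical ceiling so the numba kernel
# can index them directly
_TABLE_CEIL = 2000

HAIRPIN_TABLE = np.full(_TABLE_CEIL + 1, INF, dtype=np.int64)
for n in range(3, 31):
    HAIRPIN_TABLE[n] = _HAIRPIN[n - 3]
for n in range(31, _TABLE_CEIL + 1):
    HAIRPIN_TABLE[n] = _extrapolate(_HAIRPIN[-1], n)

BULGE_TABLE = np.full(MAXLOOP + 1, INF, dtype=np.int64)
for n in range(1, 31):
    BULGE_TABLE[n] = _BULGE[n - 1]

INTERIOR_TABLE = np.full(MAXLOOP + 1, INF, dtype=np.int64)
for n in range(2, 31):
    INTERIOR_TABLE[n] = _INTERIOR[n - 2]


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string (ACGU) as int codes for the folding kernels."""
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"non-RNA symbol in sequence: {exc}") from None


def pair_code(a: str, b: str) -> int:
    """Pair code of two bases, or -1 if they cannot pair."""
    return int(PAIR_TABLE[_BASE_CODE[a], _BASE_CODE[b]])


def can_pair(a: str, b: str) -> bool:
    return pair_code(a, b) >= 0


def hairpin_energy(size: int) -> int:
    """Hairpin-loop initiation (dcal/mol) for `size` unpaired bases."""
    if size < MIN_HAIRPIN:
        return INF
    if size <= _TABLE_CEIL:
        return int(HAIRPIN_TABLE[size])
    return _extrapolate(_HAIRPIN[-1], size)


def internal_energy(u1: int, u2: int, p_outer: int, p_inner: int) -> int:
    """Energy (dcal/mol) of the two-strand loop between two pairs.

    ``u1``/``u2`` are the unpaired counts on each strand; (0,0) is a stack,
    one-sided loops are bulges (a 1-bulge keeps the closing-pair stack), the
    rest are interior loops with Ninio asymmetry.
    """
    if u1 == 0 and u2 == 0:
        return int(STACK[p_outer, p_inner])
    total = u1 + u2
    if total > MAXLOOP:
        return INF
    if u1 == 0 or u2 == 0:
        e = int(BULGE_TABLE[total])
        if total == 1:
            e += int(STACK[p_outer, p_inner])
        return e
    e = int(INTERIOR_TABLE[total])
    e += min(NINIO_MAX, NINIO_SLOPE * abs(u1 - u2))
    return e
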