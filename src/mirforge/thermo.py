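"""Nearest-neighbour thermodynamic model shared by folding and duplexes.

The model is the standard loop-decomposition free energy: stacked pairs
contribute tabulated stacking energies, hairpin/bulge/internal loops pay
size-dependent initiation penalties, and multibranch loops pay a linear
``a + b * branches + c * unpaired`` term.  Energies are Turner-like
defaults shipped with the package (no dangles, no coaxial stacking, no
terminal-AU term) and are handled internally as integer centi-kcal/mol so
that optima and tie-breaks are exact.

Pair encoding: bases A,C,G,U -> 0..3; pair types AU,UA,CG,GC,GU,UG -> 0..5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ENERGY_MODEL_VERSION = "mirforge-nn-1.0"

BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")

#: 4x4 base -> pair-type lookup, -1 where unpairable
PAIR_TABLE = np.full((4, 4), -1, dtype=np.int64)
for _t, (_a, _b) in enumerate(PAIR_NAMES):
    PAIR_TABLE[BASE_CODE[_a], BASE_CODE[_b]] = _t

WC_PARTNER = {"A": "U", "U": "A", "C": "G", "G": "C"}

# stacking energies, kcal/mol: STACK[outer pair][inner pair], outer = (i, j),
# inner = (i+1, j-1).  Turner-like magnitudes; all <= 0 by model invariant.
_STACK_KCAL = [
    #  AU     UA     CG     GC     GU     UG     (inner)
    [-0.90, -1.10, -2.20, -2.10, -0.60, -1.40],  # outer AU
    [-1.30, -0.90, -2.40, -2.10, -1.00, -1.30],  # outer UA
    [-2.10, -2.10, -3.30, -2.40, -1.40, -2.10],  # outer CG
    [-2.40, -2.20, -3.40, -3.30, -1.50, -2.50],  # outer GC
    [-1.30, -1.40, -2.50, -2.10, -0.50, -1.30],  # outer GU
    [-1.00, -0.60, -1.50, -1.40, -0.30, -0.50],  # outer UG
]

_HAIRPIN_KCAL = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.8, 7: 5.9, 8: 6.0, 9: 6.1}
_BULGE_KCAL = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_KCAL = {2: 1.7, 3: 2.7, 4: 3.0, 5: 3.3, 6: 3.6}
_LOOP_EXTRAPOLATION = 1.08  # kcal/mol multiplier on ln(n / n_max)

MAX_LOOP_TABLE = 2048  # longest loop size with a tabulated penalty


def _loop_array(table: dict[int, float], n_max: int) -> np.ndarray:
    """Centi-kcal penalty array indexed by loop size, log-extrapolated."""
    biggest = max(table)
    arr = np.full(n_max + 1, 10**8, dtype=np.int64)
    for size in range(min(table), n_max + 1):
        if size in table:
            kcal = table[size]
        else:
            kcal = table[biggest] + _LOOP_EXTRAPOLATION * math.log(size / biggest)
        arr[size] = round(kcal * 100)
    return arr


@dataclass
class FoldParams:
    """Energy tables and structural constants for the fold model.

    All integer arrays are centi-kcal/mol.  ``min_hairpin`` is the minimum
    number of unpaired nucleotides in a hairpin loop; ``max_internal``
    caps the total unpaired size of bulge/internal loops considered by
    the dynamic programme (a standard speed cap; the brute-force oracle
    in the test-suite runs on sequences far below this cap).
    """

    stack: np.ndarray = field(
        default_factory=lambda: np.rint(np.array(_STACK_KCAL) * 100).astype(np.int64)
    )
    hairpin: np.ndarray = field(
        default_factory=lambda: _loop_array(_HAIRPIN_KCAL, MAX_LOOP_TABLE)
    )
    bulge: np.ndarray = field(
        default_factory=lambda: _loop_array(_BULGE_KCAL, MAX_LOOP_TABLE)
    )
    internal: np.ndarray = field(
        default_factory=lambda: _loop_array(_INTERNAL_KCAL, MAX_LOOP_TABLE)
    )
    multi_close: int = 340  # "a": multiloop closing penalty
    multi_branch: int = 40  # "b": per inner branch
    multi_unpaired: int = 0  # "c": per unpaired nucleotide in the loop
    min_hairpin: int = 3
    max_internal: int = 30

    def __post_init__(self) -> None:
        if (self.stack > 0).any():
            raise ValueError("stacking energies must be <= 0")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")


DEFAULT_FOLD_PARAMS = FoldParams()


def encode(seq: str) -> np.ndarray:
    return np.array([BASE_CODE[b] for b in seq], dtype=np.int64)


def pair_type(a: str, b: str) -> int:
    """Pair type of bases (5' base, 3' base), -1 if unpairable."""
    return int(PAIR_TABLE[BASE_CODE[a], BASE_CODE[b]])


def can_pair(a: str, b: str) -> bool:
    return pair_type(a, b) >= 0


def is_watson_crick(a: str, b: str) -> bool:
    return WC_PARTNER[a] == b


# ---------------------------------------------------------------------------
# loop-decomposition energy of an explicit structure
# ---------------------------------------------------------------------------

def structure_energy(
    seq: str,
    pairs: list[tuple[int, int]],
    params: FoldParams | None = None,
) -> float:
    """Free energy (kcal/mol) of a given nested structure on ``seq``.

    This evaluator is the single source of truth for what a structure is
    worth under the shipped model; the fold DP and the precursor-region
    energies must agree with it.  Raises ``ValueError`` for non-nested
    pairs, unpairable bases, or hairpin loops below the minimum size.
    """
    params = params or DEFAULT_FOLD_PARAMS
    return _structure_energy_int(seq, pairs, params) / 100.0


def _structure_energy_int(
    seq: str, pairs: list[tuple[int, int]], params: FoldParams
) -> int:
    pairs = sorted(pairs)
    for i, j in pairs:
        if pair_type(seq[i], seq[j]) < 0:
            raise ValueError(f"bases {i},{j} ({seq[i]}{seq[j]}) cannot pair")
        if j - i - 1 < params.min_hairpin:
            raise ValueError(f"hairpin loop closed by ({i},{j}) is too small")
    # nesting check + children of each pair
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        if stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            raise ValueError(f"pairs {stack[-1]} and {p} are not nested")
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    total = 0
    for (i, j) in pairs:
        kids = children[p := (i, j)]
        if not kids:
            total += int(params.hairpin[j - i - 1])
        elif len(kids) == 1:
            (k, l) = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += int(
                    params.stack[pair_type(seq[i], seq[j]), pair_type(seq[k], seq[l])]
                )
            elif n1 == 0 or n2 == 0:
                total += int(params.bulge[n1 + n2])
            else:
                total += int(params.internal[n1 + n2])
        else:
            unpaired = (j - i - 1) - sum(l2 - k2 + 1 for k2, l2 in kids)
            total += (
                params.multi_close
                + params.multi_branch * len(kids)
                + params.multi_unpaired * unpaired
            )
    return total


def duplex_stack_energy(columns: list[tuple[str, str]]) -> float:
    """Stacking energy (kcal/mol) of an aligned antiparallel duplex.

    ``columns`` run 5'->3' along the first strand; each column is
    (first-strand base, second-strand base) or ``("-", x)`` / ``(x, "-")``
    for gap columns.  Only consecutive paired columns stack; a fully
    unpaired alignment has energy 0.
    """
    params = DEFAULT_FOLD_PARAMS
    total = 0
    prev = -1
    for a, b in columns:
        pt = pair_type(a, b) if a != "-" and b != "-" else -1
        if pt >= 0 and prev >= 0:
            total += int(params.stack[prev, pt])
        prev = pt
    return total / 100.0
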