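"""Minimum-free-energy folding of RNA by dynamic programming.

A Zuker-style recursion over the nearest-neighbour model of
:mod:`mirforge.thermo`: ``V[i,j]`` is the optimum given that (i, j) pair,
decomposed into hairpin / stack / bulge / internal / multibranch loops,
with ``ML``/``M1`` arrays for multibranch interiors and an external
prefix array ``W``.  Structures are fully nested (no pseudoknots).
Energies are integer centi-kcal so the optimum is exact; the DP equals
exhaustive enumeration over all nested structures (property-tested).

The O(n^3) kernel is JIT-compiled with numba; traceback is plain Python
with a fixed transition preference so equal-energy optima resolve
deterministically (pairing is preferred, and among pairings the leftmost).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .io_formats import DotBracket
from .thermo import DEFAULT_FOLD_PARAMS, FoldParams, PAIR_TABLE, encode

INF = np.int64(10**9)

MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 1000


@njit(cache=True)
def _fold_tables(s, ptab, stack, hairpin, bulge, internal,
                 ml_a, ml_b, ml_c, min_loop, max_internal):
    n = s.shape[0]
    V = np.full((n, n), INF, np.int64)
    ML = np.full((n, n), INF, np.int64)
    M1 = np.full((n, n), INF, np.int64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            p = ptab[s[i], s[j]]
            if p >= 0 and span > min_loop:
                best = hairpin[j - i - 1]
                # stack / bulge / internal closed by (i, j)
                for k in range(i + 1, j):
                    n1 = k - i - 1
                    if n1 > max_internal:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        if n1 + n2 > max_internal:
                            break
                        if V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = V[k, l] + stack[p, ptab[s[k], s[l]]]
                        elif n1 == 0 or n2 == 0:
                            e = V[k, l] + bulge[n1 + n2]
                        else:
                            e = V[k, l] + internal[n1 + n2]
                        if e < best:
                            best = e
                # multibranch: a + ML[i+1, u-1] + M1[u, j-1]
                for u in range(i + 2, j):
                    if ML[i + 1, u - 1] < INF and M1[u, j - 1] < INF:
                        e = ml_a + ML[i + 1, u - 1] + M1[u, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # M1: exactly one branch starting at i, optional unpaired tail
            b1 = INF
            if V[i, j] < INF:
                b1 = V[i, j] + ml_b
            if j > i and M1[i, j - 1] < INF:
                e = M1[i, j - 1] + ml_c
                if e < b1:
                    b1 = e
            M1[i, j] = b1
            # ML: at least one branch somewhere in i..j
            bm = M1[i, j]
            if j > i:
                if ML[i, j - 1] < INF:
                    e = ML[i, j - 1] + ml_c
                    if e < bm:
                        bm = e
                if ML[i + 1, j] < INF:
                    e = ML[i + 1, j] + ml_c
                    if e < bm:
                        bm = e
                for u in range(i + 1, j + 1):
                    if ML[i, u - 1] < INF and V[u, j] < INF:
                        e = ML[i, u - 1] + V[u, j] + ml_b
                        if e < bm:
                            bm = e
            ML[i, j] = bm
    W = np.zeros(n + 1, np.int64)  # W[j]: optimum over prefix s[0:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - 1):
            if V[i, j - 1] < INF:
                e = W[i] + V[i, j - 1]
                if e < best:
                    best = e
        W[j] = best
    return V, ML, M1, W


class _Tracer:
    def __init__(self, seq: str, V, ML, M1, W, params: FoldParams):
        self.s = encode(seq)
        self.V, self.ML, self.M1, self.W = V, ML, M1, W
        self.p = params
        self.pairs: list[tuple[int, int]] = []

    def ptype(self, i, j):
        return PAIR_TABLE[self.s[i], self.s[j]]

    def run(self) -> list[tuple[int, int]]:
        self._external(len(self.s))
        return sorted(self.pairs)

    def _external(self, j):
        # prefix decomposition; prefer the pairing with the smallest i
        while j > 0:
            hit = None
            for i in range(0, j - 1):
                if self.V[i, j - 1] < INF and self.W[i] + self.V[i, j - 1] == self.W[j]:
                    hit = i
                    break
            if hit is None:
                j -= 1
            else:
                self._pair(hit, j - 1)
                j = hit

    def _pair(self, i, j):
        self.pairs.append((i, j))
        p = self.p
        e = self.V[i, j]
        pt = self.ptype(i, j)
        # bulge/internal/stack, smallest loop first (stack is n1=n2=0)
        for size in range(0, p.max_internal + 1):
            for n1 in range(0, size + 1):
                n2 = size - n1
                k, l = i + 1 + n1, j - 1 - n2
                if not (i < k < l < j) or self.V[k, l] >= INF:
                    continue
                if size == 0:
                    cost = p.stack[pt, self.ptype(k, l)]
                elif n1 == 0 or n2 == 0:
                    cost = p.bulge[size]
                else:
                    cost = p.internal[size]
                if self.V[k, l] + cost == e:
                    self._pair(k, l)
                    return
        for u in range(i + 2, j):
            if (
                self.ML[i + 1, u - 1] < INF
                and self.M1[u, j - 1] < INF
                and p.multi_close + self.ML[i + 1, u - 1] + self.M1[u, j - 1] == e
            ):
                self._ml(i + 1, u - 1)
                self._m1(u, j - 1)
                return
        assert e == p.hairpin[j - i - 1], "traceback failed in V"

    def _m1(self, i, j):
        p = self.p
        while True:
            if self.V[i, j] < INF and self.V[i, j] + p.multi_branch == self.M1[i, j]:
                self._pair(i, j)
                return
            assert j > i
            assert self.M1[i, j - 1] + p.multi_unpaired == self.M1[i, j]
            j -= 1

    def _ml(self, i, j):
        p = self.p
        while True:
            if self.M1[i, j] == self.ML[i, j]:
                self._m1(i, j)
                return
            if j > i and self.ML[i + 1, j] < INF and self.ML[i + 1, j] + p.multi_unpaired == self.ML[i, j]:
                i += 1
                continue
            if j > i and self.ML[i, j - 1] < INF and self.ML[i, j - 1] + p.multi_unpaired == self.ML[i, j]:
                j -= 1
                continue
            hit = False
            for u in range(i + 1, j + 1):
                if (
                    self.ML[i, u - 1] < INF
                    and self.V[u, j] < INF
                    and self.ML[i, u - 1] + self.V[u, j] + p.multi_branch == self.ML[i, j]
                ):
                    self._pair(u, j)
                    j = u - 1
                    hit = True
                    break
            assert hit, "traceback failed in ML"


def fold(
    seq: str,
    params: FoldParams | None = None,
    *,
    min_len: int = 1,
) -> DotBracket:
    """Fold ``seq`` to its minimum-energy nested structure.

    Parameters
    ----------
    seq:
        RNA sequence (A/C/G/U).
    params:
        Energy tables; defaults to the shipped Turner-like set.
    min_len:
        Reject sequences shorter than this (precursor windows use 40).

    Returns the optimal :class:`DotBracket`; an unpairable sequence folds
    to the all-dot structure at energy 0.
    """
    params = params or DEFAULT_FOLD_PARAMS
    if len(seq) < min_len:
        raise ValueError(f"sequence of length {len(seq)} is below minimum {min_len}")
    s = encode(seq)
    V, ML, M1, W = _fold_tables(
        s,
        PAIR_TABLE,
        params.stack,
        params.hairpin,
        params.bulge,
        params.internal,
        np.int64(params.multi_close),
        np.int64(params.multi_branch),
        np.int64(params.multi_unpaired),
        np.int64(params.min_hairpin),
        np.int64(params.max_internal),
    )
    pairs = _Tracer(seq, V, ML, M1, W, params).run()
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return DotBracket("".join(structure), int(W[len(seq)]) / 100.0)
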