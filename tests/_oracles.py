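"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the package's dynamic programmes: structures are
enumerated exhaustively and scored by a free-standing loop-decomposition
evaluator; target alignments are enumerated by explicit gap placement.
They share only the tabulated energy constants (data, not algorithm).
"""

from __future__ import annotations

from mirforge.thermo import DEFAULT_FOLD_PARAMS, pair_type


# ---------------------------------------------------------------------------
# exhaustive secondary-structure enumeration
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All nested structures (tuples of 0-based pairs) over allowed pairs."""
    memo: dict[tuple[int, int], list[tuple]] = {}

    def go(i: int, j: int):
        if j - i + 1 <= 0:
            return [()]
        if (i, j) in memo:
            return memo[(i, j)]
        out = list(go(i + 1, j))  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            if pair_type(seq[i], seq[k]) >= 0:
                for inner in go(i + 1, k - 1):
                    for rest in go(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        memo[(i, j)] = out
        return out

    return go(0, len(seq) - 1)


def loop_decomposition_energy(seq: str, pairs) -> float:
    """Free-standing evaluator of a structure's energy (kcal/mol)."""
    p = DEFAULT_FOLD_PARAMS
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def direct_children(i: int, j: int):
        kids = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    total = 0
    for i, j in sorted(pairs):
        kids = direct_children(i, j)
        if not kids:
            total += int(p.hairpin[j - i - 1])
        elif len(kids) == 1:
            k, l = kids[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += int(p.stack[pair_type(seq[i], seq[j]), pair_type(seq[k], seq[l])])
            elif n1 == 0 or n2 == 0:
                total += int(p.bulge[n1 + n2])
            else:
                total += int(p.internal[n1 + n2])
        else:
            unpaired = (j - i - 1) - sum(l2 - k2 + 1 for k2, l2 in kids)
            total += p.multi_close + p.multi_branch * len(kids) + p.multi_unpaired * unpaired
    return total / 100.0


def brute_force_min_energy(seq: str) -> float:
    """Minimum energy over every enumerated structure (0 if none pairs)."""
    return min(
        loop_decomposition_energy(seq, list(s)) for s in enumerate_structures(seq)
    )


# ---------------------------------------------------------------------------
# exhaustive target-alignment search (total gap columns <= 1, the cap the
# default penalties imply: a second gap already exceeds the threshold)
# ---------------------------------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}


def _score_columns(cols, restricted_rows, params):
    """Penalty of an explicit column list, or None if a constraint fails."""
    penalty = 0.0
    mir_row = 0
    for a, b in cols:
        if a != "-":
            mir_row += 1
        restricted = a != "-" and restricted_rows[mir_row - 1]
        if a == "-" or b == "-":
            if restricted:
                return None
            penalty += params.gap_value
        elif (a, b) in _WC:
            pass
        elif (a, b) in _GU:
            if restricted:
                return None
            penalty += params.gu_value
        else:
            if restricted:
                return None
            penalty += params.mm_value
    return penalty


def brute_force_target_penalty(mirna: str, window: str, params):
    """Minimum qualifying penalty over all alignments, or None.

    Enumerates every start offset and every placement of at most one gap
    column (opposite either strand, internal only for gaps opposite the
    miRNA), scores the columns directly, and applies the minimum-length,
    restricted-position and threshold rules.
    """
    m = len(mirna)
    rm = mirna[::-1]
    restricted_rows = [
        (m - k) in params.no_mismatch_positions for k in range(m)
    ]
    candidates = []
    for start in range(len(window) + 1):
        # no gap
        if start + m <= len(window):
            cols = list(zip(rm, window[start : start + m]))
            candidates.append((cols, m))
        # one gap opposite the transcript: miRNA base k unopposed
        if start + m - 1 <= len(window):
            for k in range(m):
                sub = window[start : start + m - 1]
                cols, si = [], 0
                for r in range(m):
                    if r == k:
                        cols.append((rm[r], "-"))
                    else:
                        cols.append((rm[r], sub[si]))
                        si += 1
                candidates.append((cols, m))
        # one gap opposite the miRNA: extra transcript base between rows
        if start + m + 1 <= len(window):
            for pos in range(1, m):  # internal insertion points
                sub = window[start : start + m + 1]
                cols, si = [], 0
                for r in range(m):
                    if r == pos:
                        cols.append(("-", sub[si]))
                        si += 1
                    cols.append((rm[r], sub[si]))
                    si += 1
                candidates.append((cols, m + 1))
    best = None
    for cols, ncols in candidates:
        if ncols < params.min_length:
            continue
        pen = _score_columns(cols, restricted_rows, params)
        if pen is None or pen > params.score_threshold:
            continue
        if best is None or pen < best:
            best = pen
    return best
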