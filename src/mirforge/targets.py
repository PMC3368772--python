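"""Penalty-scored plant miRNA target prediction and cleavage-site calling.

A target site is an antiparallel complementarity alignment between a
miRNA (5'->3') and a transcript window, scored by accumulated penalties
(lower is better): ``mm_value`` per mismatch, ``gu_value`` per G:U wobble
and ``gap_value`` per gap column.  A site is reported when the optimal
alignment penalty is at or below ``score_threshold``, the alignment
spans at least ``min_length`` columns, and miRNA positions 10-11 (1-based
from the 5' end, the nucleotides flanking the canonical cleavage site)
are perfect Watson-Crick pairs.  Since every gap column costs
``gap_value``, alignments with more than ``floor(threshold/gap_value)``
gap columns can never pass, so the search is exact over that cap.

The predicted cleavage coordinate is the transcript position paired with
the 10th miRNA nucleotide, the canonical plant AGO1 slicer position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import NucSequence
from .thermo import BASE_CODE, ENERGY_MODEL_VERSION, duplex_stack_energy, is_watson_crick

_INF32 = np.int32(2**30)


@dataclass(frozen=True)
class TargetScoringParams:
    """Penalty weights (paper defaults for the conserved-miRNA preset)."""

    gap_value: float = 2.0
    mm_value: float = 1.0
    gu_value: float = 0.5
    score_threshold: float = 3.0
    min_length: int = 20
    no_mismatch_positions: frozenset[int] = frozenset({10, 11})

    def __post_init__(self) -> None:
        if min(self.gap_value, self.mm_value, self.gu_value) < 0:
            raise ValueError("penalties must be >= 0")
        if self.score_threshold < 0:
            raise ValueError("threshold must be >= 0")

    @property
    def max_gap_columns(self) -> int:
        if self.gap_value <= 0:
            return 2  # degenerate config: still bound the search
        return int(self.score_threshold // self.gap_value)


#: the two standard presets: the conserved-miRNA scan requires 20 aligned
#: columns, the novel-miRNA re-scan relaxes the minimum to 18
PRESETS = {
    "conserved": TargetScoringParams(min_length=20),
    "novel": TargetScoringParams(min_length=18),
}


@dataclass
class TargetSite:
    mirna_id: str
    mirna_seq: str  # 5'->3'
    transcript_id: str
    start: int  # 0-based half-open site span on the transcript
    end: int
    columns: list[tuple[str, str]]  # (miRNA base 3'->5' order, site base) per column
    penalty: float
    energy: float  # duplex stacking estimate, kcal/mol
    cleavage: int  # 1-based transcript coordinate opposite miRNA position 10
    energy_model: str = ENERGY_MODEL_VERSION

    @property
    def cleavage_mirna_position(self) -> int:
        """1-based miRNA position opposite the cleavage coordinate."""
        consumed_t = self.start
        consumed_m = 0
        m = len(self.mirna_seq)
        for a, b in self.columns:
            t_here = consumed_t + 1 if b != "-" else None
            if a != "-":
                consumed_m += 1
            if b != "-":
                consumed_t += 1
            if t_here == self.cleavage and a != "-":
                return m - consumed_m + 1
        raise ValueError("cleavage coordinate not inside the site")

    def alignment_text(self) -> str:
        """Report-style block: miRNA strand 3'->5' over the site 5'->3'."""
        top, mid, bot = [], [], []
        for a, b in self.columns:
            top.append(a)
            bot.append(b)
            if a == "-" or b == "-":
                mid.append(" ")
            elif is_watson_crick(a, b):
                mid.append(":")
            elif {a, b} == {"G", "U"}:
                mid.append(".")
            else:
                mid.append(" ")
        return (
            f"miRNA  3' {''.join(top)} 5'\n"
            f"          {''.join(mid)}\n"
            f"target 5' {''.join(bot)} 3'"
        )


@njit(cache=True)
def _scan_kernel(rm, t, wc, gu, restricted, mm_c, gu_c, gap_c, max_up, max_left):
    """Half-unit penalty DP.

    ``rm``: miRNA codes reversed (3'->5', i.e. column order along the
    site); ``restricted[k]`` flags rows that must be Watson-Crick paired.
    State: D[i, j, u, l] = best penalty having consumed i miRNA bases and
    the transcript prefix up to j, with u gap columns opposite the miRNA
    and l gap columns opposite the transcript.  Row 0 starts free at any
    j (sites may begin anywhere).
    """
    m = rm.shape[0]
    n = t.shape[0]
    D = np.full((m + 1, n + 1, max_up + 1, max_left + 1), _INF32, np.int32)
    for j in range(n + 1):
        D[0, j, 0, 0] = 0
    for i in range(m):
        for j in range(n + 1):
            for u in range(max_up + 1):
                for l in range(max_left + 1):
                    d = D[i, j, u, l]
                    if d >= _INF32:
                        continue
                    if j < n:
                        a = rm[i]
                        b = t[j]
                        if wc[a, b]:
                            c = 0
                        elif gu[a, b]:
                            c = -1 if restricted[i] else gu_c
                        else:
                            c = -1 if restricted[i] else mm_c
                        if c >= 0 and d + c < D[i + 1, j + 1, u, l]:
                            D[i + 1, j + 1, u, l] = d + c
                    # gap opposite the transcript (miRNA base unopposed)
                    if u + l < max_up and u < max_up and not restricted[i]:
                        if d + gap_c < D[i + 1, j, u + 1, l]:
                            D[i + 1, j, u + 1, l] = d + gap_c
                    # gap opposite the miRNA (transcript base unopposed);
                    # only internal (not before the first or after the
                    # last miRNA base)
                    if 0 < i < m and j < n and u + l < max_left and l < max_left:
                        if d + gap_c < D[i, j + 1, u, l + 1]:
                            D[i, j + 1, u, l + 1] = d + gap_c
    return D


def _half_units(params: TargetScoringParams) -> tuple[int, int, int, int]:
    vals = (params.mm_value, params.gu_value, params.gap_value, params.score_threshold)
    out = []
    for v in vals:
        h = round(v * 2)
        if abs(h - v * 2) > 1e-9:
            raise ValueError("penalties must be multiples of 0.5")
        out.append(int(h))
    return tuple(out)


def _tables():
    wc = np.zeros((4, 4), np.bool_)
    gu = np.zeros((4, 4), np.bool_)
    for a, b in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")):
        wc[BASE_CODE[a], BASE_CODE[b]] = True
    for a, b in (("G", "U"), ("U", "G")):
        gu[BASE_CODE[a], BASE_CODE[b]] = True
    return wc, gu


_WC, _GU = _tables()


def align_target(
    mirna: NucSequence,
    transcript: NucSequence,
    params: TargetScoringParams | None = None,
) -> list[TargetSite]:
    """All penalty-passing target sites of ``mirna`` on ``transcript``.

    Overlapping sites reduce to the minimum-penalty one (ties broken by
    lower duplex energy, then leftmost).
    """
    params = params or PRESETS["conserved"]
    m = len(mirna.seq)
    if not 17 <= m <= 27:
        raise ValueError(f"miRNA length {m} outside [17, 27]")
    mm_c, gu_c, gap_c, thr = _half_units(params)
    maxg = params.max_gap_columns
    rm = np.array([BASE_CODE[b] for b in mirna.seq[::-1]], np.int64)
    t = np.array([BASE_CODE[b] for b in transcript.seq], np.int64)
    restricted = np.zeros(m, np.bool_)
    for pos in params.no_mismatch_positions:
        if not 1 <= pos <= m:
            raise ValueError(f"restricted position {pos} outside the miRNA")
        restricted[m - pos] = True  # row k handles miRNA position m - k
    D = _scan_kernel(
        rm, t, _WC, _GU, restricted,
        np.int32(mm_c), np.int32(gu_c), np.int32(gap_c),
        np.int64(maxg), np.int64(maxg),
    )
    sites: list[TargetSite] = []
    for j in range(len(t) + 1):
        best = None
        for u in range(maxg + 1):
            for l in range(maxg + 1 - u):
                pen = int(D[m, j, u, l])
                if pen > thr or m + l < params.min_length:
                    continue
                if best is None or pen < best[0]:
                    best = (pen, u, l)
        if best is None:
            continue
        pen, u, l = best
        cols, start = _traceback(D, rm, t, j, u, l, restricted,
                                 mm_c, gu_c, gap_c, mirna.seq)
        site = _build_site(mirna, transcript, cols, start, j, pen / 2.0)
        sites.append(site)
    return _reduce(sites)


def _traceback(D, rm, t, j, u, l, restricted, mm_c, gu_c, gap_c, mirna_seq):
    m = rm.shape[0]
    i = m
    cols: list[tuple[str, str]] = []
    code_to_base = "ACGU"
    while i > 0:
        d = int(D[i, j, u, l])
        moved = False
        if i > 0 and j > 0:
            a, b = int(rm[i - 1]), int(t[j - 1])
            if _WC[a, b]:
                c = 0
            elif _GU[a, b]:
                c = -1 if restricted[i - 1] else gu_c
            else:
                c = -1 if restricted[i - 1] else mm_c
            if c >= 0 and int(D[i - 1, j - 1, u, l]) + c == d:
                cols.append((code_to_base[a], code_to_base[b]))
                i, j = i - 1, j - 1
                moved = True
        if not moved and i > 0 and u > 0 and not restricted[i - 1]:
            if int(D[i - 1, j, u - 1, l]) + gap_c == d:
                cols.append((code_to_base[int(rm[i - 1])], "-"))
                i, u = i - 1, u - 1
                moved = True
        if not moved and 0 < i < m and j > 0 and l > 0:
            if int(D[i, j - 1, u, l - 1]) + gap_c == d:
                cols.append(("-", code_to_base[int(t[j - 1])]))
                j, l = j - 1, l - 1
                moved = True
        if not moved:
            raise AssertionError("target traceback failed")
    cols.reverse()
    start = j
    return cols, start


def _build_site(mirna, transcript, cols, start, end, penalty) -> TargetSite:
    m = len(mirna.seq)
    # transcript coordinate opposite miRNA position 10 (1-based)
    consumed_m = 0
    consumed_t = start
    cleavage = None
    for a, b in cols:
        if a != "-":
            consumed_m += 1
        if b != "-":
            consumed_t += 1
        if a != "-" and m - consumed_m + 1 == 10 and b != "-":
            cleavage = consumed_t
    if cleavage is None:
        raise ValueError("miRNA position 10 is not opposed in the alignment")
    return TargetSite(
        mirna_id=mirna.id,
        mirna_seq=mirna.seq,
        transcript_id=transcript.id,
        start=start,
        end=end,
        columns=cols,
        penalty=penalty,
        energy=duplex_stack_energy(cols),
        cleavage=cleavage,
    )


def _reduce(sites: list[TargetSite]) -> list[TargetSite]:
    kept: list[TargetSite] = []
    for site in sorted(sites, key=lambda s: (s.penalty, s.energy, s.start)):
        if any(
            s.transcript_id == site.transcript_id
            and s.start < site.end
            and site.start < s.end
            for s in kept
        ):
            continue
        kept.append(site)
    return sorted(kept, key=lambda s: (s.transcript_id, s.start))


def predict_cleavage(site: TargetSite) -> int:
    """1-based transcript coordinate of the predicted cleavage site.

    The cut falls opposite the canonical 10th nucleotide from the miRNA
    5' end; the coordinate always lies within the site span.
    """
    if not site.start < site.cleavage <= site.end:
        raise ValueError("cleavage outside the site span")
    return site.cleavage


def scan_transcripts(
    mirnas: list[NucSequence],
    transcripts: list[NucSequence],
    params: TargetScoringParams | None = None,
) -> list[TargetSite]:
    """Scan every miRNA against every transcript."""
    out: list[TargetSite] = []
    for mirna in mirnas:
        for tx in transcripts:
            out.extend(align_target(mirna, tx, params))
    return out
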