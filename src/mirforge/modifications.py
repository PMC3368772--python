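"""Post-transcriptional modification detection within miRNA families.

Two isoform signatures are recognised against a family's reference
mature: single-nucleotide substitutions (RNA-editing-like events, from
reads whose best placement has exactly one mismatch inside the reference
span) and the "-1+UU" isoform (5'-most nucleotide deleted, two uridines
appended at the 3' end).  Frequencies are percentages of all reads
assigned to the family, reported to 3 decimals as is conventional for
these tables (e.g. "G-A: 7.692%").
"""

from __future__ import annotations

from dataclasses import dataclass

from .families import FamilyAssignment, _best_placement


@dataclass
class ModificationEvent:
    family: str
    kind: str  # "substitution" | "minus1_UU"
    position: int | None  # 1-based along the reference mature
    ref_base: str | None
    obs_base: str | None
    supporting_reads: int
    frequency: float  # percent of all family reads, 3-decimal precision

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 100:
            raise ValueError("frequency out of (0, 100]")
        if self.kind == "substitution" and self.position is None:
            raise ValueError("substitution events carry a position")
        if self.kind == "minus1_UU" and self.position is not None:
            raise ValueError("minus1_UU events carry no position")

    @property
    def label(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref_base}-{self.obs_base}: {self.frequency:.3f}%"
        return f"-1+UU: {self.frequency:.3f}%"


def _round3(x: float) -> float:
    return float(f"{x:.3f}")


def detect_editing(
    family_reads: list[tuple[str, int]],
    reference_mature: str,
    family: str = "",
    min_support: int = 1,
) -> list[ModificationEvent]:
    """Substitution events among a family's reads, sorted by frequency.

    ``family_reads`` are (sequence, read count) pairs already assigned to
    the family; the total of their counts is the frequency denominator.
    Reads whose single mismatch falls in a 5'/3' extension beyond the
    reference are not editing candidates.
    """
    total = sum(count for _, count in family_reads)
    if total == 0:
        raise ValueError("family has zero reads")
    events: dict[tuple[int, str, str], int] = {}
    for seq, count in family_reads:
        placed = _best_placement(seq, reference_mature, max_mismatch=1)
        if placed is None:
            continue
        overlap, mm, offset = placed
        if mm != 1:
            continue
        lo = max(0, offset)
        hi = min(len(reference_mature), offset + len(seq))
        diff = [
            k for k in range(lo, hi) if seq[k - offset] != reference_mature[k]
        ]
        if len(diff) != 1:
            continue  # the mismatch lies outside the reference span
        pos = diff[0]
        key = (pos + 1, reference_mature[pos], seq[pos - offset])
        events[key] = events.get(key, 0) + count
    out = [
        ModificationEvent(
            family, "substitution", pos, ref, obs, n,
            _round3(100.0 * n / total),
        )
        for (pos, ref, obs), n in events.items()
        if n >= min_support
    ]
    out.sort(key=lambda e: (-e.frequency, e.position or 0, e.obs_base or ""))
    return out


def detect_minus1_UU(read: str, reference_mature: str) -> bool:
    """True iff ``read`` is the reference minus its 5' base, plus 3' "UU"."""
    return read == reference_mature[1:] + "UU"


def detect_family_modifications(
    family: str,
    family_reads: list[tuple[str, int]],
    reference_mature: str,
    min_support: int = 1,
) -> list[ModificationEvent]:
    """Substitution and -1+UU events for one family."""
    events = detect_editing(family_reads, reference_mature, family, min_support)
    total = sum(count for _, count in family_reads)
    uu = sum(
        count for seq, count in family_reads if detect_minus1_UU(seq, reference_mature)
    )
    if uu >= min_support and uu > 0:
        events.append(
            ModificationEvent(
                family, "minus1_UU", None, None, None, uu,
                _round3(100.0 * uu / total),
            )
        )
    return events
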