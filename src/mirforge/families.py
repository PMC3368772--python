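"""Assignment of reads to known miRNA families and per-family profiles.

A read joins a family when it has an ungapped, same-strand placement
against a reference mature with overlap >= 19 nt and at most one
substitution inside the overlap.  Offsets may run past either reference
end, so 3' extensions (the 23-27 nt lmiRNA class) and 5'-shifted isomiRs
are captured as long as the overlap rule holds.  The best placement
maximises overlap, then minimises mismatches; ties between families are
broken lexicographically by family name and logged, unless the families
are declared synonyms (e.g. miR159/319) and merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import NucSequence
from .preprocess import CollapsedLibrary

logger = logging.getLogger("mirforge.families")

#: family pairs the literature treats as one (near-identical matures)
DEFAULT_SYNONYM_GROUPS: tuple[tuple[str, ...], ...] = ()

SHORT_CLASS = (20, 22)  # canonical mature lengths
LONG_CLASS = (23, 27)  # lmiRNA lengths


@dataclass(frozen=True)
class FamilyAssignment:
    read: str
    family: str
    reference_id: str
    overlap: int
    mismatches: int
    offset: int  # read start relative to the reference 5' end (may be < 0)

    def __post_init__(self) -> None:
        if self.overlap < 1 or self.mismatches not in (0, 1):
            raise ValueError("invalid assignment")


@dataclass
class FamilyProfile:
    family: str
    total_reads: int
    unique_sequences: int
    length_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def dominant_length(self) -> int:
        # ties resolve to the shorter length
        return min(
            self.length_histogram,
            key=lambda ln: (-self.length_histogram[ln], ln),
        )

    @property
    def size_class(self) -> str:
        d = self.dominant_length
        if SHORT_CLASS[0] <= d <= SHORT_CLASS[1]:
            return "short"
        if LONG_CLASS[0] <= d <= LONG_CLASS[1]:
            return "long"
        return "other"


def _best_placement(
    read: str,
    ref: str,
    min_overlap: int = 1,
    max_mismatch: int | None = None,
) -> tuple[int, int, int] | None:
    """(overlap, mismatches, offset) of the best qualifying placement.

    Only placements with overlap >= ``min_overlap`` and (when given)
    mismatches <= ``max_mismatch`` compete; among them overlap is
    maximised, then mismatches minimised, then the smallest offset wins.
    """
    best: tuple[int, int, int] | None = None
    for offset in range(-len(read) + 1, len(ref)):
        lo = max(0, offset)
        hi = min(len(ref), offset + len(read))
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mm = sum(
            1 for k in range(lo, hi) if read[k - offset] != ref[k]
        )
        if max_mismatch is not None and mm > max_mismatch:
            continue
        cand = (overlap, mm, offset)
        if best is None or (-cand[0], cand[1], cand[2]) < (-best[0], best[1], best[2]):
            best = cand
    return best


def _merge_map(groups: tuple[tuple[str, ...], ...]) -> dict[str, str]:
    merged = {}
    for group in groups:
        name = "/".join(sorted(group))
        for fam in group:
            merged[fam] = name
    return merged


def assign_family(
    read: str,
    mature_db: list[NucSequence],
    min_overlap: int = 19,
    max_mismatch: int = 1,
    synonym_groups: tuple[tuple[str, ...], ...] = DEFAULT_SYNONYM_GROUPS,
) -> FamilyAssignment | None:
    """Best family assignment for ``read``, or ``None`` below the rules.

    ``mature_db`` records must carry a ``family=`` tag in their FASTA
    description.
    """
    merged = _merge_map(synonym_groups)
    candidates: list[FamilyAssignment] = []
    for ref in mature_db:
        family = merged.get(ref.meta["family"], ref.meta["family"])
        placed = _best_placement(read, ref.seq, min_overlap, max_mismatch)
        if placed is None:
            continue
        overlap, mm, offset = placed
        candidates.append(
            FamilyAssignment(read, family, ref.id, overlap, mm, offset)
        )
    if not candidates:
        return None
    candidates.sort(key=lambda a: (-a.overlap, a.mismatches, a.family, a.reference_id))
    best = candidates[0]
    rivals = {
        a.family
        for a in candidates
        if (a.overlap, a.mismatches) == (best.overlap, best.mismatches)
    }
    if len(rivals) > 1:
        logger.info(
            "read %s ties between families %s; kept %s",
            read, sorted(rivals), best.family,
        )
    return best


def assign_library(
    library: CollapsedLibrary,
    mature_db: list[NucSequence],
    min_overlap: int = 19,
    max_mismatch: int = 1,
    synonym_groups: tuple[tuple[str, ...], ...] = DEFAULT_SYNONYM_GROUPS,
) -> dict[str, FamilyAssignment]:
    """Unique read -> best assignment, for every assignable library read."""
    out = {}
    for seq in library.entries:
        a = assign_family(seq, mature_db, min_overlap, max_mismatch, synonym_groups)
        if a is not None:
            out[seq] = a
    return out


def family_profile(
    assignments: dict[str, FamilyAssignment],
    library: CollapsedLibrary,
) -> list[FamilyProfile]:
    """Per-family abundance/length profiles, read counts from the library.

    Families with zero assigned reads do not appear.  Output is sorted by
    descending total reads, then name.
    """
    by_family: dict[str, FamilyProfile] = {}
    for seq, a in assignments.items():
        count = library.entries.get(seq)
        if count is None:
            raise KeyError(f"assigned read {seq!r} absent from library")
        prof = by_family.setdefault(a.family, FamilyProfile(a.family, 0, 0))
        prof.total_reads += count
        prof.unique_sequences += 1
        prof.length_histogram[len(seq)] = (
            prof.length_histogram.get(len(seq), 0) + count
        )
    return sorted(by_family.values(), key=lambda p: (-p.total_reads, p.family))
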