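"""Categorisation of unique small RNAs against an annotated reference set.

Replaces a BLASTN-vs-genome step with exact, oracle-testable matching:
every ungapped, full-length placement of a 17-32 nt query on either
strand of a reference record with at most ``max_mismatch`` substitutions
is a hit.  Matching is seed-and-extend (pigeonhole over ``max_mismatch+1``
query slices located with C-speed substring search), which is exhaustive
for substitution-only alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AnnotatedReference, CATEGORIES, reverse_complement
from .preprocess import CollapsedLibrary, ConfigError

#: tie precedence for multi-category hits; structural RNAs outrank mRNA so
#: degradation products do not mask annotations
CATEGORY_PRECEDENCE = (
    "miRNA",
    "tRNA",
    "rRNA",
    "sn/snoRNA",
    "ncRNA",
    "transposon",
    "pseudo mRNA",
    "coding mRNA",
)

NO_HIT = "no hit"
HIT_UNKNOWN = "hit, unknown"


@dataclass(frozen=True)
class Hit:
    record_id: str
    offset: int  # 0-based on the plus strand of the record
    strand: str  # "+" or "-"
    mismatches: int


@dataclass
class CategoryCall:
    sequence: str
    category: str
    best_hit: str | None
    mismatches: int | None

    def __post_init__(self) -> None:
        if (self.category == NO_HIT) != (self.best_hit is None):
            raise ValueError("'no hit' iff best_hit is None")


def _scan(query: str, target: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(offset, mismatches) of all <=max_mismatch ungapped placements."""
    m, n = len(query), len(target)
    if m > n:
        return []
    hits: dict[int, int] = {}
    parts = max_mismatch + 1
    step = m // parts
    for p in range(parts):
        lo = p * step
        hi = (p + 1) * step if p < parts - 1 else m
        seed = query[lo:hi]
        pos = target.find(seed)
        while pos != -1:
            off = pos - lo
            if 0 <= off <= n - m and off not in hits:
                mm = sum(1 for a, b in zip(query, target[off : off + m]) if a != b)
                if mm <= max_mismatch:
                    hits[off] = mm
            pos = target.find(seed, pos + 1)
    return sorted(hits.items())


def match_reference(
    query: str, reference: AnnotatedReference, max_mismatch: int = 1
) -> list[Hit]:
    """All ungapped full-length hits of ``query`` on both reference strands."""
    if not reference.records:
        raise ConfigError("reference set is empty")
    if len(query) < 17:
        raise ValueError("queries shorter than 17 nt are not categorised")
    hits: list[Hit] = []
    for rec in reference.records:
        for off, mm in _scan(query, rec.seq, max_mismatch):
            hits.append(Hit(rec.id, off, "+", mm))
        rc = reverse_complement(rec.seq)
        for off, mm in _scan(query, rc, max_mismatch):
            # report the plus-strand offset of the matched window
            hits.append(Hit(rec.id, len(rec.seq) - off - len(query), "-", mm))
    return hits


def categorize(
    query: str, hits: list[Hit], reference: AnnotatedReference
) -> CategoryCall:
    """Resolve hits to a single category by mismatches then fixed precedence."""
    if not hits:
        return CategoryCall(query, NO_HIT, None, None)
    cats = {rec.id: rec.meta.get("category") for rec in reference.records}
    best_mm = min(h.mismatches for h in hits)
    best = [h for h in hits if h.mismatches == best_mm]
    labelled = [h for h in best if cats.get(h.record_id) is not None]
    if not labelled:
        h = best[0]
        return CategoryCall(query, HIT_UNKNOWN, h.record_id, h.mismatches)
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    top = min(labelled, key=lambda h: (rank[cats[h.record_id]], h.record_id))
    return CategoryCall(query, cats[top.record_id], top.record_id, top.mismatches)


def classify_library(
    library: CollapsedLibrary,
    reference: AnnotatedReference,
    max_mismatch: int = 1,
) -> list[CategoryCall]:
    """One :class:`CategoryCall` per unique sequence in the library."""
    return [
        categorize(seq, match_reference(seq, reference, max_mismatch), reference)
        for seq in library.entries
    ]


def category_summary(calls: list[CategoryCall]) -> dict[str, int]:
    """Category -> unique-sequence count, over the full closed vocabulary.

    Together with "no hit" and "hit, unknown" these partition the unique
    read set.
    """
    counts = {NO_HIT: 0, HIT_UNKNOWN: 0, **{c: 0 for c in CATEGORIES}}
    for call in calls:
        counts[call.category] += 1
    return counts
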