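"""Adapter trimming, length filtering and read collapsing.

Trimming removes the 3' sequencing adapter by the leftmost suffix/prefix
overlap: the read suffix starting at the leftmost position that matches a
prefix of the adapter over at least ``min_clip`` nucleotides (or runs into
the full adapter) is clipped off.  Reads with no adapter evidence are
rejected by default; inserts are then kept if their length falls in the
retention window (17-32 nt by default, the observed small-RNA range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import NucSequence, normalize_rna


class ConfigError(ValueError):
    pass


@dataclass
class CollapsedLibrary:
    """Unique insert sequences with read counts.

    ``length_histogram`` maps insert length -> (unique sequences, reads).
    """

    entries: dict[str, int] = field(default_factory=dict)
    total_raw: int = 0
    total_clean: int = 0

    @property
    def length_histogram(self) -> dict[int, tuple[int, int]]:
        hist: dict[int, tuple[int, int]] = {}
        for seq, count in self.entries.items():
            u, r = hist.get(len(seq), (0, 0))
            hist[len(seq)] = (u + 1, r + count)
        return dict(sorted(hist.items()))

    @property
    def unique_count(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        if sum(self.entries.values()) != self.total_clean:
            raise ValueError("counts do not sum to total_clean")
        if self.total_clean > self.total_raw:
            raise ValueError("total_clean exceeds total_raw")


def trim_adapter(
    read: NucSequence,
    adapter3: str,
    min_clip: int = 6,
    max_mismatch: int = 0,
    keep_untrimmed: bool = False,
) -> NucSequence | None:
    """Clip the 3' adapter from a read; ``None`` means the read is rejected.

    The clip point is the leftmost read position from which the remaining
    read suffix matches the start of the adapter over >= ``min_clip``
    bases with at most ``max_mismatch`` substitutions (0 by default).
    Where the adapter is fully contained, everything from its first base
    onward is removed, so the longest insert-removal wins among equal
    anchors.  Reads showing no adapter are dropped unless
    ``keep_untrimmed`` is set.
    """
    adapter3 = normalize_rna(adapter3)
    if len(adapter3) < min_clip:
        raise ConfigError(
            f"adapter of length {len(adapter3)} is shorter than min_clip={min_clip}"
        )
    seq = read.seq
    for start in range(0, len(seq) - min_clip + 1):
        overlap = min(len(seq) - start, len(adapter3))
        if overlap < min_clip:
            break
        mismatches = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter3) if a != b
        )
        if mismatches <= max_mismatch:
            if start == 0:
                return None  # adapter dimer, no insert
            return NucSequence(read.id, seq[:start], dict(read.meta))
    return read if keep_untrimmed else None


def filter_length(seq: str, min_len: int = 17, max_len: int = 32) -> bool:
    """Keep iff ``min_len <= len(seq) <= max_len``."""
    if min_len > max_len:
        raise ConfigError("min_len exceeds max_len")
    return min_len <= len(seq) <= max_len


def mean_quality_ok(read: NucSequence, min_mean_q: float | None) -> bool:
    if min_mean_q is None:
        return True
    quals = read.meta.get("qual")
    if not quals:
        return True
    return sum(quals) / len(quals) >= min_mean_q


def collapse(reads: Iterable[str], total_raw: int | None = None) -> CollapsedLibrary:
    """Collapse clean insert sequences into a counted unique-sequence library."""
    lib = CollapsedLibrary()
    n = 0
    for seq in reads:
        n += 1
        lib.entries[seq] = lib.entries.get(seq, 0) + 1
    lib.total_clean = n
    lib.total_raw = total_raw if total_raw is not None else n
    lib.validate()
    return lib


def preprocess_reads(
    reads: Iterable[NucSequence],
    adapter3: str,
    min_clip: int = 6,
    min_len: int = 17,
    max_len: int = 32,
    max_mismatch: int = 0,
    keep_untrimmed: bool = False,
    min_mean_quality: float | None = None,
) -> tuple[CollapsedLibrary, dict[str, int]]:
    """Run trim -> length filter -> collapse; returns (library, drop log)."""
    log = {"raw": 0, "no_adapter": 0, "low_quality": 0, "length": 0, "clean": 0}
    clean: list[str] = []
    for read in reads:
        log["raw"] += 1
        if not mean_quality_ok(read, min_mean_quality):
            log["low_quality"] += 1
            continue
        trimmed = trim_adapter(
            read, adapter3, min_clip=min_clip, max_mismatch=max_mismatch,
            keep_untrimmed=keep_untrimmed,
        )
        if trimmed is None:
            log["no_adapter"] += 1
            continue
        if not filter_length(trimmed.seq, min_len, max_len):
            log["length"] += 1
            continue
        clean.append(trimmed.seq)
        log["clean"] += 1
    return collapse(clean, total_raw=log["raw"]), log
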