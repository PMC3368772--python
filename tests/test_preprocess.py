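import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirforge.io_formats import NucSequence
from mirforge.preprocess import (
    ConfigError,
    collapse,
    filter_length,
    preprocess_reads,
    trim_adapter,
)

ADAPTER = "UCGUAUGCCGUCUUCUGCUUGU"


def read(seq):
    return NucSequence("r", seq)


class TestTrimAdapter:
    def test_clips_full_adapter_prefix(self):
        insert = "UUGACAGAAGAUAGAGAGC"
        out = trim_adapter(read(insert + ADAPTER[:6]), ADAPTER, min_clip=6)
        assert out is not None and out.seq == insert

    def test_partial_overlap_below_min_clip_is_no_evidence(self):
        # 5 adapter bases at the 3' end do not qualify with min_clip 6
        insert = "UUGACAGAAGAUAGAGAGC"
        assert trim_adapter(read(insert + ADAPTER[:5]), ADAPTER, min_clip=6) is None
        kept = trim_adapter(
            read(insert + ADAPTER[:5]), ADAPTER, min_clip=6, keep_untrimmed=True
        )
        assert kept is not None and kept.seq == insert + ADAPTER[:5]

    def test_leftmost_occurrence_wins(self):
        # adapter occurs twice: trimming at the leftmost match removes the
        # longest tail, matching a brute-force scan over all clip points
        insert = "ACGUACGUACGUACGUA"
        seq = insert + ADAPTER + "ACAC" + ADAPTER[:8]
        out = trim_adapter(read(seq), ADAPTER, min_clip=6)
        # brute-force: leftmost start whose suffix matches an adapter prefix
        expected = None
        for start in range(len(seq)):
            tail = seq[start:]
            n = min(len(tail), len(ADAPTER))
            if n >= 6 and tail[:n] == ADAPTER[:n]:
                expected = seq[:start]
                break
        assert out is not None and out.seq == expected == insert

    def test_adapter_dimer_rejected(self):
        assert trim_adapter(read(ADAPTER), ADAPTER, min_clip=6) is None

    def test_adapter_shorter_than_min_clip_is_config_error(self):
        with pytest.raises(ConfigError):
            trim_adapter(read("ACGUACGU"), "ACGU", min_clip=6)

    @given(st.text(alphabet="ACGU", min_size=10, max_size=60))
    def test_trimming_never_lengthens(self, seq):
        out = trim_adapter(read(seq), ADAPTER, min_clip=6, keep_untrimmed=True)
        assert out is not None and len(out.seq) <= len(seq)


@pytest.mark.parametrize(
    "length,kept", [(16, False), (17, True), (32, True), (33, False)]
)
def test_filter_length_boundaries(length, kept):
    assert filter_length("A" * length) is kept


class TestCollapse:
    def test_counts_and_totals(self):
        s1, s2 = "ACGUACGUACGUACGUA", "GGGGACGUACGUACGUA"
        lib = collapse([s1, s1, s2])
        assert lib.entries == {s1: 2, s2: 1}
        assert lib.total_clean == 3

    def test_empty_input(self):
        lib = collapse([])
        assert lib.entries == {} and lib.total_clean == 0

    def test_count_conservation_at_scale(self):
        rng = random.Random(99)
        pool = ["".join(rng.choice("ACGU") for _ in range(21)) for _ in range(500)]
        reads = [rng.choice(pool) for _ in range(100_000)]
        lib = collapse(reads)
        assert sum(lib.entries.values()) == 100_000
        hist = lib.length_histogram
        assert sum(r for _, r in hist.values()) == 100_000


@given(
    st.lists(
        st.text(alphabet="ACGU", min_size=12, max_size=40), max_size=60
    )
)
def test_pipeline_count_conservation(seqs):
    """clean + dropped == raw for arbitrary read sets."""
    reads = [NucSequence(f"r{i}", s + ADAPTER) for i, s in enumerate(seqs)]
    lib, log = preprocess_reads(reads, ADAPTER)
    assert log["raw"] == len(seqs)
    assert log["clean"] + log["no_adapter"] + log["length"] == log["raw"]
    assert sum(lib.entries.values()) == log["clean"] == lib.total_clean


def test_filtering_order_independent_of_collapse():
    seqs = ["ACGU" * 5, "ACGU" * 4 + "A", "AC" * 4, "GU" * 20]
    filtered_then_collapsed = collapse([s for s in seqs if filter_length(s)])
    collapsed = collapse(seqs)
    survivors = {
        s: c for s, c in collapsed.entries.items() if filter_length(s)
    }
    assert filtered_then_collapsed.entries == survivors
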