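import random

import pytest

from mirforge.annotate import (
    HIT_UNKNOWN,
    NO_HIT,
    categorize,
    category_summary,
    classify_library,
    match_reference,
)
from mirforge.io_formats import AnnotatedReference, NucSequence, reverse_complement
from mirforge.preprocess import ConfigError, collapse


def make_ref(*records):
    return AnnotatedReference(list(records))


def brute_force_hits(query, record, max_mismatch):
    """Scan every window on both strands, counting substitutions."""
    hits = []
    for strand, seq in (("+", record.seq), ("-", reverse_complement(record.seq))):
        for off in range(len(seq) - len(query) + 1):
            mm = sum(1 for a, b in zip(query, seq[off : off + len(query)]) if a != b)
            if mm <= max_mismatch:
                plus_off = off if strand == "+" else len(seq) - off - len(query)
                hits.append((record.id, plus_off, strand, mm))
    return sorted(hits)


def test_exact_substring_hit_with_zero_mismatches(rng):
    body = "".join(rng.choice("ACGU") for _ in range(200))
    query = body[50:71]
    ref = make_ref(NucSequence("m1", body, {"category": "coding mRNA"}))
    hits = match_reference(query, ref, max_mismatch=1)
    assert any(h.offset == 50 and h.strand == "+" and h.mismatches == 0 for h in hits)


def test_reverse_complement_hits_minus_strand(rng):
    body = "".join(rng.choice("ACGU") for _ in range(200))
    query = reverse_complement(body[30:51])
    ref = make_ref(NucSequence("m1", body, {"category": "coding mRNA"}))
    hits = match_reference(query, ref, max_mismatch=0)
    assert any(h.strand == "-" and h.offset == 30 for h in hits)


def test_matches_equal_brute_force_scan(rng):
    record = NucSequence(
        "m1", "".join(rng.choice("ACGU") for _ in range(300)),
        {"category": "coding mRNA"},
    )
    ref = make_ref(record)
    for _ in range(40):
        if rng.random() < 0.5:
            start = rng.randrange(0, 280)
            query = list(record.seq[start : start + 20])
            for _ in range(rng.randrange(0, 3)):  # plant 0-2 substitutions
                pos = rng.randrange(20)
                query[pos] = rng.choice("ACGU")
            query = "".join(query)
        else:
            query = "".join(rng.choice("ACGU") for _ in range(20))
        got = sorted(
            (h.record_id, h.offset, h.strand, h.mismatches)
            for h in match_reference(query, ref, max_mismatch=1)
        )
        assert got == brute_force_hits(query, record, 1)


def test_two_mismatches_everywhere_gives_no_hit(rng):
    body = "".join(rng.choice("ACGU") for _ in range(100))
    query = list(body[10:31])
    query[3] = {"A": "C", "C": "A", "G": "U", "U": "G"}[query[3]]
    query[15] = {"A": "C", "C": "A", "G": "U", "U": "G"}[query[15]]
    query = "".join(query)
    ref = make_ref(NucSequence("m1", body, {"category": "coding mRNA"}))
    if brute_force_hits(query, ref.records[0], 1):
        pytest.skip("random sequence happened to rescue the query")
    assert match_reference(query, ref, max_mismatch=1) == []


def test_empty_reference_is_config_error():
    with pytest.raises(ConfigError):
        match_reference("A" * 21, AnnotatedReference([]), 1)


def test_precedence_mirna_beats_mrna(rng):
    seq = "".join(rng.choice("ACGU") for _ in range(21))
    ref = make_ref(
        NucSequence("mrna", seq, {"category": "coding mRNA"}),
        NucSequence("mir", seq, {"category": "miRNA"}),
    )
    call = categorize(seq, match_reference(seq, ref, 1), ref)
    assert call.category == "miRNA"


def test_no_hits_yields_no_hit_call():
    ref = make_ref(NucSequence("m1", "A" * 100, {"category": "coding mRNA"}))
    call = categorize("GC" * 10 + "G", [], ref)
    assert call.category == NO_HIT and call.best_hit is None


def test_uncategorized_record_yields_hit_unknown(rng):
    seq = "".join(rng.choice("ACGU") for _ in range(21))
    ref = make_ref(NucSequence("anon", seq))
    call = categorize(seq, match_reference(seq, ref, 1), ref)
    assert call.category == HIT_UNKNOWN and call.best_hit == "anon"


def test_category_counts_match_planted_truth_and_partition(rng):
    # disjoint per-category references; every query from exactly one
    cats = ["rRNA", "tRNA", "transposon", "coding mRNA"]
    records, queries, planted = [], [], {c: 0 for c in cats}
    for i, cat in enumerate(cats):
        body = "".join(rng.choice("ACGU") for _ in range(400))
        records.append(NucSequence(f"ref{i}", body, {"category": cat}))
        for k in range(5):
            queries.append(body[20 * k : 20 * k + 20])
            planted[cat] += 1
    queries.append("ACGU" * 5)  # likely no hit
    ref = make_ref(*records)
    lib = collapse(queries)
    calls = classify_library(lib, ref, max_mismatch=0)
    summary = category_summary(calls)
    assert sum(summary.values()) == lib.unique_count
    for cat in cats:
        assert summary[cat] == planted[cat]


def test_lowering_max_mismatch_never_adds_hits(rng):
    record = NucSequence(
        "m1", "".join(rng.choice("ACGU") for _ in range(200)),
        {"category": "coding mRNA"},
    )
    ref = make_ref(record)
    for _ in range(25):
        query = "".join(rng.choice("ACGU") for _ in range(18))
        h0 = match_reference(query, ref, max_mismatch=0)
        h1 = match_reference(query, ref, max_mismatch=1)
        assert len(h0) <= len(h1)
        assert {(h.record_id, h.offset, h.strand) for h in h0} <= {
            (h.record_id, h.offset, h.strand) for h in h1
        }
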