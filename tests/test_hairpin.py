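import random

import pytest

from mirforge.fold import fold
from mirforge.hairpin import (
    HairpinCandidate,
    PrecursorRules,
    RuleViolation,
    classify_precursor,
    find_precursors,
    map_read_stack,
    predict_star,
    validate_candidate,
)
from mirforge.io_formats import DotBracket, NucSequence, reverse_complement
from mirforge.simulate import _embed, build_hairpin


def _mature(rng, n=21, gc=0.6):
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AU") for _ in range(n)
    )


class TestPredictStar:
    def test_perfect_duplex_star_is_offset_reverse_complement(self):
        # mature[0:21] + 8-nt loop + exact reverse complement
        m = 21
        structure = (
            "(" * m + "." * 8 + ")" * m
        )
        db = DotBracket(structure, -30.0)
        star = predict_star(db, (0, m))
        assert star == (m + 8 + 2, m + 8 + 2 + m)

    def test_bulged_star_arm_lengthens_star(self):
        # trace the pairing by hand: a 1-nt bulge on the star arm makes a
        # 21-nt mature pair across 22 star nucleotides
        m = 21
        left = "(" * m
        right = ")" * 10 + "." + ")" * 11
        db = DotBracket(left + "...." + right, -30.0)
        star = predict_star(db, (0, m))
        assert star[1] - star[0] == 22

    def test_star_disjoint_from_mature(self, rng):
        for _ in range(10):
            mature = _mature(rng)
            hp, m_span, _ = build_hairpin(mature, rng=rng)
            db = fold(hp)
            star = predict_star(db, m_span)
            assert star[1] <= m_span[0] or m_span[1] <= star[0]

    def test_fully_unpaired_mature_is_an_error(self):
        db = DotBracket("." * 40, 0.0)
        with pytest.raises(ValueError):
            predict_star(db, (5, 26))


class TestFindPrecursors:
    def test_planted_hairpin_recovered_exactly(self, rng):
        mature = _mature(rng)
        hp, m_span, _ = build_hairpin(mature, rng=rng)
        tx_seq, off = _embed(rng, 200, hp)
        cands = find_precursors(NucSequence("tx", tx_seq), mature)
        assert len(cands) == 1
        c = cands[0]
        assert c.mature_seq == mature
        assert c.window[0] + c.mature[0] == off + m_span[0]
        validate_candidate(c, PrecursorRules())  # independent re-check

    def test_eight_unpaired_duplex_nucleotides_rejected(self, rng):
        # four broken pairs leave 8 nt unpaired inside the duplex: over the
        # six allowed
        mature = _mature(rng, n=22, gc=0.8)
        hp, m_span, _ = build_hairpin(mature, rng=rng, star_mismatches=4)
        tx_seq, off = _embed(rng, 120, hp)
        assert find_precursors(NucSequence("tx", tx_seq), mature) == []

    def test_mature_in_terminal_loop_rejected(self, rng):
        mature = "".join(rng.choice("AAC") for _ in range(21))
        stem = "".join(rng.choice("GC") for _ in range(28))
        hp = stem + mature + reverse_complement(stem)
        tx_seq, _ = _embed(rng, 120, hp)
        assert find_precursors(NucSequence("tx", tx_seq), mature) == []

    def test_read_absent_from_transcript_is_an_error(self, rng):
        tx = NucSequence("tx", "".join(rng.choice("ACGU") for _ in range(300)))
        with pytest.raises(ValueError):
            find_precursors(tx, "G" * 21)

    def test_every_emitted_candidate_passes_the_validator(self, rng):
        rules = PrecursorRules()
        for _ in range(5):
            mature = _mature(rng)
            hp, *_ = build_hairpin(mature, loop_len=rng.choice((8, 14, 20)), rng=rng)
            tx_seq, _ = _embed(rng, 250, hp)
            for cand in find_precursors(NucSequence("tx", tx_seq), mature, rules):
                validate_candidate(cand, rules)


class TestValidator:
    def _candidate(self, rng, **kwargs):
        mature = _mature(rng)
        hp, m_span, _ = build_hairpin(mature, rng=rng)
        db = fold(hp)
        star = predict_star(db, m_span)
        defaults = dict(
            transcript_id="tx",
            window=(0, len(hp)),
            precursor_seq=hp,
            structure=db,
            energy=db.energy,
            mature=m_span,
            star=(max(0, star[0]), min(len(hp), star[1])),
            arm="5p",
            core_energy=db.energy,
        )
        defaults.update(kwargs)
        return HairpinCandidate(**defaults)

    def test_energy_rule_violation_named(self, rng):
        cand = self._candidate(rng, core_energy=-10.0)
        with pytest.raises(RuleViolation) as exc:
            validate_candidate(cand, PrecursorRules())
        assert exc.value.rule == "max_energy"

    def test_mature_length_rule(self, rng):
        cand = self._candidate(rng)
        with pytest.raises(RuleViolation) as exc:
            validate_candidate(cand, PrecursorRules(mature_len=(24, 27)))
        assert exc.value.rule == "mature_length"

    def test_unpaired_rule_flagged_specifically(self, rng):
        # the only broken rule on this construct is the duplex-unpaired cap
        mature = _mature(rng, n=22, gc=0.8)
        hp, m_span, _ = build_hairpin(mature, rng=rng, star_mismatches=4)
        db = fold(hp)
        star = predict_star(db, m_span)
        cand = HairpinCandidate(
            "tx", (0, len(hp)), hp, db, db.energy, m_span,
            (max(0, star[0]), min(len(hp), star[1])), "5p",
            core_energy=db.energy,
        )
        with pytest.raises(RuleViolation) as exc:
            validate_candidate(cand, PrecursorRules())
        assert exc.value.rule == "max_duplex_unpaired"


class TestClassify:
    def _candidate_with_stack(self, rng, reads):
        mature = _mature(rng)
        hp, m_span, s_span = build_hairpin(mature, rng=rng)
        (cand,) = find_precursors(
            NucSequence("tx", _embed(rng, 150, hp)[0]), mature
        )
        entries = {}
        for which, count in reads:
            if which == "mir":
                entries[cand.mature_seq] = count
            elif which == "star":
                entries[cand.star_seq] = count
            else:  # a read crossing the terminal loop
                off = cand.mature[1] - 3
                entries[cand.precursor_seq[off : off + 20]] = count
        return map_read_stack(cand, entries)

    def test_mir_and_star_only_is_class_1(self, rng):
        cand = self._candidate_with_stack(rng, [("mir", 10), ("star", 2)])
        assert classify_precursor(cand) == "1"

    def test_star_plus_lower_outside_is_class_2(self, rng):
        cand = self._candidate_with_stack(
            rng, [("mir", 10), ("star", 2), ("loop", 3)]
        )
        assert classify_precursor(cand) == "2"

    def test_multiple_mir_reads_only_is_class_3a(self, rng):
        cand = self._candidate_with_stack(rng, [("mir", 10)])
        assert classify_precursor(cand) == "3a"

    def test_single_read_is_class_3b(self, rng):
        cand = self._candidate_with_stack(rng, [("mir", 1)])
        assert classify_precursor(cand) == "3b"

    def test_lower_outside_without_star_is_class_4(self, rng):
        cand = self._candidate_with_stack(rng, [("mir", 5), ("loop", 3)])
        assert classify_precursor(cand) == "4"

    def test_dominant_outside_read_is_class_5(self, rng):
        cand = self._candidate_with_stack(rng, [("mir", 5), ("loop", 9)])
        assert classify_precursor(cand) == "5"

    def test_empty_stack_is_an_error(self, rng):
        mature = _mature(rng)
        hp, *_ = build_hairpin(mature, rng=rng)
        (cand,) = find_precursors(
            NucSequence("tx", _embed(rng, 150, hp)[0]), mature
        )
        with pytest.raises(ValueError):
            classify_precursor(cand)

    def test_class_labels_partition_all_read_configurations(self, rng):
        """Any non-empty stack containing the defining read gets exactly
        one label from the closed set."""
        labels = set()
        for _ in range(30):
            reads = [("mir", rng.randint(1, 20))]
            if rng.random() < 0.5:
                reads.append(("star", rng.randint(1, 5)))
            if rng.random() < 0.5:
                reads.append(("loop", rng.randint(1, 30)))
            cand = self._candidate_with_stack(rng, reads)
            labels.add(classify_precursor(cand))
        assert labels <= {"1", "2", "3a", "3b", "4", "5"}
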