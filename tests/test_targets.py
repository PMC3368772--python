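import random

import pytest

from mirforge.io_formats import NucSequence, reverse_complement
from mirforge.targets import (
    PRESETS,
    TargetScoringParams,
    align_target,
    predict_cleavage,
)
from mirforge.thermo import duplex_stack_energy, is_watson_crick

from _oracles import brute_force_target_penalty

# Published strands of the experimentally validated miR156/Squamosa duplex:
# the miRNA strand is published 3'->5', the target site 5'->3'
MIR156_3TO5 = "CUACACGAGAGAGAGAAGACAGU"
SQUAMOSA_SITE = "GUUGUGCUCUCUCUCUUCUGUCA"


def mk(seq, name="m"):
    return NucSequence(name, seq)


def embed(site, rng, flank=60):
    left = "".join(rng.choice("ACGU") for _ in range(flank))
    right = "".join(rng.choice("ACGU") for _ in range(flank))
    return NucSequence("tx", left + site + right), flank


def validate_site(site, params):
    """Independent re-check of every reported-site constraint."""
    assert site.penalty <= params.score_threshold
    assert len(site.columns) >= params.min_length
    penalty = 0.0
    mir_pos = len(site.mirna_seq)
    for a, b in site.columns:
        if a == "-" or b == "-":
            penalty += params.gap_value
            if a != "-":
                mir_pos -= 1
            continue
        if is_watson_crick(a, b):
            pass
        elif {a, b} == {"G", "U"}:
            penalty += params.gu_value
        else:
            penalty += params.mm_value
        if mir_pos in params.no_mismatch_positions:
            assert is_watson_crick(a, b)
        mir_pos -= 1
    assert penalty == pytest.approx(site.penalty)
    assert site.start < site.cleavage <= site.end


class TestAlignTarget:
    def test_perfect_complement_scores_zero(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        tx, flank = embed(reverse_complement(mirna), rng)
        (site,) = align_target(mk(mirna), tx, PRESETS["conserved"])
        assert site.penalty == 0.0
        assert (site.start, site.end) == (flank, flank + 21)

    def test_single_wobble_costs_half(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        mirna = mirna[:4] + "G" + mirna[5:]  # ensure a G outside 10/11
        site_seq = list(reverse_complement(mirna))
        site_seq[21 - 5] = "U"  # G:U against miRNA position 5
        tx, _ = embed("".join(site_seq), rng)
        sites = align_target(mk(mirna), tx, PRESETS["conserved"])
        assert min(s.penalty for s in sites) == 0.5

    def test_published_mir156_squamosa_site_reported_at_oracle_penalty(self, rng):
        mirna = MIR156_3TO5[::-1]
        tx, flank = embed(SQUAMOSA_SITE, rng)
        params = PRESETS["conserved"]
        (site,) = align_target(mk(mirna, "HbmiR156"), tx, params)
        window = tx.seq[flank - 5 : flank + len(SQUAMOSA_SITE) + 5]
        assert site.penalty == brute_force_target_penalty(mirna, window, params)
        assert site.penalty == 1.0  # one mismatch opposite miRNA position 22

    def test_mismatch_at_position_ten_disqualifies(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        site_seq = list(reverse_complement(mirna))
        base = mirna[9]  # miRNA position 10
        site_seq[21 - 10] = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
        tx, flank = embed("".join(site_seq), rng)
        sites = align_target(mk(mirna), tx, PRESETS["conserved"])
        assert not any(s.start == flank and s.end == flank + 21 for s in sites)

    def test_mirna_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            align_target(mk("ACGU" * 4), mk("ACGU" * 30), PRESETS["conserved"])

    def test_raising_threshold_never_removes_sites(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        site_seq = list(reverse_complement(mirna))
        site_seq[3] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site_seq[3]]
        tx, _ = embed("".join(site_seq), rng)
        lo = align_target(mk(mirna), tx, TargetScoringParams(score_threshold=1.0))
        hi = align_target(mk(mirna), tx, TargetScoringParams(score_threshold=3.0))
        assert {(s.start, s.end) for s in lo} <= {(s.start, s.end) for s in hi}

    def test_optimal_penalty_matches_brute_force(self, rng):
        """DP penalties equal exhaustive gap-placement enumeration."""
        params = PRESETS["conserved"]
        for _ in range(60):
            m = rng.randint(20, 22)
            mirna = "".join(rng.choice("ACGU") for _ in range(m))
            if rng.random() < 0.6:
                window = list(reverse_complement(mirna))
                for _ in range(rng.randrange(0, 4)):
                    window[rng.randrange(len(window))] = rng.choice("ACGU")
                if rng.random() < 0.5:  # planted 1-nt bulge
                    window.insert(rng.randrange(1, len(window)), rng.choice("ACGU"))
                window = "".join(window) + "".join(
                    rng.choice("ACGU") for _ in range(6)
                )
            else:
                window = "".join(rng.choice("ACGU") for _ in range(30))
            oracle = brute_force_target_penalty(mirna, window, params)
            sites = align_target(mk(mirna), NucSequence("w", window), params)
            if oracle is None:
                assert sites == []
            else:
                assert sites and min(s.penalty for s in sites) == oracle
                for s in sites:
                    validate_site(s, params)


class TestDuplexEnergy:
    def test_fully_unpaired_alignment_is_zero(self):
        cols = [("A", "C"), ("A", "A"), ("C", "U")]
        assert duplex_stack_energy(cols) == 0.0

    def test_gc_duplex_more_stable_than_au(self):
        gc = [("G", "C"), ("C", "G")] * 10 + [("G", "C")]
        au = [("A", "U"), ("U", "A")] * 10 + [("A", "U")]
        assert duplex_stack_energy(gc) < duplex_stack_energy(au) < 0

    def test_extra_stacked_pair_never_raises_energy(self, rng):
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        for _ in range(20):
            strand = [rng.choice("ACGU") for _ in range(rng.randint(5, 15))]
            cols = [(a, comp[a]) for a in strand]
            extra = rng.choice("ACGU")
            assert (
                duplex_stack_energy(cols + [(extra, comp[extra])])
                <= duplex_stack_energy(cols)
            )


class TestCleavage:
    def test_cleavage_opposite_position_ten(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        tx, flank = embed(reverse_complement(mirna), rng, flank=100)
        (site,) = align_target(mk(mirna), tx, PRESETS["conserved"])
        # site spans transcript positions 101..121 (1-based); the base
        # opposite miRNA position 10 is the 10th from the site's 3' end
        assert predict_cleavage(site) == flank + 21 - 10 + 1
        assert site.cleavage_mirna_position == 10

    def test_published_mir156_duplex_cleaves_at_position_ten(self, rng):
        tx, _ = embed(SQUAMOSA_SITE, rng)
        (site,) = align_target(mk(MIR156_3TO5[::-1]), tx, PRESETS["conserved"])
        assert site.cleavage_mirna_position == 10

    def test_shifting_the_site_shifts_cleavage_equally(self, rng):
        mirna = "".join(rng.choice("ACGU") for _ in range(21))
        site_seq = reverse_complement(mirna)
        left = "".join(rng.choice("ACGU") for _ in range(50))
        right = "".join(rng.choice("ACGU") for _ in range(50))
        c1 = align_target(
            mk(mirna), NucSequence("a", left + site_seq + right),
            PRESETS["conserved"],
        )
        c2 = align_target(
            mk(mirna), NucSequence("b", left + "ACGUA" + site_seq + right),
            PRESETS["conserved"],
        )
        s1 = min(c1, key=lambda s: s.penalty)
        s2 = min(c2, key=lambda s: s.penalty)
        assert s2.cleavage - s1.cleavage == 5
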