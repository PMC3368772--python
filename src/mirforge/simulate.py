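"""Synthetic small-RNA studies with planted ground truth.

The generator emulates the statistical structure of a deeply sequenced
plant small-RNA library: 17-32 nt inserts behind a 3' adapter, a heavy
singleton/doubleton skew among unique background sequences (32% / 53% of
clean unique reads by default), family abundances spanning under 100 to
over 20,000 reads on a deterministic ladder (3 families > 20,000, 12
above the 1,000-read mark, 18 under 100 — the composition described for
the Hevea library), miRNA* at a small fraction of the mature, planted
RNA-editing and -1+UU isoforms at fixed rates, and degradation-fragment
background drawn as substrings of the transcripts.

Everything is driven by one integer seed and is bit-reproducible.
Planted items (precursors with a class scenario, rule-violating decoy
hairpins, target sites) are recorded in a serialisable ground truth.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

from .io_formats import NucSequence, reverse_complement

DEFAULT_ADAPTER = "UCGUAUGCCGUCUUCUGCUUGU"  # classic small-RNA 3' adapter

#: class scenarios cycled over planted precursors
DEFAULT_CLASS_PLAN = ("1", "2", "3a", "3b", "4", "5")


#: editing substitutions used when the observed base is left unspecified,
#: favouring the transitions the editing literature reports (G-A, A-U...)
AUTO_EDIT = {"G": "A", "A": "U", "C": "U", "U": "C"}


@dataclass
class EditingSpec:
    position: int  # 1-based along the mature
    rate: float  # fraction of family reads carrying the substitution
    alt: str | None = None  # observed base; None = pick via AUTO_EDIT


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_families: int = 48
    family_abundances: list[int] | None = None  # default: deterministic ladder
    singleton_fraction: float = 0.32
    doubleton_fraction: float = 0.53
    length_weights: dict[int, float] | None = None  # insert length -> weight
    n_planted_hairpins: int = 20
    n_decoy_hairpins: int = 20
    n_background_unique: int = 0  # degradation fragments (0 = noise off)
    editing: dict[int, EditingSpec] = field(default_factory=dict)  # family idx ->
    minus1_uu: dict[int, float] = field(default_factory=dict)  # family idx -> rate
    star_ratio: float = 0.05
    adapter: str = DEFAULT_ADAPTER
    transcript_len: int = 800
    mature_len_choices: tuple[int, ...] = (20, 21, 22)
    class_plan: tuple[str, ...] = DEFAULT_CLASS_PLAN

    def __post_init__(self) -> None:
        if not 0 <= self.singleton_fraction <= 1 or not 0 <= self.doubleton_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.singleton_fraction + self.doubleton_fraction > 1:
            raise ValueError("singleton + doubleton fractions exceed 1")
        for spec in self.editing.values():
            if not 0 < spec.rate < 1:
                raise ValueError("editing rates must lie in (0, 1)")


def default_abundance_ladder(n_families: int = 48) -> list[int]:
    """Deterministic per-family read counts emulating the library skew.

    3 families above 20,000 reads, 9 more above 1,000 (12 predominant in
    all), 18 between 100 and 1,000 and the rest below 100 reads.
    """
    ladder: list[int] = [25000, 22000, 21000]
    for k in range(9):
        ladder.append(int(18000 * (1200 / 18000) ** (k / 8)))
    for k in range(18):
        ladder.append(int(950 * (110 / 950) ** (k / 17)))
    while len(ladder) < n_families:
        k = len(ladder) - 30
        ladder.append(max(3, int(95 * (4 / 95) ** (k / max(1, n_families - 31)))))
    return ladder[:n_families]


DEFAULT_LENGTH_WEIGHTS = {
    17: 0.10, 18: 0.04, 19: 0.09, 20: 0.05, 21: 0.06, 22: 0.06,
    23: 0.07, 24: 0.16, 25: 0.07, 26: 0.08, 27: 0.14, 28: 0.03,
    29: 0.02, 30: 0.01, 31: 0.01, 32: 0.01,
}


@dataclass
class PlantedPrecursor:
    name: str
    transcript_id: str
    precursor_span: tuple[int, int]  # transcript coords, 0-based half-open
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    mature_seq: str
    star_seq: str
    true_class: str
    mature_count: int
    star_count: int
    outside_reads: list[tuple[str, int]] = field(default_factory=list)
    conserved_family: str | None = None


@dataclass
class PlantedDecoy:
    name: str
    transcript_id: str
    span: tuple[int, int]
    mature_seq: str
    violated_rule: str
    mature_count: int = 2


@dataclass
class PlantedTarget:
    mirna: str
    transcript_id: str
    span: tuple[int, int]
    expected_penalty: float
    kind: str  # perfect | wobble | mismatch | decoy


@dataclass
class GroundTruth:
    families: dict[str, dict] = field(default_factory=dict)
    precursors: list[PlantedPrecursor] = field(default_factory=list)
    decoys: list[PlantedDecoy] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    background: dict[str, int] = field(default_factory=dict)
    total_raw_reads: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AU") for _ in range(n)
    )


def _duplex_clears_ceiling(mature: str, ceiling: float = -30.0) -> bool:
    """True when the perfect mature:star helix is stable enough that the
    planted hairpin satisfies the precursor energy rule with headroom."""
    from .thermo import structure_energy

    hp = mature + "AAA" + reverse_complement(mature)
    pairs = [(i, len(hp) - 1 - i) for i in range(len(mature))]
    return structure_energy(hp, pairs) <= ceiling


def _draw_mature(
    rng: random.Random,
    lengths: tuple[int, ...],
    seen: set[str],
    foldable: bool = True,
) -> str:
    while True:
        mature = _rand_seq(rng, rng.choice(lengths), gc=0.55)
        if mature in seen:
            continue
        if foldable and not _duplex_clears_ceiling(mature):
            continue
        seen.add(mature)
        return mature


def _loop_seq(rng: random.Random, n: int) -> str:
    # A/C-only loops cannot pair internally under the allowed-pair set
    return "".join(rng.choice("AAC") for _ in range(n))


def build_hairpin(
    mature: str,
    loop_len: int = 14,
    ext_len: int = 30,
    rng: random.Random | None = None,
    star_mismatches: int = 0,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """A precursor sequence [ext][mature][loop][star arm][rc ext].

    Returns (sequence, mature span, star-arm block span); the true star
    (2-nt offset) lies inside the star-arm block.  ``star_mismatches``
    breaks that many duplex pairs by mutating spread-out star positions.
    """
    rng = rng or random.Random(0)
    ext = _rand_seq(rng, ext_len, gc=0.6)
    loop = _loop_seq(rng, loop_len)
    arm = list(reverse_complement(mature))
    if star_mismatches:
        step = max(1, len(arm) // (star_mismatches + 1))
        picked = [3 + k * step for k in range(star_mismatches)]
        for p in picked:
            original = arm[p % len(arm)]
            arm[p % len(arm)] = {"A": "C", "C": "A", "G": "A", "U": "C"}[original]
    seq = ext + mature + loop + "".join(arm) + reverse_complement(ext)
    ms = ext_len
    me = ms + len(mature)
    ss = me + loop_len
    return seq, (ms, me), (ss, ss + len(arm))


def _embed(rng: random.Random, flank_len: int, insert: str) -> tuple[str, int]:
    left = _rand_seq(rng, flank_len, gc=0.45)
    right = _rand_seq(rng, flank_len, gc=0.45)
    return left + insert + right, flank_len


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[NucSequence], list[NucSequence], GroundTruth]:
    """(transcripts, mature miRNA database, ground truth).

    Transcripts carry the planted precursor hairpins, the decoy hairpins
    (each engineered to break exactly one precursor rule) and the planted
    target sites; the mature database holds the conserved-family matures
    with ``family=`` tags.
    """
    rng = random.Random(config.seed)
    truth = GroundTruth()
    transcripts: list[NucSequence] = []

    abundances = config.family_abundances or default_abundance_ladder(
        config.n_families
    )
    if len(abundances) != config.n_families:
        raise ValueError("family_abundances length must equal n_families")

    mature_db: list[NucSequence] = []
    matures: list[str] = []
    seen: set[str] = set()
    for i in range(config.n_families):
        mature = _draw_mature(rng, config.mature_len_choices, seen)
        name = f"fam{i + 1:03d}"
        matures.append(mature)
        mature_db.append(
            NucSequence(f"mat_{name}", mature, {"family": name})
        )
        truth.families[name] = {
            "mature": mature,
            "abundance": abundances[i],
            "editing": [],
            "minus1_uu_count": 0,
        }

    # planted precursors: the first few defined by conserved-family matures,
    # the rest by novel matures absent from the database.  Classes needing
    # single-read or dominated defining reads (3b, 5) only fit novel loci,
    # whose read counts the generator controls directly.
    conserved_plan = tuple(c for c in config.class_plan if c not in ("3b", "5"))
    n_conserved = min(8, config.n_planted_hairpins)
    for k in range(config.n_planted_hairpins):
        if k < n_conserved:
            mature = matures[k]
            fam = f"fam{k + 1:03d}"
            cls = conserved_plan[k % len(conserved_plan)]
        else:
            mature = _draw_mature(rng, config.mature_len_choices, seen)
            fam = None
            cls = config.class_plan[(k - n_conserved) % len(config.class_plan)]
        loop_len = 20 if cls == "5" else 14
        hp, m_span, s_span = build_hairpin(mature, loop_len=loop_len, rng=rng)
        tx_seq, off = _embed(rng, (config.transcript_len - len(hp)) // 2, hp)
        tx_id = f"precursor_tx{k + 1:03d}"
        transcripts.append(NucSequence(tx_id, tx_seq))
        mature_count = (
            truth.families[fam]["abundance"] if fam else
            {"1": 40, "2": 30, "3a": 12, "3b": 1, "4": 15, "5": 5}[cls]
        )
        star_count = (
            max(1, round(config.star_ratio * mature_count))
            if cls in ("1", "2") else 0
        )
        # the predicted star (2-nt 3' overhangs): star-arm block shifted by 2
        star_seq = hp[s_span[0] + 2 : s_span[1] + 2]
        outside: list[tuple[str, int]] = []
        if cls in ("2", "4", "5"):
            # a read spanning the terminal loop: outside the miR/miR*
            # regions yet never a valid hairpin seed on its own
            o_start = m_span[1] - 3
            o_read = hp[o_start : o_start + loop_len + 6]
            o_count = mature_count * 2 if cls == "5" else max(1, mature_count // 3)
            outside.append((o_read, o_count))
        truth.precursors.append(
            PlantedPrecursor(
                name=f"hp{k + 1:03d}",
                transcript_id=tx_id,
                precursor_span=(off, off + len(hp)),
                mature_span=(off + m_span[0], off + m_span[1]),
                star_span=(off + s_span[0] + 2, off + s_span[1] + 2),
                mature_seq=mature,
                star_seq=star_seq,
                true_class=cls,
                mature_count=mature_count,
                star_count=star_count,
                outside_reads=outside,
                conserved_family=fam,
            )
        )

    # decoys: each breaks exactly one rule
    decoy_rules = ("max_energy", "max_duplex_unpaired", "distance", "mature_in_stem")
    for k in range(config.n_decoy_hairpins):
        rule = decoy_rules[k % len(decoy_rules)]
        while True:
            if rule == "max_energy":
                mature = _rand_seq(rng, 21, gc=0.0)  # AU-only: weak stem
            elif rule == "mature_in_stem":
                mature = "".join(
                    rng.choice("AAAC") for _ in range(21)
                )  # nothing to pair against a G/C stem
            elif rule == "max_duplex_unpaired":
                # GC-heavy 22-mer: the broken duplex still clears the
                # energy ceiling, so only the unpaired rule fails
                mature = _rand_seq(rng, 22, gc=0.8)
            else:
                mature = _rand_seq(rng, 21, gc=0.55)
            if mature not in seen:
                seen.add(mature)
                break
        if rule == "max_energy":
            hp, m_span, _ = build_hairpin(mature, loop_len=14, ext_len=0, rng=rng)
        elif rule == "max_duplex_unpaired":
            hp, m_span, _ = build_hairpin(
                mature, loop_len=14, ext_len=30, rng=rng, star_mismatches=4
            )
        elif rule == "distance":
            filler = _rand_seq(rng, 270, gc=0.3)
            hp = mature + filler + reverse_complement(mature)
            m_span = (0, len(mature))
        else:  # mature_in_stem: mature sits in the terminal loop
            stem = _rand_seq(rng, 28, gc=0.9)
            hp = stem + mature + reverse_complement(stem)
            m_span = (len(stem), len(stem) + len(mature))
        tx_seq, off = _embed(
            rng, max(60, (config.transcript_len - len(hp)) // 2), hp
        )
        tx_id = f"decoy_tx{k + 1:03d}"
        transcripts.append(NucSequence(tx_id, tx_seq))
        truth.decoys.append(
            PlantedDecoy(
                name=f"decoy{k + 1:03d}",
                transcript_id=tx_id,
                span=(off, off + len(hp)),
                mature_seq=mature,
                violated_rule=rule,
            )
        )

    # planted target sites on dedicated transcripts
    site_kinds = ("perfect", "wobble", "mismatch", "decoy")
    for k, kind in enumerate(site_kinds * 2):
        fam_idx = k % config.n_families
        mirna = matures[fam_idx]
        site = list(reverse_complement(mirna))
        m = len(mirna)
        expected = 0.0
        if kind == "wobble":
            # one G:U wobble outside the restricted positions 10-11
            pos = next(
                (
                    p
                    for p in range(3, m - 1)
                    if p not in (10, 11) and mirna[p - 1] in "GU"
                ),
                None,
            )
            if pos is None:
                continue  # no wobble constructible for this mature
            col = m - pos  # site runs 3'->5' of the miRNA
            site[col] = "U" if mirna[pos - 1] == "G" else "G"
            expected = 0.5
        elif kind == "mismatch":
            pos = 4
            col = m - pos
            base = mirna[pos - 1]
            site[col] = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
            expected = 1.0
        elif kind == "decoy":
            shuffled = site[:]
            rng.shuffle(shuffled)
            site = shuffled
            expected = float("nan")
        tx_seq, off = _embed(rng, 120, "".join(site))
        tx_id = f"target_tx{k + 1:03d}"
        transcripts.append(NucSequence(tx_id, tx_seq))
        truth.targets.append(
            PlantedTarget(
                mirna=f"fam{fam_idx + 1:03d}",
                transcript_id=tx_id,
                span=(off, off + len(site)),
                expected_penalty=expected,
                kind=kind,
            )
        )

    # dedicated degradation-background transcripts: fragments are sampled
    # only from these, so planted read stacks stay exactly as configured
    for k in range(6):
        transcripts.append(
            NucSequence(
                f"background_tx{k + 1:03d}",
                _rand_seq(rng, config.transcript_len, gc=0.45),
            )
        )

    return transcripts, mature_db, truth


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def generate_library(
    config: SyntheticConfig,
    transcripts: list[NucSequence],
    mature_db: list[NucSequence],
    truth: GroundTruth,
) -> list[NucSequence]:
    """Raw reads (inserts + 3' adapter) with counts recorded in ``truth``.

    Family reads are exact mature copies except for the planted editing
    and -1+UU isoforms, whose counts are the deterministic rounding of
    rate x abundance.  Background fragments are substrings of the
    transcripts that avoid every planted locus.
    """
    rng = random.Random(config.seed + 1)
    inserts: list[tuple[str, int]] = []

    precursor_matures = {p.mature_seq for p in truth.precursors}
    for i, (name, fam) in enumerate(truth.families.items()):
        n = fam["abundance"]
        mature = fam["mature"]
        edited = 0
        if i in config.editing:
            spec = config.editing[i]
            count = round(spec.rate * n)
            if count:
                pos = spec.position - 1
                alt = spec.alt or AUTO_EDIT[mature[pos]]
                if mature[pos] == alt:
                    raise ValueError("editing alt equals the reference base")
                var = mature[:pos] + alt + mature[pos + 1 :]
                inserts.append((var, count))
                fam["editing"].append(
                    {
                        "position": spec.position,
                        "ref": mature[pos],
                        "alt": alt,
                        "count": count,
                    }
                )
                edited += count
        uu = 0
        if i in config.minus1_uu:
            uu = round(config.minus1_uu[i] * n)
            if uu:
                inserts.append((mature[1:] + "UU", uu))
                fam["minus1_uu_count"] = uu
        remaining = n - edited - uu
        if remaining < 0:
            raise ValueError(f"family {name}: modification rates exceed 1")
        if mature not in precursor_matures or remaining > 0:
            inserts.append((mature, remaining))

    for p in truth.precursors:
        if p.conserved_family is None:
            inserts.append((p.mature_seq, p.mature_count))
        if p.star_count:
            inserts.append((p.star_seq, p.star_count))
        for seq, count in p.outside_reads:
            inserts.append((seq, count))
    for d in truth.decoys:
        inserts.append((d.mature_seq, d.mature_count))

    # degradation background: transcript substrings avoiding planted loci
    if config.n_background_unique:
        weights = config.length_weights or DEFAULT_LENGTH_WEIGHTS
        lengths = sorted(weights)
        wvals = [weights[ln] for ln in lengths]
        forbidden: dict[str, list[tuple[int, int]]] = {}
        for p in truth.precursors:
            forbidden.setdefault(p.transcript_id, []).append(p.precursor_span)
        for d in truth.decoys:
            forbidden.setdefault(d.transcript_id, []).append(d.span)
        planted_seqs = {s for s, _ in inserts}
        bg_pool = [
            tx for tx in transcripts if tx.id.startswith("background_tx")
        ] or transcripts
        n_bg = config.n_background_unique
        n_single = round(config.singleton_fraction * n_bg)
        n_double = round(config.doubleton_fraction * n_bg)
        made = 0
        attempts = 0
        while made < n_bg and attempts < n_bg * 50:
            attempts += 1
            tx = rng.choice(bg_pool)
            ln = rng.choices(lengths, weights=wvals, k=1)[0]
            if len(tx.seq) <= ln:
                continue
            start = rng.randrange(0, len(tx.seq) - ln)
            bad = any(
                start < e and s < start + ln
                for s, e in forbidden.get(tx.id, [])
            )
            if bad:
                continue
            frag = tx.seq[start : start + ln]
            if frag in planted_seqs or frag in truth.background:
                continue
            if made < n_single:
                count = 1
            elif made < n_single + n_double:
                count = 2
            else:
                count = rng.randint(3, 12)
            truth.background[frag] = count
            inserts.append((frag, count))
            made += 1

    reads: list[NucSequence] = []
    idx = 0
    for seq, count in inserts:
        for _ in range(count):
            idx += 1
            reads.append(
                NucSequence(f"read_{idx}", seq + config.adapter)
            )
    rng.shuffle(reads)
    truth.total_raw_reads = len(reads)
    return reads


def generate_study(config: SyntheticConfig):
    """Convenience wrapper: (reads, transcripts, mature_db, references, truth).

    ``references`` is the annotated reference set for categorisation: the
    transcripts labelled as coding mRNA, the mature database as miRNA,
    plus one synthetic record per structural-RNA category.
    """
    transcripts, mature_db, truth = generate_transcriptome(config)
    reads = generate_library(config, transcripts, mature_db, truth)
    rng = random.Random(config.seed + 2)
    references: list[NucSequence] = []
    for tx in transcripts:
        references.append(
            NucSequence(tx.id, tx.seq, {"category": "coding mRNA"})
        )
    for rec in mature_db:
        references.append(
            NucSequence(f"ref_{rec.id}", rec.seq, {"category": "miRNA"})
        )
    for cat, label in (
        ("rRNA", "rrna1"), ("tRNA", "trna1"), ("ncRNA", "ncrna1"),
        ("transposon", "te1"), ("pseudo mRNA", "pseudo1"), ("sn/snoRNA", "sno1"),
    ):
        references.append(
            NucSequence(label, _rand_seq(rng, 200, gc=0.5), {"category": cat})
        )
    return reads, transcripts, mature_db, references, truth
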