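"""Hairpin precursor discovery, miRNA* prediction and the class 1-5 taxonomy.

Discovery runs per defining read: windows around each exact read locus in
a transcript are folded, the stem-loop component enclosing the read is
extracted from the window structure, and the candidate survives only if
it satisfies the precursor rules — mature within the stated length range
and wholly inside one stem arm, hairpin free energy at or below the
energy ceiling (-25 kcal/mol by default), at most six nucleotides
unpaired within the miR:miR* duplex, and a miR-miR* distance of 5-240 nt.
The miRNA* is read off the structure with the canonical 2-nt 3'
overhangs.  Precursors are then classified 1-5 by how the sequenced read
stack distributes over the predicted miR/miR* regions versus elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .fold import MAX_FOLD_LEN, MIN_FOLD_LEN, fold
from .io_formats import DotBracket, NucSequence
from .thermo import DEFAULT_FOLD_PARAMS, FoldParams, structure_energy


@dataclass
class PrecursorRules:
    """Structural acceptance rules for a miRNA precursor."""

    mature_len: tuple[int, int] = (20, 22)
    max_energy: float = -25.0  # kcal/mol ceiling for the hairpin
    max_duplex_unpaired: int = 6
    distance: tuple[int, int] = (5, 240)  # nt between miR and miR*
    star_overhang: int = 2
    class_margin: int = 12  # per-side margin of the "25-bp region"

    def __post_init__(self) -> None:
        if self.max_energy >= 0:
            raise ValueError("energy ceiling must be negative")
        if min(self.mature_len) < 1 or min(self.distance) < 1:
            raise ValueError("bounds must be positive")


@dataclass
class HairpinCandidate:
    transcript_id: str
    window: tuple[int, int]  # precursor span on the transcript, 0-based half-open
    precursor_seq: str
    structure: DotBracket  # over the precursor span
    energy: float  # full precursor free energy, kcal/mol
    mature: tuple[int, int]  # precursor-relative, 0-based half-open
    star: tuple[int, int]
    arm: str  # "5p" | "3p"
    core_energy: float | None = None  # miR-through-miR* core hairpin energy
    precursor_class: str | None = None
    read_stack: list[tuple[str, int, int]] = field(default_factory=list)
    # (sequence, count, precursor-relative offset)

    @property
    def mature_seq(self) -> str:
        return self.precursor_seq[self.mature[0] : self.mature[1]]

    @property
    def star_seq(self) -> str:
        s, e = self.star
        return self.precursor_seq[max(0, s) : e]


class RuleViolation(ValueError):
    """Raised by the validator with the name of the violated rule."""

    def __init__(self, rule: str, detail: str = ""):
        self.rule = rule
        super().__init__(f"{rule}: {detail}" if detail else rule)


# ---------------------------------------------------------------------------
# star prediction
# ---------------------------------------------------------------------------

def _interpolated_partner(bp: dict[int, int], positions: range, forward: bool) -> int:
    """Partner of the first paired position scanning ``positions``, offset-
    corrected for unpaired (bulged) leading positions."""
    step = 1 if forward else -1
    for n_skipped, pos in enumerate(positions):
        if pos in bp:
            return bp[pos] + step * n_skipped
    raise ValueError("mature is fully unpaired")


def predict_star(
    structure: DotBracket,
    mature: tuple[int, int],
    overhang: int = 2,
) -> tuple[int, int]:
    """miRNA* coordinates for a mature within a hairpin structure.

    The star spans the positions pairing with the mature, shifted so both
    duplex ends carry ``overhang``-nt 3' overhangs; bulged mature
    positions are interpolated from the nearest paired neighbour.  For a
    perfect duplex this is the reverse-complement block offset by two.
    """
    bp = structure.partner_map()
    ms, me = mature
    if not any(p in bp for p in range(ms, me)):
        raise ValueError("mature is fully unpaired")
    # partner of (mature 3' end - overhang) marks the star 5' start;
    # partner of the mature 5' start plus overhang marks the star 3' end
    lo = _interpolated_partner(bp, range(me - 1 - overhang, ms - 1, -1), forward=False)
    hi = _interpolated_partner(bp, range(ms, me), forward=True)
    return (min(lo, hi + 1 + overhang), max(lo, hi + 1 + overhang))


def predict_star_checked(
    structure: DotBracket, mature: tuple[int, int], overhang: int = 2
) -> tuple[int, int]:
    star = predict_star(structure, mature, overhang)
    if not (star[1] <= mature[0] or mature[1] <= star[0]):
        raise ValueError("star overlaps the mature")
    return star


# ---------------------------------------------------------------------------
# structural checks
# ---------------------------------------------------------------------------

def _mature_arm(bp: dict[int, int], mature: tuple[int, int]) -> str | None:
    """"5p"/"3p" when every paired mature base points one way, else None."""
    partners = [bp[p] for p in range(*mature) if p in bp]
    if len(partners) < (mature[1] - mature[0]) // 2:
        return None  # mostly unpaired: not in a stem
    if all(q >= mature[1] for q in partners):
        return "5p"
    if all(q < mature[0] for q in partners):
        return "3p"
    return None


def _duplex_unpaired(
    bp: dict[int, int], mature: tuple[int, int], star: tuple[int, int]
) -> int:
    """Nucleotides of mature+star not paired to the opposite region,
    excluding the 2-nt 3' overhang allowances at the duplex ends."""
    ms, me = mature
    ss, se = star
    n = 0
    for p in range(ms, me):
        if bp.get(p) is None or not (ss <= bp[p] < se):
            n += 1
    for p in range(ss, se):
        if bp.get(p) is None or not (ms <= bp[p] < me):
            n += 1
    return max(0, n - 4)  # the two 2-nt overhangs are by construction unpaired


def validate_candidate(
    candidate: HairpinCandidate, rules: PrecursorRules
) -> None:
    """Independent re-check of every precursor rule; raises RuleViolation."""
    ms, me = candidate.mature
    if not rules.mature_len[0] <= me - ms <= rules.mature_len[1]:
        raise RuleViolation("mature_length", f"{me - ms} nt")
    bp = candidate.structure.partner_map()
    if _mature_arm(bp, candidate.mature) is None:
        raise RuleViolation("mature_in_stem", "mature not wholly in one arm")
    # the energy ceiling applies to the miR-through-miR* core hairpin, so
    # structured flanking sequence cannot rescue a weak duplex
    energy = candidate.core_energy if candidate.core_energy is not None else candidate.energy
    if energy > rules.max_energy:
        raise RuleViolation("max_energy", f"{energy:.2f} > {rules.max_energy}")
    star = candidate.star
    unpaired = _duplex_unpaired(bp, candidate.mature, star)
    if unpaired > rules.max_duplex_unpaired:
        raise RuleViolation("max_duplex_unpaired", f"{unpaired} nt")
    if star[0] >= me:
        dist = star[0] - me
    else:
        dist = ms - star[1]
    if not rules.distance[0] <= dist <= rules.distance[1]:
        raise RuleViolation("distance", f"{dist} nt")


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _enclosing_hairpin(
    bp: dict[int, int], mature: tuple[int, int], n: int
) -> tuple[int, int] | None:
    """Span of the stem-loop component containing the mature.

    Starting from the outermost pair adjacent to the mature's helix, walk
    outward through stacked pairs and bulge/internal loops; stop when the
    next enclosing pair closes a multibranch loop or when the exterior is
    reached.  Returns a 0-based half-open span or None.
    """
    partners = [(p, bp[p]) for p in range(*mature) if p in bp]
    if not partners:
        return None
    lo = min(min(p, q) for p, q in partners)
    hi = max(max(p, q) for p, q in partners)
    # walk outward while pairs continue to enclose [lo, hi] as a single stem
    i, j = lo, hi
    while True:
        ni, nj = None, None
        for step_i in range(i, max(i - 31, -1), -1):
            if step_i in bp and bp[step_i] > j:
                ni, nj = step_i, bp[step_i]
                break
        if ni is None or nj - j > 30:
            break
        # the skipped gaps must be loop-only, so the walk never crosses a
        # multibranch junction and the component stays a single stem-loop
        if any(p in bp for p in range(ni + 1, i)):
            break
        if any(p in bp for p in range(j + 1, nj)):
            break
        i, j = ni, nj
    return (i, j + 1)


def _component_pairs(
    bp: dict[int, int], span: tuple[int, int]
) -> list[tuple[int, int]]:
    lo, hi = span
    return [
        (p, bp[p])
        for p in range(lo, hi)
        if p in bp and p < bp[p] and lo <= bp[p] < hi
    ]


def find_precursors(
    transcript: NucSequence,
    read: str,
    rules: PrecursorRules | None = None,
    params: FoldParams | None = None,
    window: tuple[int, int] = (250, 250),
) -> list[HairpinCandidate]:
    """Hairpin candidates for every exact locus of ``read`` in ``transcript``.

    For each locus, the read +/- the window flanks (and shrinking
    sub-windows of halved flanks) are folded; the stem-loop enclosing the
    read is extracted and kept when all precursor rules hold.
    Overlapping survivors reduce to the lowest-energy one.
    """
    rules = rules or PrecursorRules()
    params = params or DEFAULT_FOLD_PARAMS
    seq = transcript.seq
    loci = []
    pos = seq.find(read)
    while pos != -1:
        loci.append(pos)
        pos = seq.find(read, pos + 1)
    if not loci:
        raise ValueError(f"read not found in transcript {transcript.id!r}")
    if not rules.mature_len[0] <= len(read) <= rules.mature_len[1]:
        return []

    survivors: list[HairpinCandidate] = []
    for locus in loci:
        flanks = []
        f = max(window)
        while f >= 30:
            flanks.append(f)
            f //= 2
        seen_spans = set()
        for flank in flanks:
            lo = max(0, locus - min(flank, window[0]))
            hi = min(len(seq), locus + len(read) + min(flank, window[1]))
            if hi - lo < max(MIN_FOLD_LEN, len(read) + 15) or hi - lo > MAX_FOLD_LEN:
                continue
            if (lo, hi) in seen_spans:
                continue
            seen_spans.add((lo, hi))
            cand = _candidate_from_window(
                transcript, (lo, hi), locus, read, rules, params
            )
            if cand is not None:
                survivors.append(cand)
    return reduce_overlapping(survivors)


def _candidate_from_window(
    transcript: NucSequence,
    span: tuple[int, int],
    locus: int,
    read: str,
    rules: PrecursorRules,
    params: FoldParams,
) -> HairpinCandidate | None:
    lo, hi = span
    window_seq = transcript.seq[lo:hi]
    folded = fold(window_seq, params, min_len=MIN_FOLD_LEN)
    bp = folded.partner_map()
    mature_w = (locus - lo, locus - lo + len(read))
    comp = _enclosing_hairpin(bp, mature_w, len(window_seq))
    if comp is None:
        return None
    clo, chi = comp
    if not (clo <= mature_w[0] and mature_w[1] <= chi):
        return None  # the stem-loop does not contain the whole mature
    pre_seq = window_seq[clo:chi]
    pre_pairs = [(i - clo, j - clo) for i, j in _component_pairs(bp, comp)]
    structure = ["."] * len(pre_seq)
    for i, j in pre_pairs:
        structure[i], structure[j] = "(", ")"
    try:
        energy = structure_energy(pre_seq, pre_pairs, params)
    except ValueError:
        return None
    pre_db = DotBracket("".join(structure), energy)
    mature = (mature_w[0] - clo, mature_w[1] - clo)
    pre_bp = pre_db.partner_map()
    arm = _mature_arm(pre_bp, mature)
    if arm is None:
        return None
    try:
        star = predict_star_checked(pre_db, mature, rules.star_overhang)
    except ValueError:
        return None
    star = (max(0, star[0]), min(len(pre_seq), star[1]))
    # energy-rule region: the miR:miR* duplex through the loop, plus the
    # few base pairs stacking directly on the duplex base
    pad = 2 * rules.star_overhang
    core_lo = max(0, min(mature[0], star[0]) - pad)
    core_hi = min(len(pre_seq), max(mature[1], star[1]) + pad)
    core_pairs = [
        (i, j) for i, j in pre_pairs if core_lo <= i and j < core_hi
    ]
    try:
        core_energy = structure_energy(pre_seq, core_pairs, params)
    except ValueError:
        return None
    cand = HairpinCandidate(
        transcript_id=transcript.id,
        window=(lo + clo, lo + chi),
        precursor_seq=pre_seq,
        structure=pre_db,
        energy=energy,
        mature=mature,
        star=star,
        arm=arm,
        core_energy=core_energy,
    )
    try:
        validate_candidate(cand, rules)
    except RuleViolation:
        return None
    return cand


def reduce_overlapping(
    candidates: list[HairpinCandidate],
) -> list[HairpinCandidate]:
    """Among candidates with overlapping spans, keep the lowest energy."""
    kept: list[HairpinCandidate] = []
    for cand in sorted(candidates, key=lambda c: (c.energy, c.window)):
        if any(
            c.transcript_id == cand.transcript_id
            and c.window[0] < cand.window[1]
            and cand.window[0] < c.window[1]
            for c in kept
        ):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda c: (c.transcript_id, c.window))


# ---------------------------------------------------------------------------
# read-stack classification
# ---------------------------------------------------------------------------

def map_read_stack(
    candidate: HairpinCandidate, library_entries: dict[str, int]
) -> HairpinCandidate:
    """Attach every library read occurring exactly within the precursor."""
    stack = []
    pre = candidate.precursor_seq
    for seq, count in library_entries.items():
        pos = pre.find(seq)
        while pos != -1:
            stack.append((seq, count, pos))
            pos = pre.find(seq, pos + 1)
    return replace(candidate, read_stack=sorted(stack, key=lambda t: (t[2], t[0])))


def classify_precursor(
    candidate: HairpinCandidate,
    rules: PrecursorRules | None = None,
) -> str:
    """Assign the class 1-5 label from the candidate's read stack.

    * class 1: all reads inside the miR/miR* regions, miR* read-supported
    * class 2: miR and miR* supported plus lower-abundance reads outside
    * class 3a: reads on the defining miR region only, >= 2 reads
    * class 3b: a single read on the defining miR region
    * class 4: defining miR plus lower-abundance outside reads, no miR*
    * class 5: some read outside the duplex outnumbers the defining read
    """
    rules = rules or PrecursorRules()
    stack = candidate.read_stack
    if not stack:
        raise ValueError("empty read stack")
    m = candidate.mature
    s = candidate.star
    margin = rules.class_margin
    tol = rules.star_overhang

    def region(span):
        return (span[0] - margin, span[1] + margin)

    def inside(span, off, ln):
        return span[0] <= off and off + ln <= span[1]

    mir_region, star_region = region(m), region(s)
    defining = 0
    star_support = 0
    outside: list[int] = []
    for seq, count, off in stack:
        ln = len(seq)
        if abs(off - m[0]) <= tol and inside(mir_region, off, ln):
            defining += count
        elif abs(off - s[0]) <= tol and inside(star_region, off, ln):
            star_support += count
        elif inside(mir_region, off, ln) or inside(star_region, off, ln):
            # inside the 25-bp regions but not at the miR/miR* register
            outside.append(0)  # counts as in-region, non-defining
            defining += 0
        else:
            outside.append(count)
    if defining == 0:
        # the defining read must sit at the mature register
        raise ValueError("no read supports the predicted mature")
    outside_counts = [c for c in outside if c > 0]
    if outside_counts and max(outside_counts) > defining:
        return "5"
    if star_support:
        return "2" if outside_counts else "1"
    if outside_counts:
        return "4"
    total_reads = defining
    return "3a" if total_reads >= 2 else "3b"


def attach_classes(
    candidates: list[HairpinCandidate],
    library_entries: dict[str, int],
    rules: PrecursorRules | None = None,
) -> list[HairpinCandidate]:
    out = []
    for cand in candidates:
        cand = map_read_stack(cand, library_entries)
        if cand.read_stack:
            cand.precursor_class = classify_precursor(cand, rules)
        out.append(cand)
    return out
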