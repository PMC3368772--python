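"""End-to-end orchestration and paper-shaped report emission.

Stages run in the order the analysis is defined: preprocess -> categorise
-> conserved-family assignment -> hairpin discovery (per defining read)
-> precursor classification -> modification detection -> target
prediction.  Reports are written as TSV/JSON twins: the JSON mirror is
canonical for tests, the TSVs are for humans.  All report coordinates
are 1-based inclusive (stated in each header).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import CategoryCall, category_summary, classify_library
from .families import FamilyAssignment, FamilyProfile, assign_library, family_profile
from .hairpin import (
    HairpinCandidate,
    PrecursorRules,
    attach_classes,
    find_precursors,
)
from .io_formats import NucSequence, write_collapsed_fasta, write_tsv
from .modifications import ModificationEvent, detect_family_modifications
from .preprocess import CollapsedLibrary, preprocess_reads
from .targets import PRESETS, TargetScoringParams, TargetSite, align_target
from .thermo import FoldParams

logger = logging.getLogger("mirforge.pipeline")


@dataclass
class PipelineConfig:
    adapter: str
    min_clip: int = 6
    min_len: int = 17
    max_len: int = 32
    max_mismatch_annotation: int = 1
    family_min_overlap: int = 19
    family_max_mismatch: int = 1
    rules: PrecursorRules = field(default_factory=PrecursorRules)
    fold_params: FoldParams = field(default_factory=FoldParams)
    target_params_conserved: TargetScoringParams = field(
        default_factory=lambda: PRESETS["conserved"]
    )
    target_params_novel: TargetScoringParams = field(
        default_factory=lambda: PRESETS["novel"]
    )
    window: tuple[int, int] = (250, 250)
    run_targets: bool = True


@dataclass
class PipelineResult:
    library: CollapsedLibrary
    drop_log: dict[str, int]
    calls: list[CategoryCall]
    summary: dict[str, int]
    assignments: dict[str, FamilyAssignment]
    profiles: list[FamilyProfile]
    precursors: list[HairpinCandidate]
    modifications: list[ModificationEvent]
    targets: list[TargetSite]

    @property
    def conserved_family_count(self) -> int:
        return len(self.profiles)

    @property
    def novel_precursors(self) -> list[HairpinCandidate]:
        return [
            c for c in self.precursors if c.mature_seq not in self.assignments
        ]

    @property
    def novel_family_count(self) -> int:
        return len({c.mature_seq for c in self.novel_precursors})


def discover_precursors(
    library: CollapsedLibrary,
    transcripts: list[NucSequence],
    rules: PrecursorRules,
    params: FoldParams,
    window: tuple[int, int] = (250, 250),
) -> list[HairpinCandidate]:
    """Hairpin candidates over all transcripts, one search per unique read.

    Candidates from different defining reads that overlap on a transcript
    reduce to the one with the dominant (most abundant) defining read,
    then lowest energy — the "dominant mature sequence" convention.
    """
    candidates: list[tuple[int, HairpinCandidate]] = []
    lo, hi = rules.mature_len
    for seq, count in library.entries.items():
        if not lo <= len(seq) <= hi:
            continue
        for tx in transcripts:
            if seq not in tx.seq:
                continue
            for cand in find_precursors(tx, seq, rules, params, window):
                candidates.append((count, cand))
    kept: list[tuple[int, HairpinCandidate]] = []
    for count, cand in sorted(
        candidates, key=lambda t: (-t[0], t[1].energy, t[1].window)
    ):
        if any(
            c.transcript_id == cand.transcript_id
            and c.window[0] < cand.window[1]
            and cand.window[0] < c.window[1]
            for _, c in kept
        ):
            continue
        kept.append((count, cand))
    return sorted((c for _, c in kept), key=lambda c: (c.transcript_id, c.window))


def run_pipeline(
    reads,
    transcripts: list[NucSequence],
    mature_db: list[NucSequence],
    references: list[NucSequence],
    config: PipelineConfig,
) -> PipelineResult:
    from .io_formats import AnnotatedReference

    logger.info("preprocess: adapter=%s min_clip=%d length=[%d, %d]",
                config.adapter, config.min_clip, config.min_len, config.max_len)
    library, drop_log = preprocess_reads(
        reads, config.adapter, config.min_clip, config.min_len, config.max_len
    )
    logger.info("preprocess: %s", drop_log)

    calls = classify_library(
        library, AnnotatedReference(references), config.max_mismatch_annotation
    )
    summary = category_summary(calls)

    assignments = assign_library(
        library, mature_db, config.family_min_overlap, config.family_max_mismatch
    )
    profiles = family_profile(assignments, library)

    precursors = discover_precursors(
        library, transcripts, config.rules, config.fold_params, config.window
    )
    precursors = attach_classes(precursors, library.entries, config.rules)

    mature_by_family = {rec.meta["family"]: rec.seq for rec in mature_db}
    modifications: list[ModificationEvent] = []
    for prof in profiles:
        fam_reads = [
            (seq, library.entries[seq])
            for seq, a in assignments.items()
            if a.family == prof.family
        ]
        modifications.extend(
            detect_family_modifications(
                prof.family, fam_reads, mature_by_family[prof.family]
            )
        )

    targets: list[TargetSite] = []
    if config.run_targets:
        detected_families = {p.family for p in profiles}
        conserved = [
            rec for rec in mature_db if rec.meta["family"] in detected_families
        ]
        novel = [
            NucSequence(f"novel_{i + 1}", seq)
            for i, seq in enumerate(
                sorted(
                    {
                        c.mature_seq
                        for c in precursors
                        if c.mature_seq not in assignments
                    }
                )
            )
        ]
        for mirna in conserved:
            for tx in transcripts:
                targets.extend(
                    align_target(mirna, tx, config.target_params_conserved)
                )
        for mirna in novel:
            for tx in transcripts:
                targets.extend(align_target(mirna, tx, config.target_params_novel))

    result = PipelineResult(
        library, drop_log, calls, summary, assignments, profiles,
        precursors, modifications, targets,
    )
    _check_consistency(result)
    return result


def _check_consistency(result: PipelineResult) -> None:
    if sum(result.summary.values()) != result.library.unique_count:
        raise AssertionError("category counts do not partition the unique reads")
    for prof in result.profiles:
        if sum(prof.length_histogram.values()) != prof.total_reads:
            raise AssertionError(f"family {prof.family}: histogram inconsistent")


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def write_reports(result: PipelineResult, outdir) -> dict:
    """Write the TSV reports plus the canonical JSON mirror; returns it."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    write_collapsed_fasta(result.library.entries, out / "collapsed.fa")

    stats_rows = [
        ("read sequences", result.library.total_raw),
        ("clean sequences", result.library.total_clean),
        ("unique clean sequences", result.library.unique_count),
        *sorted(result.summary.items()),
        ("conserved miRNA family", result.conserved_family_count),
        ("putative novel miRNA family", result.novel_family_count),
    ]
    write_tsv(out / "summary.tsv", ("statistic", "value"), stats_rows)

    write_tsv(
        out / "length_histogram.tsv",
        ("length", "unique_sequences", "reads"),
        [
            (ln, u, r)
            for ln, (u, r) in result.library.length_histogram.items()
        ],
    )

    write_tsv(
        out / "family_profiles.tsv",
        ("family", "total_reads", "unique_sequences", "dominant_length",
         "size_class", "length_histogram"),
        [
            (
                p.family, p.total_reads, p.unique_sequences, p.dominant_length,
                p.size_class,
                ";".join(f"{k}:{v}" for k, v in sorted(p.length_histogram.items())),
            )
            for p in result.profiles
        ],
    )

    # precursor report (1-based inclusive coordinates)
    rows = []
    for i, c in enumerate(result.precursors, 1):
        star_reads = sum(
            cnt
            for seq, cnt, off in c.read_stack
            if abs(off - c.star[0]) <= 2 and seq != c.mature_seq
        )
        rows.append(
            (
                f"cand_{i}",
                c.mature_seq,
                len(c.mature_seq),
                f"yes ({star_reads})" if star_reads else "nd",
                len(c.precursor_seq),
                c.transcript_id,
                c.window[0] + 1,
                c.window[1],
                c.arm,
                c.precursor_class or "",
                f"{c.energy:.2f}",
                c.structure.structure,
            )
        )
    write_tsv(
        out / "precursors.tsv",
        ("name", "mature_sequence", "mature_length", "star_support",
         "precursor_length", "transcript", "start_1based", "end_1based",
         "arm", "class", "energy_kcal_mol", "dot_bracket"),
        rows,
    )

    write_tsv(
        out / "modifications.tsv",
        ("family", "modification", "supporting_reads"),
        [(m.family, m.label, m.supporting_reads) for m in result.modifications],
    )

    write_tsv(
        out / "targets.tsv",
        ("miRNA", "transcript", "start_1based", "end_1based", "penalty",
         "energy_kcal_mol", "cleavage_1based"),
        [
            (
                t.mirna_id, t.transcript_id, t.start + 1, t.end, t.penalty,
                f"{t.energy:.2f}", t.cleavage,
            )
            for t in result.targets
        ],
    )
    with open(out / "target_alignments.txt", "w") as fh:
        for t in result.targets:
            fh.write(
                f"# {t.mirna_id} -> {t.transcript_id}:{t.start + 1}-{t.end} "
                f"penalty={t.penalty} energy={t.energy:.2f} kcal/mol "
                f"cleavage={t.cleavage}\n{t.alignment_text()}\n\n"
            )

    mirror = {
        "statistics": {k: v for k, v in stats_rows},
        "drop_log": result.drop_log,
        "length_histogram": {
            str(ln): {"unique": u, "reads": r}
            for ln, (u, r) in result.library.length_histogram.items()
        },
        "families": [
            {
                "family": p.family,
                "total_reads": p.total_reads,
                "unique_sequences": p.unique_sequences,
                "dominant_length": p.dominant_length,
                "size_class": p.size_class,
                "length_histogram": {
                    str(k): v for k, v in sorted(p.length_histogram.items())
                },
            }
            for p in result.profiles
        ],
        "precursors": [
            {
                "transcript": c.transcript_id,
                "start_1based": c.window[0] + 1,
                "end_1based": c.window[1],
                "mature": c.mature_seq,
                "mature_length": len(c.mature_seq),
                "star": c.star_seq,
                "arm": c.arm,
                "class": c.precursor_class,
                "energy": c.energy,
                "precursor_length": len(c.precursor_seq),
            }
            for c in result.precursors
        ],
        "modifications": [
            {
                "family": m.family,
                "kind": m.kind,
                "position": m.position,
                "ref": m.ref_base,
                "obs": m.obs_base,
                "supporting_reads": m.supporting_reads,
                "frequency_percent": m.frequency,
            }
            for m in result.modifications
        ],
        "targets": [
            {
                "miRNA": t.mirna_id,
                "transcript": t.transcript_id,
                "start_1based": t.start + 1,
                "end_1based": t.end,
                "penalty": t.penalty,
                "energy": t.energy,
                "cleavage_1based": t.cleavage,
            }
            for t in result.targets
        ],
    }
    with open(out / "results.json", "w") as fh:
        json.dump(mirror, fh, indent=1, sort_keys=True)
    return mirror
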