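"""Sequence containers and the file formats the pipeline touches.

All sequences are held as RNA (A/C/G/U); DNA input (EST databases,
sequencer output) is accepted anywhere and silently normalised by the
T->U substitution.  Internal coordinates are 0-based half-open; every
report writer emits 1-based inclusive coordinates and says so in its
header line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: closed category vocabulary for annotated references
CATEGORIES = (
    "coding mRNA",
    "transposon",
    "rRNA",
    "pseudo mRNA",
    "ncRNA",
    "miRNA",
    "tRNA",
    "sn/snoRNA",
)

COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FastaParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input; carries the offending line."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U.  Idempotent."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class NucSequence:
    """A single RNA record.

    ``meta`` holds free-form ``key=value`` tags parsed from the FASTA
    description line (e.g. ``category=rRNA`` or ``family=miR156``).
    """

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = normalize_rna(self.seq)
        if not self.seq:
            raise FastaParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r} contains non-ACGU symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotatedReference:
    """A categorised reference set (the generalisation of a genome annotation)."""

    records: list[NucSequence]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaParseError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            cat = rec.meta.get("category")
            if cat is not None and cat not in CATEGORIES:
                raise FastaParseError(
                    f"record {rec.id!r} has unknown category {cat!r}"
                )

    def category_of(self, record_id: str) -> str | None:
        for rec in self.records:
            if rec.id == record_id:
                return rec.meta.get("category")
        raise KeyError(record_id)


@dataclass
class DotBracket:
    """A nested secondary structure annotating one sequence."""

    structure: str
    energy: float  # kcal/mol

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket symbol {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    def pairs(self) -> list[tuple[int, int]]:
        """0-based (i, j) pairs, i < j."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.append((stack.pop(), i))
        return sorted(out)

    def partner_map(self) -> dict[int, int]:
        bp: dict[int, int] = {}
        for i, j in self.pairs():
            bp[i] = j
            bp[j] = i
        return bp


def _parse_meta(description: str) -> dict:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value.replace("_", " ") if key == "category" else value
    return meta


def read_fasta(path) -> list[NucSequence]:
    """Read a FASTA file into normalised RNA records, order preserved."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython raises ValueError with context
        raise FastaParseError(str(exc)) from exc
    seen = set()
    for rec in parsed:
        if len(rec.seq) == 0:
            raise FastaParseError(
                f"record {rec.id!r} has no sequence line"
            )
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            NucSequence(rec.id, str(rec.seq), _parse_meta(rec.description))
        )
    if not records:
        # distinguish empty file (fine) from a lone header (malformed)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith(">"):
                    raise FastaParseError(
                        f"line {lineno}: header without sequence"
                    )
    return records


def read_fastq(path) -> Iterator[NucSequence]:
    """Stream FASTQ records as normalised RNA; qualities kept in meta."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield NucSequence(
            rec.id,
            str(rec.seq),
            {"qual": rec.letter_annotations["phred_quality"]},
        )


def write_fastq(records: Iterable[NucSequence], path) -> None:
    """Write records as FASTQ; constant qualities unless ``qual`` meta set."""
    with open(path, "w") as fh:
        for rec in records:
            quals = rec.meta.get("qual") or [40] * len(rec.seq)
            fh.write(
                f"@{rec.id}\n{rec.seq}\n+\n"
                + "".join(chr(q + 33) for q in quals)
                + "\n"
            )


def write_fasta(records: Iterable[NucSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            tags = "".join(
                f" {k}={str(v).replace(' ', '_')}" for k, v in rec.meta.items()
            )
            fh.write(f">{rec.id}{tags}\n{rec.seq}\n")


def read_reads(path) -> Iterator[NucSequence]:
    """Read raw small-RNA reads from FASTA or FASTQ (by extension)."""
    p = str(path)
    if p.endswith((".fastq", ".fq")):
        yield from read_fastq(p)
    else:
        yield from read_fasta(p)


# ---------------------------------------------------------------------------
# collapsed-library FASTA dialect: ">acc_<i>_x<count>"
# ---------------------------------------------------------------------------

def write_collapsed_fasta(entries: Mapping[str, int], handle_or_path) -> None:
    """Write unique sequences with counts, one record per sequence.

    Header dialect is ``acc_<i>_x<count>`` with ``i`` numbered in
    descending-count order (ties broken by sequence) so the naming echoes
    accession-style identifiers while carrying abundances.
    """
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(
        handle_or_path, "__fspath__"
    )
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        order = sorted(entries.items(), key=lambda kv: (-kv[1], kv[0]))
        for i, (seq, count) in enumerate(order, 1):
            fh.write(f">acc_{i}_x{count}\n{seq}\n")
    finally:
        if own:
            fh.close()


def read_collapsed_fasta(path) -> dict[str, int]:
    """Inverse of :func:`write_collapsed_fasta`."""
    entries: dict[str, int] = {}
    for rec in read_fasta(path):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise FastaParseError(
                f"header {rec.id!r} is not in acc_<i>_x<count> form"
            ) from exc
        entries[rec.seq] = entries.get(rec.seq, 0) + count
    return entries


def collapsed_fasta_text(entries: Mapping[str, int]) -> str:
    buf = io.StringIO()
    write_collapsed_fasta(entries, buf)
    return buf.getvalue()


def write_tsv(path, header: Iterable[str], rows: Iterable[Iterable]) -> None:
    """Plain TSV writer used by all report emitters (UTF-8, header line)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
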