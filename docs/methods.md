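# Methods

This note documents the models and procedures mirforge implements, the
parameters that matter, the synthetic-data generator's scope, and the
design choices made where the workflow it re-implements left the design
open.

## Read cleanup

Adapter trimming is defined as the leftmost position in the read from
which the remaining suffix matches a prefix of the 3′ adapter over at
least `min_clip` nucleotides (default 6) with 0 mismatches (configurable
to 1). The comparison spans the whole available overlap, so a full
adapter occurrence anywhere in the read clips everything from its first
base onward. Reads with no adapter evidence are rejected by default
(`keep_untrimmed` retains them); a read that *begins* with the adapter
is an adapter dimer and always rejected. Length filtering keeps inserts
of 17–32 nt — the empirically observed small-RNA range, applied here as
the retention window and configurable. Quality filtering is an optional
mean-Phred threshold, off by default, since no published criterion
exists for the original filtering step.

Count conservation (Σ collapsed counts = surviving reads) is enforced by
the `CollapsedLibrary` invariant and property-tested.

## Categorisation

The original workflow categorised reads by BLASTN against an annotated
genome. For 17–32 nt queries, ungapped full-length matching with ≤1
substitution is exact and reproducible, so mirforge scans every
placement on both strands of each reference record (seed-and-extend by
pigeonhole: with ≤k mismatches one of k+1 query slices matches
exactly). Multi-category hits resolve by fewest mismatches, then a fixed
precedence in which structural RNAs outrank mRNA (miRNA > tRNA > rRNA >
sn/snoRNA > ncRNA > transposon > pseudo mRNA > coding mRNA) so that
degradation products of structural RNAs are not mislabelled as mRNA
fragments. Hits to records lacking a `category=` tag produce
"hit, unknown". Category counts partition the unique-read set by
construction.

## Family assignment

A read is assigned to the known family maximising ungapped overlap
(≥19 nt) with ≤1 substitution inside the overlap, ties broken by fewer
mismatches, then family name (logged); declared synonym groups
(e.g. 159/319) can be merged. The 19-nt rule is interpreted as an
*alignment overlap* minimum rather than a read-length minimum — the more
permissive reading — so 5′-trimmed and 3′-extended isomiRs (including
the −1+UU species and 23–27 nt long-miRNA forms) stay assignable.
Placements are chosen among those satisfying the mismatch cap; this
matters for isoforms whose best unconstrained overlap would be a
heavily mismatched full-length placement.

## Energy model and folding

No energy model was published for the original precursor step, so
mirforge ships its own Turner-like nearest-neighbour set
(`mirforge-nn-1.0`): a 6×6 stacking table over {AU, UA, CG, GC, GU, UG}
(all values ≤ 0, magnitudes 0.3–3.4 kcal/mol), hairpin/bulge/internal
initiation penalties by loop size with logarithmic extrapolation beyond
the tabulated sizes, and a linear multibranch model
(a = 3.4, b = 0.4 per branch, c = 0 per unpaired nucleotide). There are
no dangles, coaxial stacks, or terminal-AU terms. Energies are integer
centi-kcal/mol internally so optima and tie-breaks are exact.

Folding is a Zuker-style dynamic programme (`V`/`ML`/`M1` plus an
external prefix array), nested structures only, minimum hairpin loop 3,
internal/bulge loops capped at 30 unpaired nt (the standard speed cap),
JIT-compiled with numba. The DP provably equals exhaustive enumeration
of all nested structures under the same tables; the test-suite checks
this on hundreds of random sequences up to 20 nt against an independent
enumerator and loop-decomposition evaluator. Traceback is deterministic
with a fixed preference (pairing over unpaired, leftmost pairings
first). Because the energy threshold below is tied to the model in use,
an external folder can be substituted by supplying dot-bracket
structures and energies directly, in which case the threshold should be
recalibrated by the user.

## Precursor discovery and rules

For each unique read mapping exactly into a transcript, windows of the
read ± 250 nt (and shrinking sub-windows with halved flanks) are folded;
the stem-loop component containing the read is extracted by walking
enclosing pairs outward from the read's helix while the intervening
regions stay loop-only (so the walk never crosses a multibranch
junction). A candidate survives when:

- the mature length is within 20–22 nt (default; configurable, e.g.
  19–22 when the input set contains 19-mers);
- the mature lies wholly in one stem arm (all paired partners on one
  side, at least half the mature paired);
- the **core hairpin energy** is ≤ −25 kcal/mol. The core is the
  miR:miR\* duplex through the loop plus the few pairs stacking directly
  on the duplex base (2 × overhang nt of context). Scoring the whole
  extracted component instead would let structured flanking sequence
  rescue an arbitrarily weak duplex — in a 500-nt window random RNA
  alone reaches −100 kcal/mol — so the ceiling is applied where it
  discriminates;
- at most 6 nt of the mature+star are unpaired within the duplex
  (the four expected overhang positions are not counted);
- the miR–miR\* distance (gap between the regions) is 5–240 nt.

The miRNA\* spans the partners of the mature under the structure shifted
to produce 2-nt 3′ overhangs on both duplex ends, with bulged positions
interpolated from the nearest paired neighbour; for a perfect duplex
this is the reverse-complement block offset by two. Overlapping
candidates reduce to the lowest-energy one per defining read, and across
defining reads to the candidate whose defining read is most abundant
("dominant mature sequence"), then lowest energy. An independent
validator re-checks every emitted candidate against all rules and names
the violated rule otherwise.

Read stacks map every library sequence occurring exactly within the
precursor. Classes follow the read-stack taxonomy with the "25-bp
region" around miR and miR\* implemented as a ±12 nt margin per side
(the phrase is ambiguous between total span and per-side margin; the
margin reading is configurable): class 1 — all reads inside the miR/miR\*
regions with star support; class 2 — star support plus lower-abundance
outside reads; class 3a/3b — reads at the defining region only (≥2
reads / exactly 1); class 4 — outside reads but no star support;
class 5 — an outside read outnumbering the defining read. Reads within
the regions but off the miR/miR\* register (isomiRs) count as in-region.
Every candidate with a non-empty stack receives exactly one label.

## Modification detection

Editing candidates are family reads whose best placement (≤1 mismatch)
has exactly one substitution *inside* the reference span; each
(position, ref→obs) pair becomes an event with frequency
100 × supporting reads / all family reads, reported to 3 decimals. The
denominator is all reads assigned to the family (not reads of the
affected length — the alternative is not stated anywhere and the full
denominator is the conservative choice). Indel-bearing reads are out of
scope; sequencing error is not distinguished from editing (a
minimum-support option, default 1 read, is exposed). The −1+UU isoform
is the exact string `reference[1:] + "UU"`.

## Target prediction

Sites are optimal gapped complementarity alignments of the reversed
miRNA against transcript windows, scored by accumulated penalties
(lower is better): mismatch 1, G:U wobble 0.5, gap column 2; a site is
reported when the optimal penalty is ≤3, the alignment spans ≥20
columns (conserved preset) or ≥18 (novel preset), and miRNA positions
10–11 (1-based from the 5′ end) are perfect Watson–Crick pairs — wobble
and gaps are disallowed there too, since these positions flank the
cleavage site. The penalty-with-cap semantics is the standard plant
target-scoring reading of these parameter names. Because each gap
column costs 2, alignments with more than ⌊threshold/gap⌋ gap columns
cannot pass; the search is exact over that cap (one gap at the
defaults), which the brute-force oracle in the test-suite mirrors by
enumerating gap placements. Gap columns opposite the miRNA are internal
only; every miRNA base is opposed by a site base or a gap column.

Duplex "energy" is the stacking sum over consecutive paired columns
under the same shipped table, reported with the model version string.
These values are *not* comparable to energies printed by other tools
with unknown internal models; they order duplexes consistently (more
stacked pairs never raise the energy).

The predicted cleavage coordinate is the transcript position opposite
the 10th miRNA nucleotide from the 5′ end, reported 1-based; it always
lies inside the site span and shifts 1:1 with the site.

## Synthetic data

The generator emulates the statistical structure of a pooled, deeply
sequenced plant small-RNA library; one integer seed fixes every draw and
outputs are bit-reproducible.

- **Families:** 48 by default, each a distinct random mature (20–22 nt,
  ~55% GC, redrawn until the perfect mature:star helix clears the
  energy ceiling with ~5 kcal/mol headroom — the generator's contract is
  to plant *rule-satisfying* precursors). Abundances follow a
  deterministic ladder: 3 families above 20,000 reads, 12 above 1,000,
  18 between 100 and 1,000, 18 below 100 — the published composition of
  the motivating library. A deterministic ladder rather than log-uniform
  draws keeps the "12 predominant families" condition exact.
- **Precursors:** 20 planted hairpins (8 defined by conserved-family
  matures, 12 novel), built as [30-nt extension][mature][A/C-only random
  loop][star arm][reverse-complement extension] and embedded in ~800-nt
  random transcripts. Loops are A/C-only so they cannot pair internally,
  and random per precursor so loop-spanning reads are locus-specific.
  Each precursor carries a class scenario (star reads at ratio 0.05 for
  classes 1–2; loop-spanning outside reads for classes 2/4/5; class 3b
  gets a single defining read). Classes needing controlled counts (3b,
  5) are assigned only to novel loci.
- **Decoys:** 20 hairpins violating exactly one rule each — an AU-only
  duplex (energy), a GC-rich duplex with 4 broken pairs = 8 unpaired nt
  (duplex-unpaired), a 270-nt miR–miR\* separation (distance), and a
  mature placed in the terminal loop of a G/C stem (mature-in-stem).
- **Reads:** mature/star/outside reads at configured counts; editing and
  −1+UU isoforms at deterministic rounded rates; degradation background
  sampled as transcript substrings with 32%/53% singleton/doubleton
  fractions and length weights peaking at 24 and 27 nt (with 17/19-nt
  degradation modes). Background fragments come only from dedicated
  background transcripts, never from planted loci, so planted read
  stacks — and hence precursor classes — are exactly as configured.
  Reads carry the full 3′ adapter and uniform qualities.
- **Targets:** perfect, one-wobble and one-mismatch sites (mutations
  placed outside positions 10–11) plus shuffled decoy sites, embedded
  in dedicated transcripts with expected penalties recorded.

What the generator does **not** emulate: sequencing-error models beyond
the planted substitutions, quality-score realism, multi-locus gene
families, cross-mapping reads, paralogous precursors, or genomic (vs
transcript) context. Passing the planted-truth tests therefore shows the
pipeline's rules and bookkeeping are correct under clean conditions; it
does not certify discovery power on real libraries, where degradation
noise overlaps true loci and conserved families share near-identical
members.

## Numerical and procedural choices

- Integer centi-kcal energies; half-unit integer penalties in the target
  DP; all comparisons exact, no floating-point tolerances inside
  engines.
- Fold tie-breaks prefer paired bases, leftmost first; target-site
  overlap reduction keeps minimum penalty, then lowest energy, then the
  leftmost site; precursor dedup keeps the most abundant defining read,
  then lowest energy.
- Degenerate inputs: empty libraries collapse to empty reports;
  unpairable sequences fold to the all-dot structure at 0 kcal/mol; an
  empty read stack or a fully unpaired mature is an error, not a class.
- Pipeline scale defaults: ~160,000 synthetic reads, ~50 transcripts of
  800 nt, ±250-nt fold windows. A full synthetic study runs in well
  under a minute after JIT warm-up on one CPU.

## Known limitations

- Single-end, adapter-at-3′ reads only; no UMIs, no paired-end logic.
- The energy model is a self-consistent Turner-like set, not a fitted
  parameterisation; absolute kcal/mol values (and the −25 ceiling tied
  to them) should be recalibrated if an external folder is plugged in.
- Target scoring omits seed-region weighting, bulge asymmetry and site
  accessibility; it implements exactly the stated penalty set.
- Categorisation is ungapped and full-length; spliced or indel-bearing
  alignments are out of scope.
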