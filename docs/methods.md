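# Methods

This note documents the models and conventions behind each metric, the
synthetic-data generator the test suite is anchored to, and the numerical
choices made where the underlying definitions left room.

## Coordinate and read-location conventions

All intervals are 0-based half-open, on every input and output format. A
read's location is its **3′ end** throughout (signal tracks, densities,
pause index, exon:intron, FRiF read assignment): for run-on data the 3′ end
is the polymerase active-site position, which is the biologically meaningful
coordinate. On a plus-strand alignment `[start, end)` the 3′ end is
`end − 1`; on minus, `start`. Gene-level metrics count **sense-strand** reads
only; the aggregate TSS profile uses **both** strands so the divergent
upstream peak of run-on data is visible. A read end at `x` overlaps
`[s, e)` iff `s ≤ x < e`.

## Raw-read model and insert sizes

A single-end read is modeled as `insert + UMI + 3′adapter` on the sequenced
strand (the sequencer reads the nascent RNA 3′→5′, hence the final
reverse-complementation step). Adapter localization scans offsets left to
right and accepts the first offset where the read suffix matches a prefix of
the adapter over ≥ 3 positions with a mismatch fraction ≤ 0.1; scanning
left-to-right yields the longest trimmed adapter, matching common trimmer
behavior. Insert length is the adapter offset minus the UMI length, floored
at 0. Both parameters are configurable (`min_adapter_overlap`,
`max_adapter_error_rate`).

Paired-end insert sizes come from overlap fusion: read 2 is
reverse-complemented and slid along read 1 over non-negative offsets; among
admissible overlaps (≥ 10 nt, mismatch fraction ≤ 0.25) the one with the
most matching positions wins, ties toward the longer overlap; disagreeing
bases take the higher quality call, ties to read 1. Fused length minus the
UMI (read 1 only carries one) is the insert. Dovetailing pairs — insert +
UMI shorter than the read length, so the mates read through each other's
adapters — are not fused and fall into the unfused pool; at the read lengths
and insert distributions this targets they are rare, and such short inserts
are visible via the single-end path anyway.

**Degradation ratio** = Σ counts[10..20] / Σ counts[30..40], both ranges
inclusive. ("Between 10 and 20" is ambiguous at the endpoints; inclusive
was fixed so the metric is exactly reproducible.) When the 30–40 sum is
zero the ratio is reported as +inf if 10–20 nt fragments exist (a totally
degraded library — still unambiguously "above 1") and as not-computable
when both sums are zero (e.g. no adapter-containing reads at all).

**Adapter-adapter products** are adapter-containing reads with insert
< `min_insert_length` (default 3 nt, following the "fewer than three
nucleotides" convention; a 2-nt reading also circulates, so the flag is
exposed).

**Deduplication** keys on the full sequence string (UMI included — it is
removed only afterwards), first occurrence wins, qualities ignored. The
pipeline order is: adapter removal (dropping adapter-adapter products) →
exact dedup → UMI trim (read-1 class only) → reverse complementation →
re-pairing by identifier for paired data.

## Alignment accounting and filtering

Serial (decoy-first) alignment statistics are bookkeeping over per-stage
counts: each stage consumes its aligned reads from the pool, the rRNA rate
is the rDNA stage's aligned count over the trimmed count (stage matched by
name containing "rdna"/"rrna", else the first stage, since decoy alignment
conventionally begins with rDNA), total efficiency is MAPQ-passing reads
over raw reads, and read depth is MAPQ-passing reads × mean kept read
length / genome size (mean read length is not otherwise specified, so it is
computed from the kept alignments). Primary-alignment filtering keeps
mapped, primary (secondary/supplementary excluded before the MAPQ check),
MAPQ ≥ 10, read-1-only records, then splits by strand.

## Metric definitions and edge policies

**Exon:intron ratio.** Per gene with ≥ 2 exons and ≥ 1 intron:
exon RPKM over exons excluding the first exon in transcription direction
(the max-coordinate exon on minus-strand genes), intron RPKM over all
introns; RPKM uses the total filtered aligned reads of the sample (the
per-million factors cancel in the ratio but are carried for output
fidelity). Genes with zero intron reads get a NaN ratio and are excluded
from the median.

**Pause index.** Candidate windows are `[TSS+20, TSS+120)` per annotated
TSS isoform (mirrored on minus strands so the window covers offsets 20–119
downstream in transcription direction in both cases). The predominant
window maximizes sense 3′-end density; ties go to the TSS nearest the gene
5′ end, then the smaller coordinate, so output is bit-stable. Body =
`[predominant TSS + 500, gene end)` in transcription direction. Genes with
an empty body, zero body reads or zero window reads are excluded — with
per-cause counts reported — rather than carried as 0 or infinity. Surviving
genes are ranked by expression (total sense 3′ ends in the span; "by
expression" is otherwise undefined, and the span total is depth-robust) and
the upper 50th percentile kept (threshold inclusive, so lowering the
percentile never drops genes).

**TSS enrichment.** Profile `p[−2000..2000]` sums 3′ ends of both read
strands around each usable TSS (full flank required; minus-strand TSSs
mirrored). Summit = argmax, ties to smallest |offset| then the upstream
side. Score = mean over the 100-nt window centered at the summit, divided
by the pooled mean of the two 100-nt edge windows with a +1 pseudocount on
their summed counts (so an empty background cannot divide by zero). The
score is scale-invariant up to the pseudocount, i.e. effectively invariant
once edge windows hold ≥ ~10 counts/position.

**FRiF.** Cumulative: each 3′ end (both strands) is assigned to every
overlapping element of a class; elements sort by read count descending
(ties: larger element, then coordinate) and the curve accumulates
(log10 cumulative size, cumulative reads / total aligned reads). The
denominator stays the total read count, so a class's final fraction can
reach but not exceed 1 for disjoint elements. Non-cumulative:
`log10(observed / expected)` where observed = read bases overlapping the
class's merged intervals and expected = total aligned bases × class size /
genome size — i.e. "expected" is read-base-proportional under a uniform
genome-wide placement model. This is one reading of an under-specified
quantity; it is the natural null for base-level coverage, but other
normalizations exist, so treat cross-tool comparisons of this score with
care. Zero observed bases reports −inf.

**Complexity.** A seeded permutation of the library is prefix-sampled at
fractions 0.1..1.0 (sampling without replacement), counting distinct
sequences; percent-unique is evaluated at min(10 M, library size). Without
UMIs identical sequences cannot be distinguished from identical-end
independent molecules, so the function refuses rather than mislead.
Extrapolation beyond observed depth is out of scope.

**Gene counts.** Sense 3′ ends within the gene span, one column per sample
— deliberately simple, as input for downstream differential analysis.

## Signal tracks

Strand-split 3′-end (or 5′-end) counts at single-nucleotide resolution;
optional per-million scaling (×1e6/N); optional centered moving average of
odd width (default 25 nt — the kernel and width are this package's choice,
exposed in config; window 1 is the identity). bedGraph text is the
canonical serialization (runs of equal value merged, lexicographic chrom
order); values round-trip exactly. Enzymatic sequence-bias correction
(k-mer/mappability reweighting) is out of scope; the CLI reserves a flag
that fails loudly.

## The synthetic generator

`make_toy_annotation(n_genes, seed)` builds one main chromosome of
`n_genes` × 5 kb slots with 2.5-kb margins (every TSS keeps a full ±2-kb
flank) plus a 2-kb rDNA decoy chromosome. Each gene: a 4.8-kb span, 2–4
exons with ≥ 1 intron, 1–3 TSS isoforms ≥ 200 nt apart within the first
800 nt, leaving ≥ 1.5 kb of body beyond every TSS+500. Feature classes
(promoter = primary TSS ± 250 nt, flanking ±250–1000 nt, UTRs = terminal
exons, exons, introns, intergenic enhancers) derive from the same
structures.

`simulate_library(params, annotation)` renders reads in the single-end
layout above (paired mode adds a mate-2 adapter and reverse-complemented
mate). Truth classes are drawn with deterministic counts — floor(fraction ×
n_originals) per class, remainder to `body` — so recovery tests are exact;
only positions, insert lengths and UMIs are random, all from one seed
(byte-reproducible output). Placement: `pause` ends uniform over the
+20..+119 window of the gene's 5′-most TSS; `body` ends uniform over the
whole gene span (this is the background model that makes the
no-contamination exon:intron ratio ≈ 1 and gives unpaused libraries a
finite pause index ≈ 1); `mrna` ends uniform over non-first exons; `rrna`
uniform on the decoy; `adapter_adapter` inserts of 0–2 nt with no genomic
origin. Insert lengths are round(Normal(mean, sd)) floored at 3 for genomic
classes — the floor keeps class identity well-defined, since inserts < 3
*define* the adapter-adapter class. Duplicates are exact sequence copies of
seeded-random originals; originals are guaranteed sequence-distinct (UMI
redrawn on collision, possible whenever a UMI is configured), so exact
deduplication recovers the duplicate count exactly. Truth alignments are
emitted as BED so metric tests can skip real alignment.

What the generator does **not** model: sequencing errors by default (an
optional per-base error rate exists but defaults to 0 so histogram recovery
is exact), base-composition or ligation bias, polymerase kinetics,
quality-score variation, multi-mapping, or annotation noise. Passing tests
therefore demonstrate the correctness of the metric computations and their
qualitative behavior under controlled composition shifts — not performance
on real data, where annotation mismatch and mappability dominate.

## Problem sizes and test anchors

The standard test conditions are 50 toy genes (~255 kb genome) with 20k
reads for metric-level checks, 10k reads for insert-size conditions, and
1–2k reads on 5-gene genomes for oracle-equivalence suites; the
depth-robustness check uses a 50k-read library so its 10% subsample is
still informative per gene. Intact libraries use insert ~ Normal(38, 4) —
a typical size-selected run-on insert — and degraded ones Normal(15, 3);
the degradation sweep uses sd 6 so both tails of the distribution are
populated across the whole 38→15 mean range. The simulated "efficient"
condition places 70% of 3′ ends in pause windows, matching the spike-in
style designs the metrics are meant to resolve.

## Known limitations

* Adapter localization is exact-scan with a mismatch cap, not
  indel-tolerant; inserts longer than read − UMI − 3 are invisible to the
  single-end histogram (as with any adapter-based method).
* Pair fusion ignores dovetail geometries (see above).
* The non-cumulative FRiF "expected bases" definition is one of several
  possible normalizations.
* The exon:intron recommended band (1.0–1.8) is calibrated for real
  annotated genomes; idealized uniform simulations sit slightly below 1
  (ratio-of-counts bias), so the flag — not the metric — can read `fail`
  on perfectly neutral synthetic data.
* Serial-alignment statistics are bookkeeping over supplied counts; the
  package never runs an aligner and cannot detect inconsistencies beyond
  sequential-consumption arithmetic.
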