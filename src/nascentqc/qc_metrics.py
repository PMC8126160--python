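"""Quality-control metrics for nascent-RNA libraries.

All metrics operate on filtered, strand-assigned alignments and treat the
read 3' end as the read's location (the polymerase active-site position),
consistent with the signal tracks.  Gene-level metrics use sense-strand
reads only; the aggregate TSS profile uses both strands, so the divergent
upstream peak characteristic of run-on data is visible.

Implemented here:

* exon:intron density ratio — the mRNA-contamination metric.  A nascent
  library has near-equal exonic and intronic read density per gene (ratio
  ~1); mature-mRNA contamination inflates it.  The first exon is excluded
  because promoter-proximal pausing would otherwise inflate the ratio.
* pause index — density in the most dense +20..+120 window over any
  annotated TSS isoform, divided by gene-body density (TSS+500 to gene
  end), restricted to the upper half of genes by expression.
* TSS enrichment score — summit-window over edge-window coverage of the
  aggregate +/-2000 bp TSS profile.
* cumulative and non-cumulative fraction-of-reads-in-features (FRiF).
* library-complexity points by seeded subsampling.
* a per-gene counts table for downstream differential expression.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_accounting import AlignedRead
from .read_preproc import Read

__all__ = [
    "GeneModel",
    "PauseIndexRecord",
    "FeatureClass",
    "FrifCurve",
    "EndIndex",
    "read_density",
    "exon_intron_ratios",
    "pause_indices",
    "tss_enrichment",
    "cumulative_frif",
    "noncumulative_frif",
    "complexity_points",
    "gene_counts",
    "load_gene_models_refflat",
    "write_gene_models_refflat",
    "load_feature_classes_bed",
    "write_feature_classes_bed",
]

FEATURE_CLASS_NAMES = (
    "enhancer",
    "promoter",
    "promoter_flanking",
    "5UTR",
    "3UTR",
    "exon",
    "intron",
)


# ---------------------------------------------------------------------------
# Gene models and annotation I/O
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene: strand, all annotated TSS isoform positions, exon
    structure, and the overall span (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    tss_list: list[int]
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        start, end = self.span
        if start >= end:
            raise ValueError(f"{self.gene_id}: empty span")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in self.exons:
            if s < start or e > end:
                raise ValueError(f"{self.gene_id}: exon outside span")
        for tss in self.tss_list:
            if not (start <= tss < end):
                raise ValueError(f"{self.gene_id}: TSS {tss} outside span")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Complement of the exons within the span."""
        introns = []
        cursor = self.span[0]
        for s, e in self.exons:
            if s > cursor:
                introns.append((cursor, s))
            cursor = e
        if cursor < self.span[1]:
            introns.append((cursor, self.span[1]))
        return introns

    @property
    def first_exon(self) -> tuple[int, int]:
        """The exon 5'-most in transcription direction."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def non_first_exons(self) -> list[tuple[int, int]]:
        first = self.first_exon
        return [e for e in self.exons if e != first]

    @property
    def tss_5prime(self) -> int:
        """The 5'-most annotated TSS in transcription direction."""
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)


def load_gene_models_refflat(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like table (geneName, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds; comma-separated exon lists).  Multiple rows per
    gene define TSS isoforms; the exon structure is taken from the row whose
    TSS is 5'-most and the span is the union of rows."""
    rows: dict[str, list[tuple[str, str, int, int, list[int], list[int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            name, chrom, strand, tx_start, tx_end, ex_starts, ex_ends = fields[:7]
            starts = [int(x) for x in ex_starts.rstrip(",").split(",")]
            ends = [int(x) for x in ex_ends.rstrip(",").split(",")]
            rows.setdefault(name, []).append(
                (chrom, strand, int(tx_start), int(tx_end), starts, ends)
            )
    genes = []
    for gene_id, isoforms in rows.items():
        chrom, strand = isoforms[0][0], isoforms[0][1]
        span = (min(r[2] for r in isoforms), max(r[3] for r in isoforms))
        tss_list = sorted(
            {r[2] if strand == "+" else r[3] - 1 for r in isoforms}
        )
        primary = min(
            isoforms,
            key=lambda r: (r[2] if strand == "+" else -(r[3] - 1)),
        )
        exons = list(zip(primary[4], primary[5]))
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=chrom, strand=strand,
                span=span, tss_list=tss_list, exons=exons,
            )
        )
    return genes


def write_gene_models_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    """One row per TSS isoform; the exon structure is repeated per row."""
    with open(path, "w") as fh:
        for gene in genes:
            ex_starts = ",".join(str(s) for s, _ in gene.exons) + ","
            ex_ends = ",".join(str(e) for _, e in gene.exons) + ","
            for tss in gene.tss_list:
                if gene.strand == "+":
                    tx_start, tx_end = tss, gene.span[1]
                else:
                    tx_start, tx_end = gene.span[0], tss + 1
                fh.write(
                    f"{gene.gene_id}\t{gene.chrom}\t{gene.strand}\t{tx_start}"
                    f"\t{tx_end}\t{ex_starts}\t{ex_ends}\n"
                )


@dataclass
class FeatureClass:
    """A named class of genomic features (BED intervals, possibly
    overlapping)."""

    name: str
    intervals: list[tuple[str, int, int]]

    def merged(self) -> list[tuple[str, int, int]]:
        """Union of the intervals (per chromosome, overlaps merged)."""
        merged: list[tuple[str, int, int]] = []
        for chrom, s, e in sorted(self.intervals):
            if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], e))
            else:
                merged.append((chrom, s, e))
        return merged

    def merged_size(self) -> int:
        return sum(e - s for _, s, e in self.merged())


def load_feature_classes_bed(path: str | Path) -> dict[str, FeatureClass]:
    """Read a feature-annotation BED with the class name in column 4."""
    classes: dict[str, FeatureClass] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            cls = classes.setdefault(name, FeatureClass(name=name, intervals=[]))
            cls.intervals.append((chrom, int(start), int(end)))
    return classes


def write_feature_classes_bed(
    classes: Iterable[FeatureClass], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for cls in classes:
            for chrom, start, end in cls.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{cls.name}\n")


# ---------------------------------------------------------------------------
# Shared read-end index
# ---------------------------------------------------------------------------

class EndIndex:
    """Sorted per-(chrom, strand) arrays of read 3' ends for O(log n)
    interval counting."""

    def __init__(self, alignments: Iterable[AlignedRead]):
        ends: dict[tuple[str, str], list[int]] = {}
        self.n_alignments = 0
        self.total_aligned_bases = 0
        length_sum = 0
        for aln in alignments:
            ends.setdefault((aln.chrom, aln.strand), []).append(aln.three_prime)
            self.n_alignments += 1
            length_sum += aln.length
        self.total_aligned_bases = length_sum
        self.mean_read_length = length_sum / self.n_alignments if self.n_alignments else 0.0
        self._ends = {k: sorted(v) for k, v in ends.items()}

    def count(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> int:
        """Number of 3' ends x with start <= x < end, optionally restricted
        to one strand."""
        strands = [strand] if strand else ["+", "-"]
        total = 0
        for s in strands:
            arr = self._ends.get((chrom, s))
            if arr:
                total += bisect_left(arr, end) - bisect_left(arr, start)
        return total

    def positions(self, chrom: str, strand: str) -> list[int]:
        return self._ends.get((chrom, strand), [])


def read_density(
    alignments: Iterable[AlignedRead] | EndIndex,
    chrom: str,
    interval: tuple[int, int],
    strand: str | None = None,
) -> float:
    """Read-3'-end density (ends per nucleotide) in a half-open interval,
    optionally sense-restricted."""
    start, end = interval
    if end <= start:
        raise ValueError("interval must have positive length")
    index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
    return index.count(chrom, start, end, strand) / (end - start)


# ---------------------------------------------------------------------------
# Exon:intron contamination
# ---------------------------------------------------------------------------

def _rpkm(n_reads: int, size_bp: int, n_total: int) -> float:
    return n_reads / (size_bp / 1e3) / (n_total / 1e6)


def exon_intron_ratios(
    alignments: Iterable[AlignedRead] | EndIndex,
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, float]:
    """Per-gene exon:intron RPKM ratio (first exon excluded) and the median
    — the mRNA-contamination metric.

    Sense-strand 3' ends only.  Genes need at least two exons and one
    intron; genes with zero intron reads are excluded from the median (the
    ratio is reported as NaN).  Returns (table, median).
    """
    index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
    if index.n_alignments == 0:
        raise ValueError("no alignments")
    n_total = index.n_alignments
    records = []
    for gene in genes:
        if len(gene.exons) < 2 or not gene.introns:
            continue
        exons = gene.non_first_exons
        exon_size = sum(e - s for s, e in exons)
        intron_size = sum(e - s for s, e in gene.introns)
        exon_reads = sum(
            index.count(gene.chrom, s, e, gene.strand) for s, e in exons
        )
        intron_reads = sum(
            index.count(gene.chrom, s, e, gene.strand) for s, e in gene.introns
        )
        exon_rpkm = _rpkm(exon_reads, exon_size, n_total)
        intron_rpkm = _rpkm(intron_reads, intron_size, n_total)
        ratio = exon_rpkm / intron_rpkm if intron_reads > 0 else math.nan
        records.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": gene.span[0],
                "end": gene.span[1],
                "strand": gene.strand,
                "exon_reads": exon_reads,
                "intron_reads": intron_reads,
                "exon_rpkm": exon_rpkm,
                "intron_rpkm": intron_rpkm,
                "ratio": ratio,
            }
        )
    if not records:
        raise ValueError(
            "no scoreable genes: every gene lacks a non-first exon or an intron"
        )
    table = pd.DataFrame.from_records(records)
    median = float(table["ratio"].dropna().median())
    return table, median


def write_ratio_bed(table: pd.DataFrame, path: str | Path) -> None:
    """Per-gene BED6 with the ratio (or pause index) in the score column."""
    value_col = "pause_index" if "pause_index" in table.columns else "ratio"
    with open(path, "w") as fh:
        for row in table.itertuples():
            value = getattr(row, value_col)
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}"
                f"\t{'NA' if pd.isna(value) else round(value, 6)}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# Pause index
# ---------------------------------------------------------------------------

PAUSE_WINDOW_OFFSET = 20
PAUSE_WINDOW_LENGTH = 100
BODY_OFFSET = 500


@dataclass
class PauseIndexRecord:
    gene_id: str
    predominant_tss: int
    pause_window: tuple[int, int]
    pause_density: float
    body_density: float
    pause_index: float


def _pause_window(tss: int, strand: str) -> tuple[int, int]:
    """The +20..+120 window downstream of a TSS in transcription
    direction, as genomic half-open coordinates."""
    if strand == "+":
        return (tss + PAUSE_WINDOW_OFFSET, tss + PAUSE_WINDOW_OFFSET + PAUSE_WINDOW_LENGTH)
    return (tss - PAUSE_WINDOW_OFFSET - PAUSE_WINDOW_LENGTH + 1, tss - PAUSE_WINDOW_OFFSET + 1)


def _body_interval(gene: GeneModel, tss: int) -> tuple[int, int]:
    """Gene body: 500 nt downstream of the predominant TSS to the gene end
    (transcription direction); may be empty."""
    if gene.strand == "+":
        return (tss + BODY_OFFSET, gene.span[1])
    return (gene.span[0], tss - BODY_OFFSET + 1)


def pause_indices(
    alignments: Iterable[AlignedRead] | EndIndex,
    genes: Sequence[GeneModel],
    expression_percentile: float = 50.0,
) -> tuple[pd.DataFrame, float, dict[str, int]]:
    """Per-gene pause indices and their median.

    For each gene the candidate pause windows are the +20..+120 regions of
    every annotated TSS isoform; the predominant window is the one with the
    highest sense-strand 3'-end density (ties to the TSS nearest the gene 5'
    end, then the smaller coordinate).  The body runs from 500 nt past the
    predominant TSS to the gene end.  Genes with an empty body, zero body
    reads or zero pause-window reads are excluded (counted in the third
    return value); the remainder are ranked by expression (total sense ends
    in the span) and only the upper ``expression_percentile`` percent kept.

    Returns (table, median pause index, exclusion counts).
    """
    index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
    excluded = {"no_tss": 0, "empty_body": 0, "no_body_reads": 0, "no_window_reads": 0}
    records = []
    expressions = []
    for gene in genes:
        if not gene.tss_list:
            excluded["no_tss"] += 1
            continue
        best: tuple[float, float, int] | None = None  # (density, -5'dist, -tss)
        for tss in gene.tss_list:
            win = _pause_window(tss, gene.strand)
            density = index.count(gene.chrom, win[0], win[1], gene.strand) / PAUSE_WINDOW_LENGTH
            dist_5p = abs(tss - gene.tss_5prime)
            cand = (density, -dist_5p, -tss)
            if best is None or cand > best:
                best = cand
                best_tss, best_win = tss, win
        pause_density = best[0]
        body = _body_interval(gene, best_tss)
        if body[1] <= body[0]:
            excluded["empty_body"] += 1
            continue
        body_reads = index.count(gene.chrom, body[0], body[1], gene.strand)
        if body_reads == 0:
            excluded["no_body_reads"] += 1
            continue
        if pause_density == 0:
            excluded["no_window_reads"] += 1
            continue
        body_density = body_reads / (body[1] - body[0])
        records.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "start": gene.span[0],
                "end": gene.span[1],
                "strand": gene.strand,
                "predominant_tss": best_tss,
                "window_start": best_win[0],
                "window_end": best_win[1],
                "pause_density": pause_density,
                "body_density": body_density,
                "pause_index": pause_density / body_density,
            }
        )
        expressions.append(
            index.count(gene.chrom, gene.span[0], gene.span[1], gene.strand)
        )
    if not records:
        raise ValueError(f"all genes excluded from pause index: {excluded}")
    table = pd.DataFrame.from_records(records)
    table["expression"] = expressions
    threshold = float(np.percentile(table["expression"], expression_percentile))
    table = table[table["expression"] >= threshold].reset_index(drop=True)
    median = float(table["pause_index"].median())
    return table, median, excluded


# ---------------------------------------------------------------------------
# TSS enrichment
# ---------------------------------------------------------------------------

TSS_FLANK = 2000
TSS_SCORE_WINDOW = 100


def tss_enrichment(
    alignments: Iterable[AlignedRead] | EndIndex,
    tss_set: Sequence[tuple[str, int, str]],
    chrom_sizes: dict[str, int],
    flank: int = TSS_FLANK,
    window: int = TSS_SCORE_WINDOW,
) -> tuple[np.ndarray, float]:
    """Aggregate +/-``flank`` 3'-end profile over a TSS reference set and
    the enrichment score.

    Reads of both strands contribute (so divergent upstream transcription
    is visible); minus-strand TSSs are mirrored so positive offsets always
    point downstream.  TSSs whose full flank exceeds the chromosome are
    skipped.  The score is the mean profile over the ``window`` positions
    centered at the summit, divided by the mean over the two edge windows
    (pooled, with a +1 pseudocount on their summed counts).

    Returns (profile array of length 2*flank+1 for offsets -flank..+flank,
    score).
    """
    index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
    profile = np.zeros(2 * flank + 1)
    n_used = 0
    for chrom, tss, strand in tss_set:
        if tss - flank < 0 or tss + flank >= chrom_sizes.get(chrom, 0):
            continue
        n_used += 1
        for read_strand in "+-":
            for pos in index.positions(chrom, read_strand):
                offset = pos - tss
                if -flank <= offset <= flank:
                    if strand == "-":
                        offset = -offset
                    profile[offset + flank] += 1
    if n_used == 0:
        raise ValueError("no TSS with a full flank inside its chromosome")

    # summit: max value; ties to the smallest |offset|, then the negative side
    peak = profile.max()
    candidates = np.nonzero(profile == peak)[0] - flank
    summit = int(min(candidates, key=lambda o: (abs(o), o)))

    half = window // 2
    lo = max(summit - (half - 1), -flank)
    hi = min(summit + half, flank)
    numerator = float(profile[lo + flank : hi + flank + 1].mean())
    edge_sum = float(profile[:window].sum() + profile[-window:].sum())
    denominator = (edge_sum + 1.0) / (2 * window)
    return profile, numerator / denominator


# ---------------------------------------------------------------------------
# Fraction of reads in features
# ---------------------------------------------------------------------------

@dataclass
class FrifCurve:
    feature_name: str
    points: list[tuple[float, float]] = field(default_factory=list)  # (log10 cumul size, cumul fraction)
    nc_score: float | None = None

    def final_fraction(self) -> float:
        return self.points[-1][1] if self.points else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["log10_cumulative_size", "cumulative_fraction"]
        )


def cumulative_frif(
    alignments: Iterable[AlignedRead] | EndIndex,
    feature_classes: dict[str, FeatureClass],
    genome_size: int | None = None,
) -> dict[str, FrifCurve]:
    """Cumulative FRiF curve per feature class.

    Each alignment's 3' end is assigned to every overlapping element of the
    class (both strands; the fraction denominator stays the total aligned
    read count).  Elements are sorted by read count descending (ties: larger
    element, then coordinate) and the curve accumulates (log10 cumulative
    element size, cumulative read fraction).  An empty class yields a flat
    curve at zero.
    """
    index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
    if index.n_alignments == 0:
        raise ValueError("no aligned reads")
    n_total = index.n_alignments
    curves: dict[str, FrifCurve] = {}
    for name, cls in feature_classes.items():
        elements = []
        for chrom, s, e in cls.intervals:
            n = index.count(chrom, s, e)
            elements.append((n, e - s, (chrom, s, e)))
        elements.sort(key=lambda t: (-t[0], -t[1], t[2]))
        curve = FrifCurve(feature_name=name)
        cum_size = 0
        cum_reads = 0
        for n, size, _ in elements:
            cum_size += size
            cum_reads += n
            curve.points.append(
                (math.log10(cum_size) if cum_size else 0.0, cum_reads / n_total)
            )
        curves[name] = curve
    return curves


def noncumulative_frif(
    alignments: Iterable[AlignedRead],
    feature_class: FeatureClass,
    genome_size: int,
) -> float:
    """Non-cumulative FRiF: log10 of observed read bases covered by the
    class over the bases expected if read bases fell uniformly on the
    genome.

    observed = sum over alignments of bases overlapping the class's merged
    intervals; expected = total aligned bases x (merged class size /
    genome size).  Returns -inf when no read base touches the class.
    """
    merged = feature_class.merged()
    class_size = sum(e - s for _, s, e in merged)
    if class_size == 0:
        raise ValueError(f"feature class {feature_class.name!r} has zero size")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts = {c: [s for s, _ in ivs] for c, ivs in by_chrom.items()}

    observed = 0
    total_bases = 0
    n_alignments = 0
    for aln in alignments:
        n_alignments += 1
        total_bases += aln.length
        ivs = by_chrom.get(aln.chrom)
        if not ivs:
            continue
        # merged intervals are disjoint and sorted; scan the overlap range
        i = bisect_right(starts[aln.chrom], aln.start) - 1
        i = max(i, 0)
        for s, e in ivs[i:]:
            if s >= aln.end:
                break
            observed += max(0, min(aln.end, e) - max(aln.start, s))
    if total_bases == 0:
        raise ValueError("no aligned bases")
    expected = total_bases * class_size / genome_size
    if observed == 0:
        return -math.inf
    return math.log10(observed / expected)


# ---------------------------------------------------------------------------
# Library complexity
# ---------------------------------------------------------------------------

DEFAULT_DEPTH_REF = 10_000_000


def complexity_points(
    raw_reads: Sequence[Read],
    umi_length: int,
    fractions: Sequence[float] = tuple(f / 10 for f in range(1, 11)),
    depth_ref: int = DEFAULT_DEPTH_REF,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Library-complexity curve by seeded subsampling without replacement.

    Distinct full sequences (UMI still attached) approximate distinct
    molecules, so the metric is only meaningful — and only computed — for
    UMI-bearing libraries.  Returns (curve with columns n_sampled/n_unique,
    percent unique at min(depth_ref, library size)).
    """
    if umi_length <= 0:
        raise ValueError(
            "library complexity requires UMIs: without them PCR duplicates "
            "cannot be distinguished from independent molecules with "
            "identical ends"
        )
    if not raw_reads:
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    n = len(raw_reads)
    order = rng.permutation(n)
    sequences = [raw_reads[i].sequence for i in order]
    rows = []
    for f in fractions:
        k = int(round(f * n))
        rows.append({"fraction": f, "n_sampled": k,
                     "n_unique": len(set(sequences[:k]))})
    curve = pd.DataFrame(rows)
    depth = min(depth_ref, n)
    n_unique_at_depth = len(set(sequences[:depth]))
    pct_unique = 100.0 * n_unique_at_depth / depth
    return curve, pct_unique


# ---------------------------------------------------------------------------
# Gene counts table
# ---------------------------------------------------------------------------

def gene_counts(
    sample_alignments: dict[str, Iterable[AlignedRead] | EndIndex],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Counts table (genes x samples): sense-strand 3' ends within each
    gene span.  Input for downstream differential expression."""
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"duplicate gene_ids: {dupes}")
    columns = {}
    for sample, alignments in sample_alignments.items():
        index = alignments if isinstance(alignments, EndIndex) else EndIndex(alignments)
        columns[sample] = [
            index.count(g.chrom, g.span[0], g.span[1], g.strand) for g in genes
        ]
    return pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
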