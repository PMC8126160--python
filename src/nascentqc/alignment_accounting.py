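"""Serial-alignment accounting and alignment filtering.

Run-on pipelines siphon off unwanted reads by aligning serially to decoy
references (rDNA first, optionally mtDNA and others) before the primary
genome.  Alignment itself happens outside this package; here we consume
either per-stage counts or SAM/BAM streams and compute the bookkeeping:
per-stage alignment rates, the rRNA alignment rate (a nascent-purity proxy
— mature RNA is 70-80% rRNA), total alignment efficiency, and read depth.

Primary alignments are filtered (mapped, primary, MAPQ >= 10 by default,
read1 only for paired-end data) and split by strand, the form every
downstream metric consumes.  Coordinates are normalized to 0-based half-open
regardless of the source format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "AlignedRead",
    "SerialAlignmentStats",
    "FilterCounts",
    "tally_serial_alignment",
    "filter_and_split_alignments",
    "read_alignments_sam",
    "read_alignments_bed6",
    "write_alignments_bed6",
]

DEFAULT_MAPQ_MIN = 10

# Documented defaults of the external aligner invocations, carried for
# provenance only — this package never runs an aligner.
SERIAL_ALIGNER_ARGS = "-k 1 -D 20 -R 3 -N 1 -L 20 -i S,1,0.50"
PRIMARY_ALIGNER_ARGS = "--very-sensitive"
PRIMARY_MAX_FRAGMENT = 2000


@dataclass(frozen=True)
class AlignedRead:
    """A stranded genomic interval with defined 5'/3' ends (0-based,
    half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    is_read1: bool = True
    mapq: int = 255
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name or self.chrom}: start >= end")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SerialAlignmentStats:
    n_raw: int
    n_trimmed: int
    per_stage: list[tuple[str, int, float]]  # (stage, n_aligned, rate vs stage input)
    n_primary_aligned: int
    n_pass_mapq: int
    rrna_rate: float | None
    total_efficiency: float
    read_depth: float

    def as_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_trimmed": self.n_trimmed,
            "per_stage": [
                {"stage": s, "n_aligned": n, "rate": r} for s, n, r in self.per_stage
            ],
            "n_primary_aligned": self.n_primary_aligned,
            "n_pass_mapq": self.n_pass_mapq,
            "rrna_rate": self.rrna_rate,
            "total_efficiency": self.total_efficiency,
            "read_depth": self.read_depth,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            d = self.as_dict()
            for stage in d.pop("per_stage"):
                fh.write(f"aligned_{stage['stage']}\t{stage['n_aligned']}\n")
            for key, value in d.items():
                fh.write(f"{key}\t{'NA' if value is None else value}\n")


def _is_rdna_stage(name: str) -> bool:
    lowered = name.lower()
    return "rdna" in lowered or "rrna" in lowered


def tally_serial_alignment(
    n_raw: int,
    n_trimmed: int,
    stage_counts: Iterable[tuple[str, int]],
    n_primary_aligned: int,
    n_pass_mapq: int,
    genome_size: int,
    mean_read_length: float | None = None,
) -> SerialAlignmentStats:
    """Compute the serial-alignment statistics.

    Stages consume reads sequentially: stage k's input is the trimmed count
    minus everything earlier stages aligned.  ``rrna_rate`` is the rDNA
    stage's aligned count over the trimmed count (stage matched by name,
    falling back to the first stage — decoy alignment conventionally starts
    with rDNA); None when there are no serial stages.  ``total_efficiency``
    is MAPQ-passing reads out of raw reads; ``read_depth`` is MAPQ-passing
    reads x mean read length / genome size.
    """
    stage_counts = list(stage_counts)
    if min([n_raw, n_trimmed, n_primary_aligned, n_pass_mapq] +
           [n for _, n in stage_counts], default=0) < 0:
        raise ValueError("counts must be non-negative")
    if n_trimmed > n_raw or n_pass_mapq > n_primary_aligned:
        raise ValueError("inconsistent counts: expected n_pass_mapq <= "
                         "n_primary_aligned <= n_trimmed <= n_raw")
    per_stage: list[tuple[str, int, float]] = []
    remaining = n_trimmed
    for stage, n_aligned in stage_counts:
        if n_aligned > remaining:
            raise ValueError(
                f"stage {stage!r} aligned {n_aligned} reads but only "
                f"{remaining} entered it"
            )
        per_stage.append((stage, n_aligned, n_aligned / remaining if remaining else 0.0))
        remaining -= n_aligned
    if n_primary_aligned > remaining:
        raise ValueError("primary alignment consumed more reads than remained "
                         "after serial stages")

    rrna_rate: float | None = None
    if stage_counts:
        named = [n for s, n in stage_counts if _is_rdna_stage(s)]
        n_rdna = named[0] if named else stage_counts[0][1]
        rrna_rate = n_rdna / n_trimmed if n_trimmed else 0.0

    if mean_read_length is None:
        mean_read_length = 0.0
    return SerialAlignmentStats(
        n_raw=n_raw,
        n_trimmed=n_trimmed,
        per_stage=per_stage,
        n_primary_aligned=n_primary_aligned,
        n_pass_mapq=n_pass_mapq,
        rrna_rate=rrna_rate,
        total_efficiency=n_pass_mapq / n_raw if n_raw else 0.0,
        read_depth=n_pass_mapq * mean_read_length / genome_size if genome_size else 0.0,
    )


@dataclass
class FilterCounts:
    n_records: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_read2: int = 0
    n_low_mapq: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_alignments_sam(path: str | Path) -> Iterator[tuple]:
    """Yield raw pysam records from a SAM/BAM file (filtering happens in
    :func:`filter_and_split_alignments`)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        yield from fh.fetch(until_eof=True)


def filter_and_split_alignments(
    alignments: Iterable,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> tuple[list[AlignedRead], list[AlignedRead], FilterCounts]:
    """Filter a SAM/BAM record stream and partition by strand.

    Keeps records that are mapped, primary (secondary and supplementary
    records are excluded before the MAPQ check), MAPQ >= ``mapq_min``, and —
    for paired data — read1 only.  Records may also be :class:`AlignedRead`
    instances (e.g. from BED input), filtered on their ``mapq`` field.
    """
    plus: list[AlignedRead] = []
    minus: list[AlignedRead] = []
    counts = FilterCounts()
    for rec in alignments:
        counts.n_records += 1
        if isinstance(rec, AlignedRead):
            if not rec.is_read1:
                counts.n_read2 += 1
                continue
            if rec.mapq < mapq_min:
                counts.n_low_mapq += 1
                continue
            aln = rec
        else:  # pysam.AlignedSegment
            if rec.is_unmapped:
                counts.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                counts.n_secondary += 1
                continue
            if rec.is_paired and rec.is_read2:
                counts.n_read2 += 1
                continue
            if rec.mapping_quality < mapq_min:
                counts.n_low_mapq += 1
                continue
            aln = AlignedRead(
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                is_read1=True,
                mapq=rec.mapping_quality,
                name=rec.query_name,
            )
        counts.n_kept += 1
        (minus if aln.strand == "-" else plus).append(aln)
    return plus, minus, counts


def read_alignments_bed6(path: str | Path) -> Iterator[AlignedRead]:
    """Read alignments from 6-column BED (chrom, start, end, name, mapq,
    strand); the score column is interpreted as MAPQ."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, end, name, score, strand = fields[:6]
            yield AlignedRead(
                chrom=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                mapq=int(score),
                name=name,
            )


def write_alignments_bed6(alignments: Iterable[AlignedRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(
                f"{aln.chrom}\t{aln.start}\t{aln.end}\t{aln.name or '.'}"
                f"\t{aln.mapq}\t{aln.strand}\n"
            )
            n += 1
    return n
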