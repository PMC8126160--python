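"""Raw-read preprocessing for run-on sequencing libraries.

Run-on protocols (PRO-seq, GRO-seq, ChRO-seq) ligate a 3' adapter — carrying a
unique molecular identifier (UMI) — directly onto the nascent RNA 3' end, so a
single-end read has the layout ``insert + UMI + adapter`` on the sequenced
strand.  Everything this module computes falls out of locating that adapter:

* insert-size histograms (single-end directly; paired-end by overlap-fusing the
  mates first, FLASH-style);
* the degradation ratio — reads of 10-20 nt versus 30-40 nt.  RNA shorter than
  ~20 nt is sterically protected inside the polymerase, so an excess of short
  inserts means the RNA was degraded *after* the run-on;
* the adapter-adapter ligation fraction (inserts shorter than 3 nt are two
  adapters ligated with no RNA between them);
* exact-sequence PCR deduplication (the UMI is still part of the sequence at
  this stage, so identical sequences are PCR copies);
* the processed-read emitter: adapter removal, dedup, UMI trim, reverse
  complementation (the sequencer reads the nascent RNA 3'->5').
"""

from __future__ import annotations

import gzip
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Read",
    "PreprocConfig",
    "FragmentLengthHistogram",
    "DedupResult",
    "PreprocStats",
    "InvalidRecordError",
    "read_fastq",
    "write_fastq",
    "reverse_complement",
    "locate_adapter",
    "insert_size_histogram_single",
    "fuse_read_pair",
    "insert_size_histogram_paired",
    "degradation_ratio",
    "adapter_ligation_fraction",
    "deduplicate_exact",
    "preprocess_reads",
]

# Default 3' adapter of the standard small-RNA / PRO-seq kit (Illumina TruSeq
# small RNA RA3); overridable in PreprocConfig.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class InvalidRecordError(ValueError):
    """A FASTQ record violates the basic contract (empty sequence, length
    mismatch between sequence and qualities, orphaned mate)."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A raw sequencing record.

    ``qualities`` are phred scores, one per base.  ``mate_index`` is 1 or 2
    for paired-end data, ``None`` for single-end.
    """

    identifier: str
    sequence: str
    qualities: Sequence[int]
    mate_index: int | None = None

    def validate(self) -> "Read":
        if not self.sequence:
            raise InvalidRecordError(f"read {self.identifier!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise InvalidRecordError(
                f"read {self.identifier!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )
        return self


@dataclass
class PreprocConfig:
    """Tunables for adapter localization, pair fusion and read emission.

    ``min_insert_length`` follows the convention that inserts shorter than
    three nucleotides are adapter-adapter ligation products.  ``umi_length``
    is the UMI carried in the 3' adapter, located between insert and adapter
    on the sequenced strand (read1 only for paired-end data).
    """

    adapter_sequence: str = DEFAULT_ADAPTER
    umi_length: int = 8
    min_insert_length: int = 3
    min_adapter_overlap: int = 3
    max_adapter_error_rate: float = 0.1
    fuse_min_overlap: int = 10
    fuse_max_mismatch_ratio: float = 0.25
    reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_adapter_error_rate < 0.5):
            raise ValueError("max_adapter_error_rate must be in [0, 0.5)")
        if self.fuse_min_overlap < 1:
            raise ValueError("fuse_min_overlap must be >= 1")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")


@dataclass
class FragmentLengthHistogram:
    """Insert-length histogram (UMI already subtracted from the lengths).

    Reads in which no adapter was found contribute to ``n_reads_total`` only,
    so ``sum(counts.values()) <= n_reads_total``.
    """

    counts: dict[int, int] = field(default_factory=dict)
    n_reads_total: int = 0
    n_reads_with_adapter: int = 0

    def add(self, insert_length: int) -> None:
        self.counts[insert_length] = self.counts.get(insert_length, 0) + 1
        self.n_reads_with_adapter += 1

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\n")
            for length in sorted(self.counts):
                fh.write(f"{length}\t{self.counts[length]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FragmentLengthHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if header.strip() != "length\tcount":
                raise ValueError(f"{path}: not an insert-length histogram")
            for line in fh:
                length, count = line.split("\t")
                counts[int(length)] = int(count)
        n = sum(counts.values())
        return cls(counts=counts, n_reads_total=n, n_reads_with_adapter=n)


@dataclass
class DedupResult:
    unique_reads: list[Read]
    n_input: int
    n_unique: int

    @property
    def duplication_rate(self) -> float:
        return 1.0 - self.n_unique / self.n_input


@dataclass
class PreprocStats:
    """Per-stage accounting of the preprocessing pipeline."""

    n_input: int = 0
    n_with_adapter: int = 0
    n_adapter_adapter: int = 0
    n_after_adapter: int = 0
    n_duplicates: int = 0
    n_after_dedup: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.as_dict().items():
                fh.write(f"{key}\t{value}\n")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# FASTQ I/O (Biopython-backed; gzip transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, mate_index: int | None = None) -> Iterator[Read]:
    """Yield :class:`Read` records from a (possibly gzipped) FASTQ file."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield Read(
                identifier=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                mate_index=mate_index,
            ).validate()


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line FASTQ records; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.identifier}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Adapter localization and insert sizes
# ---------------------------------------------------------------------------

def locate_adapter(read_sequence: str, config: PreprocConfig) -> int | None:
    """Return the smallest 0-based offset at which a prefix of the adapter
    matches the read suffix, or None.

    A match at offset ``p`` compares ``read[p:p+k]`` against the adapter's
    first ``k`` bases, where ``k = min(len(read) - p, len(adapter))``.  It is
    accepted when ``k >= min_adapter_overlap`` and the mismatch fraction is at
    most ``max_adapter_error_rate``.  Scanning left to right yields the
    longest trimmed adapter, matching common trimmer behaviour.
    """
    if not read_sequence:
        raise InvalidRecordError("empty read sequence")
    adapter = config.adapter_sequence
    if not adapter:
        raise ValueError("adapter_sequence must be non-empty")
    n = len(read_sequence)
    max_p = n - config.min_adapter_overlap
    for p in range(0, max_p + 1):
        k = min(n - p, len(adapter))
        mismatches = sum(
            1 for a, b in zip(read_sequence[p : p + k], adapter[:k]) if a != b
        )
        if mismatches <= config.max_adapter_error_rate * k:
            return p
    return None


def _insert_length(adapter_offset: int, umi_length: int) -> int:
    # UMI sits between insert and adapter, so it is part of the pre-adapter
    # prefix; never negative.
    return max(adapter_offset - umi_length, 0)


def insert_size_histogram_single(
    reads: Iterable[Read], config: PreprocConfig
) -> FragmentLengthHistogram:
    """Insert-size histogram from single-end reads.

    Only reads containing adapter contribute lengths; the UMI length is
    subtracted from each adapter offset.
    """
    hist = FragmentLengthHistogram()
    for read in reads:
        read.validate()
        hist.n_reads_total += 1
        offset = locate_adapter(read.sequence, config)
        if offset is not None:
            hist.add(_insert_length(offset, config.umi_length))
    return hist


def fuse_read_pair(read1: Read, read2: Read, config: PreprocConfig) -> str | None:
    """Fuse an overlapping mate pair into a single sequence, FLASH-style.

    Read2 is reverse-complemented, then slid along read1; among offsets whose
    overlap is at least ``fuse_min_overlap`` long with a mismatch fraction at
    most ``fuse_max_mismatch_ratio``, the one with the most matching positions
    wins (ties toward longer overlap).  Disagreeing overlap bases take the
    higher-quality call, ties going to read1.  Returns None when no admissible
    overlap exists.
    """
    read1.validate()
    read2.validate()
    seq1, qual1 = read1.sequence, read1.qualities
    seq2 = reverse_complement(read2.sequence)
    qual2 = list(read2.qualities)[::-1]
    n1, n2 = len(seq1), len(seq2)

    best: tuple[int, int, int] | None = None  # (n_matches, overlap, offset)
    for offset in range(0, n1 - config.fuse_min_overlap + 1):
        overlap = min(n1 - offset, n2)
        if overlap < config.fuse_min_overlap:
            continue
        mism = sum(
            1
            for a, b in zip(seq1[offset : offset + overlap], seq2[:overlap])
            if a != b
        )
        if mism > config.fuse_max_mismatch_ratio * overlap:
            continue
        cand = (overlap - mism, overlap, -offset)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    overlap, offset = best[1], -best[2]

    consensus = []
    for i in range(overlap):
        a, b = seq1[offset + i], seq2[i]
        if a == b or qual1[offset + i] >= qual2[i]:
            consensus.append(a)
        else:
            consensus.append(b)
    return seq1[:offset] + "".join(consensus) + seq2[overlap:]


def insert_size_histogram_paired(
    pairs: Iterable[tuple[Read, Read]], config: PreprocConfig
) -> FragmentLengthHistogram:
    """Insert-size histogram from paired-end reads via overlap fusion.

    The fused length spans insert + UMI (only read1 carries a UMI), so the
    UMI length is subtracted once.  Non-fusable pairs contribute to the total
    only.
    """
    hist = FragmentLengthHistogram()
    for read1, read2 in pairs:
        hist.n_reads_total += 1
        fused = fuse_read_pair(read1, read2, config)
        if fused is not None:
            hist.add(max(len(fused) - config.umi_length, 0))
    return hist


# ---------------------------------------------------------------------------
# Scalar metrics on the histogram
# ---------------------------------------------------------------------------

def degradation_ratio(hist: FragmentLengthHistogram) -> float | None:
    """Sum of counts at lengths 10-20 over sum at 30-40 (both inclusive).

    A ratio above 1 indicates post-run-on degradation.  When the 30-40 sum
    is zero the ratio is +inf if any 10-20 nt fragments exist (a totally
    degraded library) and None — not computable — when both sums are zero.
    """
    import math

    short = sum(hist.counts.get(k, 0) for k in range(10, 21))
    long = sum(hist.counts.get(k, 0) for k in range(30, 41))
    if long == 0:
        return math.inf if short > 0 else None
    return short / long


def adapter_ligation_fraction(
    hist: FragmentLengthHistogram, config: PreprocConfig
) -> float:
    """Fraction of all reads that are adapter-adapter ligation products
    (adapter-containing with insert shorter than ``min_insert_length``)."""
    if hist.n_reads_total == 0:
        raise ValueError("empty library: no reads tallied")
    n_short = sum(
        c for length, c in hist.counts.items() if length < config.min_insert_length
    )
    return n_short / hist.n_reads_total


# ---------------------------------------------------------------------------
# Deduplication and the full preprocessing pipeline
# ---------------------------------------------------------------------------

def deduplicate_exact(reads: Sequence[Read]) -> DedupResult:
    """Keep the first occurrence of each distinct sequence string.

    Applied before UMI removal, so the UMI is still part of the sequence and
    distinguishes PCR duplicates from independent molecules with identical
    ends.  Qualities are ignored for the key.
    """
    if not reads:
        raise ValueError("deduplicate_exact: empty input")
    seen: set[str] = set()
    unique: list[Read] = []
    for read in reads:
        if read.sequence not in seen:
            seen.add(read.sequence)
            unique.append(read)
    return DedupResult(unique_reads=unique, n_input=len(reads), n_unique=len(unique))


def _trim_adapter(read: Read, config: PreprocConfig) -> tuple[Read, bool, bool]:
    """Returns (possibly trimmed read, had_adapter, is_adapter_adapter)."""
    offset = locate_adapter(read.sequence, config)
    if offset is None:
        return read, False, False
    insert = _insert_length(offset, config.umi_length)
    if insert < config.min_insert_length:
        return read, True, True
    trimmed = Read(
        identifier=read.identifier,
        sequence=read.sequence[:offset],
        qualities=list(read.qualities)[:offset],
        mate_index=read.mate_index,
    )
    return trimmed, True, False


def _finalize(read: Read, config: PreprocConfig) -> Read:
    """UMI trim (read1-class only) then optional reverse complementation."""
    seq, qual = read.sequence, list(read.qualities)
    if config.umi_length and read.mate_index != 2:
        seq = seq[: len(seq) - config.umi_length]
        qual = qual[: len(qual) - config.umi_length]
    if config.reverse_complement:
        seq = reverse_complement(seq)
        qual = qual[::-1]
    return Read(read.identifier, seq, qual, read.mate_index)


def preprocess_reads(
    reads: Sequence[Read],
    config: PreprocConfig,
    mate2_reads: Sequence[Read] | None = None,
) -> tuple[list[Read], PreprocStats] | tuple[list[Read], list[Read], PreprocStats]:
    """Run the pre-alignment pipeline: adapter removal (dropping
    adapter-adapter products), exact deduplication, UMI trimming (read1 only),
    reverse complementation, and — for paired-end input — re-pairing by
    identifier.

    Single-end: returns (processed_reads, stats).  Paired-end (``mate2_reads``
    given): returns (processed_read1, processed_read2, stats); only
    synchronized pairs survive.
    """
    stats = PreprocStats(n_input=len(reads))

    kept1: list[Read] = []
    for read in reads:
        read.validate()
        trimmed, had_adapter, is_aa = _trim_adapter(read, config)
        stats.n_with_adapter += had_adapter
        if is_aa:
            stats.n_adapter_adapter += 1
            continue
        kept1.append(trimmed)
    stats.n_after_adapter = len(kept1)

    if kept1:
        dedup = deduplicate_exact(kept1)
        stats.n_duplicates = dedup.n_input - dedup.n_unique
        kept1 = dedup.unique_reads
    stats.n_after_dedup = len(kept1)

    out1 = [_finalize(r, config) for r in kept1]

    if mate2_reads is None:
        stats.n_output = len(out1)
        return out1, stats

    # Paired-end: mate2 skips adapter-adapter accounting, dedup and UMI trim
    # follow read1's fate via re-pairing by identifier.
    mate2_by_id: dict[str, Read] = {}
    for read in mate2_reads:
        read.validate()
        mate2_by_id[read.identifier] = read
    paired1: list[Read] = []
    paired2: list[Read] = []
    orphans: list[str] = []
    for read in out1:
        mate = mate2_by_id.get(read.identifier)
        if mate is None:
            orphans.append(read.identifier)
            continue
        trimmed2, _, _ = _trim_adapter(mate, config)
        paired1.append(read)
        paired2.append(_finalize(trimmed2, config))
    if orphans and len(orphans) == len(out1):
        raise InvalidRecordError(
            "mismatched pair files; orphaned identifiers: "
            + ", ".join(orphans[:10])
        )
    stats.n_output = len(paired1)
    return paired1, paired2, stats
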