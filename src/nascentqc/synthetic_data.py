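"""Synthetic run-on libraries with known ground truth.

Generates toy genomes, gene annotations and raw FASTQ files carrying the
statistical structure the QC metrics assume — paused-polymerase 3' ends
concentrated +20..+120 downstream of a TSS, background signal across gene
bodies, exon-confined mRNA contamination, rRNA-decoy reads, adapter-adapter
ligation products, exact PCR duplicates and a tunable insert-length
distribution — together with per-read truth records and truth alignments,
so every metric can be validated without external data.

Reads follow the single-end PRO-seq layout: the sequencer reads the nascent
RNA 3'->5', so the raw read is ``revcomp(RNA fragment) + UMI + adapter``.
Class counts are deterministic (floor of fraction x count, remainder to the
body class); only positions, insert lengths and UMIs are random, and all
randomness flows from one seed, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_accounting import AlignedRead, write_alignments_bed6
from .qc_metrics import FeatureClass, GeneModel, write_feature_classes_bed, write_gene_models_refflat
from .read_preproc import DEFAULT_ADAPTER, Read, reverse_complement, write_fastq
from .signal_tracks import write_chrom_sizes

__all__ = [
    "LibraryParams",
    "TruthRecord",
    "Annotation",
    "SimulatedLibrary",
    "make_toy_annotation",
    "simulate_library",
]

MAIN_CHROM = "chr1"
DECOY_CHROM = "chrRDNA"
DECOY_SIZE = 2_000
GENE_SLOT = 5_000
CHROM_MARGIN = 2_500  # head/tail padding so every TSS has a full ±2 kb flank
GENE_PAD = 100  # gap between a gene span and its slot boundary
READ_QUALITY = 35

# second (5') adapter seen by read2 in paired-end mode
MATE2_ADAPTER = "GATCGTCGGACTGTAGAACTCTGAAC"

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class LibraryParams:
    """Library composition knobs.

    Fractions partition the reads into truth classes; whatever is left after
    pause/mrna/rrna/adapter-adapter goes to the ``body`` class, whose 3'
    ends are uniform over gene spans.  ``duplication_rate`` is the fraction
    of emitted reads that are exact copies of another read.  Insert lengths
    are round(Normal(insert_mean, insert_sd)), floored at 3 for genomic
    classes (shorter inserts define the adapter-adapter class).
    """

    n_reads: int = 20_000
    paired: bool = False
    umi_length: int = 8
    adapter_sequence: str = DEFAULT_ADAPTER
    pause_strength: float = 0.0
    mrna_fraction: float = 0.0
    rrna_fraction: float = 0.0
    duplication_rate: float = 0.0
    adapter_adapter_fraction: float = 0.0
    insert_mean: float = 38.0
    insert_sd: float = 4.0
    read_length: int = 75
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.pause_strength,
            self.mrna_fraction,
            self.rrna_fraction,
            self.adapter_adapter_fraction,
            self.duplication_rate,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if (self.pause_strength + self.mrna_fraction + self.rrna_fraction
                + self.adapter_adapter_fraction) > 1:
            raise ValueError("class fractions sum to more than 1")
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")


@dataclass
class TruthRecord:
    read_id: str
    chrom: str | None  # None for adapter-adapter products
    three_prime: int | None
    strand: str | None
    read_class: str  # pause | body | mrna | rrna | adapter_adapter
    insert_length: int
    is_duplicate_of: str | None = None


@dataclass
class Annotation:
    """Toy genome + gene models + feature classes."""

    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    features: dict[str, FeatureClass]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "genes": outdir / "genes.refflat.tsv",
            "features": outdir / "features.bed",
            "chrom_sizes": outdir / "chrom.sizes",
        }
        _write_fasta(self.genome, paths["genome"])
        write_gene_models_refflat(self.genes, paths["genes"])
        write_feature_classes_bed(self.features.values(), paths["features"])
        write_chrom_sizes(self.chrom_sizes, paths["chrom_sizes"])
        return paths


def _write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def make_toy_annotation(n_genes: int, seed: int = 0) -> Annotation:
    """Deterministic toy genome and annotation.

    One main chromosome of ``n_genes`` 5-kb gene slots plus 2.5-kb margins,
    and one 2-kb rDNA decoy chromosome.  Each gene occupies a 4.8-kb span
    with 2-4 exons (at least one intron) and 1-3 TSS isoforms spaced >= 200
    nt, leaving >= 1.5 kb of gene body beyond every TSS+500.  Feature
    classes (promoter = TSS +/- 250, flanks, UTRs, exons, introns, enhancers
    in intergenic gaps) are derived from the same structures.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    main_size = 2 * CHROM_MARGIN + n_genes * GENE_SLOT
    genome = {
        MAIN_CHROM: _random_sequence(rng, main_size),
        DECOY_CHROM: _random_sequence(rng, DECOY_SIZE),
    }
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    genes: list[GeneModel] = []
    features: dict[str, FeatureClass] = {
        name: FeatureClass(name=name, intervals=[])
        for name in ("enhancer", "promoter", "promoter_flanking",
                     "5UTR", "3UTR", "exon", "intron")
    }
    span_len = GENE_SLOT - 2 * GENE_PAD
    for i in range(n_genes):
        slot = CHROM_MARGIN + i * GENE_SLOT
        span = (slot + GENE_PAD, slot + GENE_PAD + span_len)
        strand = "+" if rng.integers(2) == 0 else "-"

        # exon/intron layout in transcription coordinates [0, span_len)
        n_exons = int(rng.integers(2, 5))
        cursor = 0
        tx_exons: list[tuple[int, int]] = []
        for _ in range(n_exons - 1):
            exon_len = int(rng.integers(150, 401))
            tx_exons.append((cursor, cursor + exon_len))
            cursor += exon_len + int(rng.integers(300, 801))
        tx_exons.append((cursor, span_len))

        # TSS isoforms: the 5' end plus up to two more at >= 200 nt spacing
        n_tss = int(rng.integers(1, 4))
        offsets = [0]
        if n_tss > 1:
            offsets += sorted(
                rng.choice([200, 400, 600, 800], size=n_tss - 1, replace=False).tolist()
            )

        if strand == "+":
            exons = [(span[0] + s, span[0] + e) for s, e in tx_exons]
            tss_list = [span[0] + o for o in offsets]
        else:
            exons = sorted((span[1] - e, span[1] - s) for s, e in tx_exons)
            tss_list = sorted(span[1] - 1 - o for o in offsets)
        gene = GeneModel(
            gene_id=f"gene{i:03d}", chrom=MAIN_CHROM, strand=strand,
            span=span, tss_list=tss_list, exons=exons,
        )
        genes.append(gene)

        primary_tss = gene.tss_5prime
        features["promoter"].intervals.append(
            (MAIN_CHROM, primary_tss - 250, primary_tss + 250)
        )
        features["promoter_flanking"].intervals += [
            (MAIN_CHROM, primary_tss - 1000, primary_tss - 250),
            (MAIN_CHROM, primary_tss + 250, primary_tss + 1000),
        ]
        first = gene.first_exon
        last = gene.exons[-1] if strand == "+" else gene.exons[0]
        features["5UTR"].intervals.append((MAIN_CHROM, *first))
        features["3UTR"].intervals.append((MAIN_CHROM, *last))
        features["exon"].intervals += [(MAIN_CHROM, s, e) for s, e in gene.exons]
        features["intron"].intervals += [(MAIN_CHROM, s, e) for s, e in gene.introns]
        # an enhancer in the intergenic gap ahead of the gene
        features["enhancer"].intervals.append((MAIN_CHROM, slot - 350, slot - 150))

    return Annotation(
        genome=genome, chrom_sizes=chrom_sizes, genes=genes, features=features
    )


@dataclass
class SimulatedLibrary:
    reads1: list[Read]
    reads2: list[Read] | None
    truth: dict[str, TruthRecord]
    truth_alignments: list[AlignedRead]
    params: LibraryParams

    def class_counts(self) -> Counter:
        return Counter(t.read_class for t in self.truth.values())

    def n_duplicates(self) -> int:
        return sum(1 for t in self.truth.values() if t.is_duplicate_of is not None)

    def truth_insert_histogram(self, max_detectable: int | None = None) -> dict[int, int]:
        """Insert-length counts as the read-level pipeline should see them;
        ``max_detectable`` drops inserts too long for the adapter to appear
        in the read (insert + UMI + minimum adapter overlap > read length)."""
        counts: Counter = Counter()
        for t in self.truth.values():
            if max_detectable is None or t.insert_length <= max_detectable:
                counts[t.insert_length] += 1
        return dict(counts)

    def truth_summary(self) -> dict:
        return {
            "n_reads": len(self.reads1),
            "class_counts": dict(self.class_counts()),
            "n_duplicates": self.n_duplicates(),
            "params": {k: v for k, v in self.params.__dict__.items()},
        }

    def write(self, outdir: str | Path, prefix: str = "library") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fastq1": outdir / f"{prefix}_R1.fastq"}
        write_fastq(self.reads1, paths["fastq1"])
        if self.reads2 is not None:
            paths["fastq2"] = outdir / f"{prefix}_R2.fastq"
            write_fastq(self.reads2, paths["fastq2"])
        paths["truth_bed"] = outdir / f"{prefix}_truth.bed"
        write_alignments_bed6(self.truth_alignments, paths["truth_bed"])
        paths["truth_json"] = outdir / f"{prefix}_truth.json"
        Path(paths["truth_json"]).write_text(
            json.dumps(self.truth_summary(), indent=2) + "\n"
        )
        return paths


def _class_counts(params: LibraryParams, n_orig: int) -> dict[str, int]:
    counts = {
        "pause": int(params.pause_strength * n_orig),
        "mrna": int(params.mrna_fraction * n_orig),
        "rrna": int(params.rrna_fraction * n_orig),
        "adapter_adapter": int(params.adapter_adapter_fraction * n_orig),
    }
    counts["body"] = n_orig - sum(counts.values())
    return counts


def _draw_insert(rng: np.random.Generator, params: LibraryParams) -> int:
    return max(3, int(round(rng.normal(params.insert_mean, params.insert_sd))))


def simulate_library(params: LibraryParams, annotation: Annotation) -> SimulatedLibrary:
    """Render a raw library plus truth from an annotation.

    Pause reads land +20..+119 downstream of the gene's 5'-most TSS; body
    reads land uniformly over the gene span; mRNA-contamination reads land
    uniformly over non-first exons; rRNA reads land on the decoy
    chromosome; adapter-adapter products carry inserts of 0-2 nt and no
    genomic origin.  Duplicates are exact sequence copies of earlier reads.
    Original reads are guaranteed sequence-distinct (the UMI is redrawn on
    collision) so exact deduplication recovers the duplicate count exactly.
    """
    rng = np.random.default_rng(params.seed)
    genes = annotation.genes
    if not genes:
        raise ValueError("annotation has no genes")

    n_dup = int(params.duplication_rate * params.n_reads)
    n_orig = params.n_reads - n_dup
    counts = _class_counts(params, n_orig)

    class_labels: list[str] = []
    for cls in ("pause", "mrna", "rrna", "adapter_adapter", "body"):
        class_labels += [cls] * counts[cls]

    reads1: list[Read] = []
    reads2: list[Read] | None = [] if params.paired else None
    truth: dict[str, TruthRecord] = {}
    truth_alignments: list[AlignedRead] = []
    seen_sequences: set[str] = set()

    non_first_exon_cumsizes = {}
    for g in genes:
        nfe = g.non_first_exons
        sizes = np.array([e - s for s, e in nfe]) if nfe else np.array([])
        non_first_exon_cumsizes[g.gene_id] = (nfe, np.cumsum(sizes))

    for i, cls in enumerate(class_labels):
        read_id = f"read{i:06d}"
        insert = _draw_insert(rng, params)
        chrom = strand = None
        pos = None
        if cls == "adapter_adapter":
            insert = int(rng.integers(0, 3))
            fragment = _random_sequence(rng, insert)
        else:
            if cls == "rrna":
                chrom, strand = DECOY_CHROM, "+"
                pos = int(rng.integers(insert, DECOY_SIZE - 1))
            else:
                gene = genes[int(rng.integers(len(genes)))]
                chrom, strand = gene.chrom, gene.strand
                if cls == "pause":
                    offset = int(rng.integers(20, 120))
                    tss = gene.tss_5prime
                    pos = tss + offset if strand == "+" else tss - offset
                elif cls == "mrna":
                    nfe, cumsizes = non_first_exon_cumsizes[gene.gene_id]
                    if not nfe:
                        raise ValueError(f"{gene.gene_id}: no non-first exon")
                    flat = int(rng.integers(cumsizes[-1]))
                    j = int(np.searchsorted(cumsizes, flat, side="right"))
                    within = flat - (cumsizes[j - 1] if j else 0)
                    pos = nfe[j][0] + within
                else:  # body
                    pos = int(rng.integers(gene.span[0], gene.span[1]))
            fragment = _sense_fragment(annotation, chrom, pos, strand, insert)
            truth_alignments.append(_truth_alignment(read_id, chrom, pos, strand, insert))

        umi = _random_sequence(rng, params.umi_length)
        construct = reverse_complement(fragment) + umi
        if params.umi_length > 0:
            while construct in seen_sequences:
                umi = _random_sequence(rng, params.umi_length)
                construct = reverse_complement(fragment) + umi
        seen_sequences.add(construct)

        read1_seq = (construct + params.adapter_sequence)[: params.read_length]
        if params.error_rate > 0:
            read1_seq = _apply_errors(rng, read1_seq, params.error_rate)
        reads1.append(
            Read(read_id, read1_seq, [READ_QUALITY] * len(read1_seq),
                 mate_index=1 if params.paired else None)
        )
        if params.paired:
            read2_seq = (reverse_complement(construct) + MATE2_ADAPTER)[: params.read_length]
            if params.error_rate > 0:
                read2_seq = _apply_errors(rng, read2_seq, params.error_rate)
            reads2.append(
                Read(read_id, read2_seq, [READ_QUALITY] * len(read2_seq), mate_index=2)
            )
        truth[read_id] = TruthRecord(
            read_id=read_id, chrom=chrom, three_prime=pos, strand=strand,
            read_class=cls, insert_length=insert,
        )

    # exact PCR duplicates of random originals
    for j in range(n_dup):
        src_idx = int(rng.integers(n_orig))
        src = reads1[src_idx]
        read_id = f"read{n_orig + j:06d}"
        reads1.append(Read(read_id, src.sequence, list(src.qualities), src.mate_index))
        if params.paired:
            src2 = reads2[src_idx]
            reads2.append(Read(read_id, src2.sequence, list(src2.qualities), 2))
        src_truth = truth[src.identifier]
        truth[read_id] = TruthRecord(
            read_id=read_id, chrom=src_truth.chrom,
            three_prime=src_truth.three_prime, strand=src_truth.strand,
            read_class=src_truth.read_class,
            insert_length=src_truth.insert_length,
            is_duplicate_of=src.identifier,
        )
        if src_truth.chrom is not None:
            truth_alignments.append(
                _truth_alignment(read_id, src_truth.chrom, src_truth.three_prime,
                                 src_truth.strand, src_truth.insert_length)
            )

    # shuffle emission order; truth and pairing follow the read ids
    order = rng.permutation(len(reads1))
    reads1 = [reads1[k] for k in order]
    if params.paired:
        reads2 = [reads2[k] for k in order]

    return SimulatedLibrary(
        reads1=reads1, reads2=reads2, truth=truth,
        truth_alignments=truth_alignments, params=params,
    )


def _sense_fragment(
    annotation: Annotation, chrom: str, pos: int, strand: str, insert: int
) -> str:
    """Nascent-RNA fragment (sense, 5'->3') whose 3' end sits at ``pos``."""
    seq = annotation.genome[chrom]
    if strand == "+":
        start = pos - insert + 1
        if start < 0:
            raise ValueError(f"fragment underruns {chrom}")
        return seq[start : pos + 1]
    end = pos + insert
    if end > len(seq):
        raise ValueError(f"fragment overruns {chrom}")
    return reverse_complement(seq[pos:end])


def _truth_alignment(
    read_id: str, chrom: str, pos: int, strand: str, insert: int
) -> AlignedRead:
    if strand == "+":
        start, end = pos - insert + 1, pos + 1
    else:
        start, end = pos, pos + insert
    return AlignedRead(
        chrom=chrom, start=start, end=end, strand=strand, mapq=255, name=read_id
    )


def _apply_errors(rng: np.random.Generator, sequence: str, rate: float) -> str:
    out = list(sequence)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(out)
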