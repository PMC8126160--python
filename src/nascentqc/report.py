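"""Single-sample QC orchestration and the machine-readable report.

``run_qc`` drives the full metric layer from a plain YAML config naming the
inputs that exist for a sample: raw FASTQ enables the read-level metrics
(adapter-adapter fraction, degradation ratio, duplication rate, library
complexity), an alignment file (SAM/BAM or 6-column BED) plus annotations
enables the alignment-level metrics (rRNA rate, exon:intron contamination,
pause index, TSS enrichment, FRiF, signal tracks, gene counts).  Metrics
whose inputs are absent are reported as not computable (``None`` in the
report object, ``NA`` on disk) — QC is advisory, so threshold failures
never change the exit status.

Outputs are written atomically (temp file + rename) and reruns skip stages
whose outputs already exist unless forced.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import alignment_accounting as aln_mod
from . import qc_metrics as qc
from . import read_preproc as rp
from . import signal_tracks as st

__all__ = ["QCReport", "RECOMMENDED_THRESHOLDS", "run_qc", "write_report", "load_report"]

log = logging.getLogger("nascentqc")

REPORT_SCHEMA_VERSION = "1.0"

# Recommended cutoffs for a high-quality run-on library.
RECOMMENDED_THRESHOLDS: dict[str, dict[str, float]] = {
    "degradation_ratio": {"max": 1.0},
    "pct_unique_at_10M": {"min": 75.0},
    "rrna_rate": {"max": 0.20},
    "median_exon_intron": {"min": 1.0, "max": 1.8},
    "median_pause_index": {"min": 10.0},
}

SCALAR_METRICS = (
    "adapter_adapter_fraction",
    "degradation_ratio",
    "duplication_rate",
    "pct_unique_at_10M",
    "rrna_rate",
    "total_efficiency",
    "median_exon_intron",
    "median_pause_index",
    "tss_score",
)


@dataclass
class QCReport:
    """Named scalar metrics, artifact paths, and threshold flags for one
    sample.  A metric that could not be computed is None (serialized NA)."""

    sample_name: str
    metrics: dict[str, float | None] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    schema_version: str = REPORT_SCHEMA_VERSION

    def apply_thresholds(
        self, thresholds: dict[str, dict[str, float]] | None = None
    ) -> None:
        thresholds = thresholds or RECOMMENDED_THRESHOLDS
        for metric, bounds in thresholds.items():
            value = self.metrics.get(metric)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                self.flags[metric] = "not_computable"
                continue
            ok = True
            if "min" in bounds and not value >= bounds["min"]:
                ok = False
            if "max" in bounds and not value < bounds["max"]:
                ok = False
            self.flags[metric] = "pass" if ok else "fail"

    def as_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "sample_name": self.sample_name,
            "metrics": dict(self.metrics),
            "paths": dict(self.paths),
            "flags": dict(self.flags),
        }


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_report(report: QCReport, outdir: str | Path, formats=("json", "tsv")) -> dict[str, Path]:
    """Serialize the report; JSON round-trips losslessly, TSV is flat
    metric/value with NA for not-computable entries."""
    outdir = Path(outdir)
    written: dict[str, Path] = {}
    if "json" in formats:
        path = outdir / "qc_report.json"
        _atomic_write(
            path,
            lambda p: p.write_text(json.dumps(report.as_dict(), indent=2) + "\n"),
        )
        written["json"] = path
    if "tsv" in formats:
        path = outdir / "qc_report.tsv"

        def _write_tsv(p: Path) -> None:
            with open(p, "w") as fh:
                fh.write(f"sample_name\t{report.sample_name}\n")
                for key in SCALAR_METRICS:
                    value = report.metrics.get(key)
                    if value is None or (isinstance(value, float) and math.isnan(value)):
                        fh.write(f"{key}\tNA\n")
                    else:
                        fh.write(f"{key}\t{value:.6g}\n")
                for key, flag in report.flags.items():
                    fh.write(f"flag_{key}\t{flag}\n")

        _atomic_write(path, _write_tsv)
        written["tsv"] = path
    return written


def load_report(path: str | Path) -> QCReport:
    data = json.loads(Path(path).read_text())
    return QCReport(
        sample_name=data["sample_name"],
        metrics=data["metrics"],
        paths=data["paths"],
        flags=data["flags"],
        schema_version=data.get("schema_version", REPORT_SCHEMA_VERSION),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_alignments(path: Path) -> list:
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        return list(aln_mod.read_alignments_sam(path))
    return list(aln_mod.read_alignments_bed6(path))


def _stage(outdir: Path, name: str, force: bool):
    """True when the stage's sentinel output is absent or a rerun is
    forced."""
    sentinel = outdir / name
    return force or not sentinel.exists(), sentinel


def run_qc(config_path: str | Path, force: bool = False) -> QCReport:
    """Run every stage the config's inputs allow and emit the QC report.

    The config is a plain YAML mapping; recognized keys: ``sample_name``,
    ``output_dir``, ``fastq`` (or ``fastq1``/``fastq2``), ``alignments``,
    ``genes``, ``features``, ``chrom_sizes``, ``adapter``, ``umi_length``,
    ``mapq_min``, ``decoy_chroms``, ``which_end``, ``scale``,
    ``smooth_window``, ``seed``, ``n_raw``, ``stage_counts``,
    ``thresholds``.
    """
    config_path = Path(config_path)
    cfg: dict[str, Any] = yaml.safe_load(config_path.read_text()) or {}
    base = config_path.parent

    def _path(key: str) -> Path | None:
        value = cfg.get(key)
        if value is None:
            return None
        p = Path(value)
        return p if p.is_absolute() else base / p

    sample = cfg.get("sample_name", config_path.stem)
    outdir = _path("output_dir") or (base / f"{sample}_qc")
    outdir.mkdir(parents=True, exist_ok=True)
    report = QCReport(sample_name=sample)
    metrics: dict[str, float | None] = {k: None for k in SCALAR_METRICS}
    seed = int(cfg.get("seed", 0))

    preproc_cfg = rp.PreprocConfig(
        adapter_sequence=cfg.get("adapter", rp.DEFAULT_ADAPTER),
        umi_length=int(cfg.get("umi_length", 8)),
    )

    # ---- raw-read stage -------------------------------------------------
    fastq1 = _path("fastq") or _path("fastq1")
    fastq2 = _path("fastq2")
    n_input_reads = None
    if fastq1 is not None:
        log.info("stage raw_reads: reading %s", fastq1)
        reads1 = [r for r in rp.read_fastq(fastq1, mate_index=1 if fastq2 else None)]
        if fastq2 is not None:
            reads2 = list(rp.read_fastq(fastq2, mate_index=2))
            pairs = _pair_by_id(reads1, reads2)
            hist = rp.insert_size_histogram_paired(pairs, preproc_cfg)
        else:
            hist = rp.insert_size_histogram_single(reads1, preproc_cfg)
        metrics["degradation_ratio"] = rp.degradation_ratio(hist)
        metrics["adapter_adapter_fraction"] = rp.adapter_ligation_fraction(hist, preproc_cfg)

        if fastq2 is not None:
            processed1, processed2, stats = rp.preprocess_reads(
                reads1, preproc_cfg, mate2_reads=reads2
            )
        else:
            processed1, stats = rp.preprocess_reads(reads1, preproc_cfg)
            processed2 = None
        metrics["duplication_rate"] = (
            stats.n_duplicates / stats.n_after_adapter if stats.n_after_adapter else None
        )
        if preproc_cfg.umi_length > 0:
            _, pct = qc.complexity_points(
                reads1, umi_length=preproc_cfg.umi_length, seed=seed
            )
            metrics["pct_unique_at_10M"] = pct
        n_input_reads = stats.n_input

        run_needed, _ = _stage(outdir, "processed_R1.fastq", force)
        if run_needed:
            _atomic_write(outdir / "processed_R1.fastq",
                          lambda p: rp.write_fastq(processed1, p))
            if processed2 is not None:
                _atomic_write(outdir / "processed_R2.fastq",
                              lambda p: rp.write_fastq(processed2, p))
        _atomic_write(outdir / "insert_lengths.tsv", hist.write_tsv)
        _atomic_write(outdir / "preproc_stats.tsv", stats.write_tsv)
        _atomic_write(outdir / "preproc_stats.json", stats.write_json)
        report.paths["insert_lengths"] = str(outdir / "insert_lengths.tsv")
        report.paths["preproc_stats"] = str(outdir / "preproc_stats.tsv")
        log.info(
            "stage raw_reads: %d reads in, %d out, %d adapter-adapter, %d duplicates",
            stats.n_input, stats.n_output, stats.n_adapter_adapter, stats.n_duplicates,
        )

    # ---- alignment stage ------------------------------------------------
    aln_path = _path("alignments")
    if aln_path is not None:
        log.info("stage alignments: reading %s", aln_path)
        records = _load_alignments(aln_path)
        mapq_min = int(cfg.get("mapq_min", aln_mod.DEFAULT_MAPQ_MIN))
        plus, minus, counts = aln_mod.filter_and_split_alignments(records, mapq_min)
        decoys = set(cfg.get("decoy_chroms", ["chrRDNA"]))
        decoy_alns = [a for a in plus + minus if a.chrom in decoys]
        plus = [a for a in plus if a.chrom not in decoys]
        minus = [a for a in minus if a.chrom not in decoys]
        kept = plus + minus
        log.info(
            "stage alignments: %d records, %d kept (%d plus / %d minus), %d decoy",
            counts.n_records, counts.n_kept, len(plus), len(minus), len(decoy_alns),
        )

        # Denominators default to the alignment input itself: every record
        # in the file entered alignment, so it doubles as the trimmed count
        # unless the config says otherwise.
        n_raw = int(cfg.get("n_raw", n_input_reads if n_input_reads else counts.n_records))
        n_trim = int(cfg.get("n_trimmed", counts.n_records))
        stage_counts = list((cfg.get("stage_counts") or {"rDNA": len(decoy_alns)}).items())
        index = qc.EndIndex(kept)
        genome_size = None
        chrom_sizes = None
        cs_path = _path("chrom_sizes")
        if cs_path is not None:
            chrom_sizes = st.read_chrom_sizes(cs_path)
            genome_size = sum(
                size for chrom, size in chrom_sizes.items() if chrom not in decoys
            )
        try:
            stats = aln_mod.tally_serial_alignment(
                n_raw=n_raw,
                n_trimmed=n_trim,
                stage_counts=stage_counts,
                n_primary_aligned=counts.n_kept - len(decoy_alns) + counts.n_low_mapq,
                n_pass_mapq=len(kept),
                genome_size=genome_size or 0,
                mean_read_length=index.mean_read_length,
            )
            metrics["rrna_rate"] = stats.rrna_rate
            metrics["total_efficiency"] = stats.total_efficiency
            _atomic_write(outdir / "alignment_stats.tsv", stats.write_tsv)
            _atomic_write(outdir / "alignment_stats.json", stats.write_json)
            report.paths["alignment_stats"] = str(outdir / "alignment_stats.tsv")
        except ValueError as exc:
            log.warning("serial alignment accounting skipped: %s", exc)

        genes = None
        genes_path = _path("genes")
        if genes_path is not None:
            genes = qc.load_gene_models_refflat(genes_path)

        if genes:
            try:
                table, median = qc.exon_intron_ratios(index, genes)
                metrics["median_exon_intron"] = median
                _atomic_write(outdir / "exon_intron_ratios.bed",
                              lambda p: qc.write_ratio_bed(table, p))
                report.paths["exon_intron_ratios"] = str(outdir / "exon_intron_ratios.bed")
            except ValueError as exc:
                log.warning("exon:intron ratios skipped: %s", exc)
            try:
                pi_table, pi_median, excluded = qc.pause_indices(index, genes)
                metrics["median_pause_index"] = pi_median
                _atomic_write(outdir / "pause_indices.bed",
                              lambda p: qc.write_ratio_bed(pi_table, p))
                report.paths["pause_indices"] = str(outdir / "pause_indices.bed")
                log.info("stage pause_index: %d genes scored, excluded %s",
                         len(pi_table), excluded)
            except ValueError as exc:
                log.warning("pause index skipped: %s", exc)
            if chrom_sizes is not None:
                tss_set = [(g.chrom, g.tss_5prime, g.strand) for g in genes]
                try:
                    profile, score = qc.tss_enrichment(index, tss_set, chrom_sizes)
                    metrics["tss_score"] = score
                    _atomic_write(
                        outdir / "tss_profile.tsv",
                        lambda p: _write_profile(profile, p),
                    )
                    report.paths["tss_profile"] = str(outdir / "tss_profile.tsv")
                except ValueError as exc:
                    log.warning("TSS enrichment skipped: %s", exc)
            counts_table = qc.gene_counts({sample: index}, genes)
            _atomic_write(
                outdir / "gene_counts.tsv",
                lambda p: counts_table.to_csv(p, sep="\t"),
            )
            report.paths["gene_counts"] = str(outdir / "gene_counts.tsv")

        features_path = _path("features")
        if features_path is not None and genome_size:
            classes = qc.load_feature_classes_bed(features_path)
            curves = qc.cumulative_frif(index, classes, genome_size)
            with open(outdir / "frif_curves.tsv", "w") as fh:
                fh.write("feature\tlog10_cumulative_size\tcumulative_fraction\tnc_score\n")
                for name, curve in curves.items():
                    nc = qc.noncumulative_frif(kept, classes[name], genome_size)
                    for x, y in curve.points:
                        fh.write(f"{name}\t{x:.6g}\t{y:.6g}\t{nc:.6g}\n")
            report.paths["frif_curves"] = str(outdir / "frif_curves.tsv")

        if chrom_sizes is not None:
            which_end = {"3": "3prime", "5": "5prime"}.get(
                str(cfg.get("which_end", "3")), "3prime"
            )
            plus_track, minus_track = st.end_counts(kept, chrom_sizes, which_end)
            if cfg.get("scale"):
                plus_track = st.scale_track(plus_track, len(kept))
                minus_track = st.scale_track(minus_track, len(kept))
            window = int(cfg.get("smooth_window", 0) or 0)
            if window:
                plus_track = st.smooth_track(plus_track, window)
                minus_track = st.smooth_track(minus_track, window)
            _atomic_write(outdir / "signal_plus.bedgraph",
                          lambda p: st.write_bedgraph(plus_track, p))
            _atomic_write(outdir / "signal_minus.bedgraph",
                          lambda p: st.write_bedgraph(minus_track, p))
            report.paths["signal_plus"] = str(outdir / "signal_plus.bedgraph")
            report.paths["signal_minus"] = str(outdir / "signal_minus.bedgraph")

    report.metrics = metrics
    report.apply_thresholds(cfg.get("thresholds"))
    write_report(report, outdir)
    report.paths["report_json"] = str(outdir / "qc_report.json")
    return report


def _pair_by_id(reads1, reads2):
    by_id = {r.identifier: r for r in reads2}
    pairs = []
    for r1 in reads1:
        r2 = by_id.get(r1.identifier)
        if r2 is not None:
            pairs.append((r1, r2))
    return pairs


def _write_profile(profile, path: Path) -> None:
    flank = (len(profile) - 1) // 2
    with open(path, "w") as fh:
        fh.write("offset\tcount\n")
        for i, v in enumerate(profile):
            fh.write(f"{i - flank}\t{v:g}\n")
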