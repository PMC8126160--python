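"""Metric layer: densities, exon:intron contamination, pause index, TSS
enrichment, FRiF, complexity and gene counts — each validated against an
independent brute-force oracle where the arithmetic is not forced."""

import math
from collections import Counter

import numpy as np
import pytest

from nascentqc import (
    AlignedRead,
    EndIndex,
    FeatureClass,
    GeneModel,
    LibraryParams,
    Read,
    complexity_points,
    cumulative_frif,
    exon_intron_ratios,
    gene_counts,
    noncumulative_frif,
    pause_indices,
    read_density,
    simulate_library,
    tss_enrichment,
)
from nascentqc.qc_metrics import load_gene_models_refflat, write_gene_models_refflat


def _end_at(chrom, pos, strand="+", name=""):
    """A 1-nt alignment whose 3' end is exactly ``pos`` on either strand."""
    return AlignedRead(chrom, pos, pos + 1, strand, name=name)


def _two_exon_gene(gene_id="g", chrom="chrT", strand="+"):
    # exon1 [0,100), intron [100,1100), exon2 [1100,1200)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, span=(0, 1200),
        tss_list=[0] if strand == "+" else [1199],
        exons=[(0, 100), (1100, 1200)],
    )


class TestReadDensity:
    def test_ends_per_nucleotide(self):
        alns = [_end_at("chr1", 100 + i % 30) for i in range(30)]
        assert read_density(alns, "chr1", (100, 200)) == pytest.approx(0.30)

    def test_empty_interval_coverage(self):
        assert read_density([_end_at("chr1", 5)], "chr1", (100, 200)) == 0.0

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ValueError):
            read_density([_end_at("chr1", 5)], "chr1", (100, 100))

    def test_matches_per_position_tally(self):
        rng = np.random.default_rng(5)
        alns = [
            _end_at("chr1", int(p), "+" if s else "-")
            for p, s in zip(rng.integers(0, 500, 300), rng.integers(0, 2, 300))
        ]
        index = EndIndex(alns)
        for start, end, strand in ((0, 500, None), (100, 137, "+"), (250, 260, "-")):
            per_pos = Counter(
                (a.three_prime, a.strand) for a in alns
            )
            oracle = sum(
                per_pos[(p, s)]
                for p in range(start, end)
                for s in ([strand] if strand else "+-")
            ) / (end - start)
            assert read_density(index, "chr1", (start, end), strand) == pytest.approx(oracle)


class TestExonIntronRatios:
    def test_forced_arithmetic(self):
        gene = _two_exon_gene()
        alns = [_end_at("chrT", 1100 + i % 100) for i in range(10)]
        alns += [_end_at("chrT", 100 + i * 37 % 1000) for i in range(10)]
        table, median = exon_intron_ratios(alns, [gene])
        assert median == pytest.approx(10.0)
        assert table.loc[0, "exon_reads"] == 10 and table.loc[0, "intron_reads"] == 10

    def test_deterministic_uniform_coverage_gives_ratio_one(self):
        gene = _two_exon_gene()
        alns = [_end_at("chrT", p) for p in range(0, 1200)]
        table, median = exon_intron_ratios(alns, [gene])
        assert median == pytest.approx(1.0)

    def test_first_exon_reads_do_not_change_ratio(self):
        gene = _two_exon_gene()
        base = [_end_at("chrT", p) for p in range(100, 1200)]
        spiked = base + [_end_at("chrT", p % 100, name="fx") for p in range(500)]
        t1, _ = exon_intron_ratios(base, [gene])
        t2, _ = exon_intron_ratios(spiked, [gene])
        assert t1.loc[0, "ratio"] == pytest.approx(t2.loc[0, "ratio"])

    def test_minus_strand_first_exon_is_max_coordinate(self):
        gene = _two_exon_gene(strand="-")
        assert gene.first_exon == (1100, 1200)
        # sense reads in the minus-strand gene's scored exon ([0,100))
        alns = [_end_at("chrT", i % 100, "-") for i in range(10)]
        alns += [_end_at("chrT", 100 + i * 97 % 1000, "-") for i in range(10)]
        table, median = exon_intron_ratios(alns, [gene])
        assert median == pytest.approx(10.0)

    def test_antisense_reads_ignored(self):
        gene = _two_exon_gene()
        alns = [_end_at("chrT", 1100 + i, "-") for i in range(50)]
        alns += [_end_at("chrT", 500 + i) for i in range(5)]
        table, _ = exon_intron_ratios(alns, [gene])
        assert table.loc[0, "exon_reads"] == 0

    def test_single_exon_genes_unscoreable(self):
        gene = GeneModel("g", "chrT", "+", (0, 100), [0], [(0, 100)])
        with pytest.raises(ValueError):
            exon_intron_ratios([_end_at("chrT", 5)], [gene])

    def test_contamination_sweep_is_monotone(self, annotation50):
        medians = []
        for frac in (0.0, 0.1, 0.3, 0.5, 0.9):
            lib = simulate_library(
                LibraryParams(n_reads=20_000, mrna_fraction=frac, seed=1),
                annotation50,
            )
            _, median = exon_intron_ratios(
                EndIndex(lib.truth_alignments), annotation50.genes
            )
            medians.append(median)
        assert medians == sorted(medians)
        assert medians[-1] > 3 * medians[0]


class TestPauseIndices:
    def test_forced_arithmetic(self):
        gene = GeneModel("g", "chrT", "+", (1000, 3000), [1000], [(1000, 1200), (1800, 3000)])
        alns = [_end_at("chrT", 1020 + i * 3 % 100) for i in range(30)]
        alns += [_end_at("chrT", 1500 + i * 100) for i in range(15)]
        table, median, excluded = pause_indices(alns, [gene])
        assert median == pytest.approx((30 / 100) / (15 / 1500))
        assert table.loc[0, "predominant_tss"] == 1000

    def test_predominant_window_is_densest(self):
        gene = GeneModel(
            "g", "chrT", "+", (1000, 4000), [1000, 1300], [(1000, 1200), (1800, 4000)]
        )
        # window of TSS 1000 gets 5 ends (density .05); TSS 1300 gets 20 (.20)
        alns = [_end_at("chrT", 1030 + i) for i in range(5)]
        alns += [_end_at("chrT", 1330 + i) for i in range(20)]
        alns += [_end_at("chrT", 2000 + i * 10) for i in range(30)]
        table, _, _ = pause_indices(alns, [gene])
        assert table.loc[0, "predominant_tss"] == 1300
        assert table.loc[0, "pause_density"] == pytest.approx(0.20)

    def test_all_excluded_reports_causes(self):
        gene = _two_exon_gene()  # body reads absent
        with pytest.raises(ValueError, match="no_body_reads|no_window_reads"):
            pause_indices([_end_at("chrT", 50)], [gene])

    def test_matches_exhaustive_oracle(self, paused_library, annotation50):
        """Every reported pause index equals an independent per-position
        tally over all candidate windows."""
        alns = paused_library.truth_alignments
        per_pos = Counter((a.chrom, a.strand, a.three_prime) for a in alns)

        def window_count(gene, lo, hi):
            return sum(
                per_pos[(gene.chrom, gene.strand, p)] for p in range(lo, hi)
            )

        table, _, _ = pause_indices(
            EndIndex(alns), annotation50.genes, expression_percentile=0
        )
        by_id = {g.gene_id: g for g in annotation50.genes}
        assert len(table) == 50
        for row in table.itertuples():
            gene = by_id[row.gene_id]
            best = None
            for tss in gene.tss_list:
                if gene.strand == "+":
                    lo, hi = tss + 20, tss + 120
                else:
                    lo, hi = tss - 119, tss - 19
                dens = window_count(gene, lo, hi) / 100
                key = (dens, -abs(tss - gene.tss_5prime), -tss)
                if best is None or key > best[0]:
                    best = (key, tss, lo, hi)
            _, tss, lo, hi = best
            if gene.strand == "+":
                body = (tss + 500, gene.span[1])
            else:
                body = (gene.span[0], tss - 499)
            body_count = window_count(gene, *body)
            expected = (window_count(gene, lo, hi) / 100) / (
                body_count / (body[1] - body[0])
            )
            assert row.pause_index == pytest.approx(expected)
            assert row.predominant_tss == tss

    def test_lowering_percentile_never_drops_genes(self, paused_index, annotation50):
        n = {
            pct: len(pause_indices(paused_index, annotation50.genes, pct)[0])
            for pct in (50, 25, 0)
        }
        assert n[0] >= n[25] >= n[50]

    def test_pause_strength_sweep_is_monotone(self, annotation50):
        medians = []
        for strength in (0.0, 0.2, 0.4, 0.6, 0.8):
            lib = simulate_library(
                LibraryParams(n_reads=20_000, pause_strength=strength, seed=1),
                annotation50,
            )
            _, median, _ = pause_indices(
                EndIndex(lib.truth_alignments), annotation50.genes
            )
            medians.append(median)
        assert medians == sorted(medians)


class TestTssEnrichment:
    SIZES = {"chrT": 10_000}

    def test_flat_profile_scores_near_one(self):
        alns = [_end_at("chrT", p) for p in range(0, 10_000)]
        profile, score = tss_enrichment(alns, [("chrT", 5000, "+")], self.SIZES)
        assert profile.min() == profile.max() == 1
        assert score == pytest.approx(1.0, rel=0.02)

    def test_all_reads_at_tss(self):
        alns = [_end_at("chrT", 5000, name=f"r{i}") for i in range(200)]
        profile, score = tss_enrichment(alns, [("chrT", 5000, "+")], self.SIZES)
        assert profile[2000] == 200 and profile.sum() == 200
        assert score > 100

    def test_minus_strand_tss_mirrored(self):
        # a read 30 nt downstream of a minus-strand TSS appears at +30
        alns = [_end_at("chrT", 4970, "-")]
        profile, _ = tss_enrichment(alns, [("chrT", 5000, "-")], self.SIZES)
        assert profile[2000 + 30] == 1

    def test_scale_invariance_above_pseudocount_regime(self):
        base = [_end_at("chrT", p) for p in range(3000, 7001)] * 10
        scaled = base * 5
        _, s1 = tss_enrichment(base, [("chrT", 5000, "+")], self.SIZES)
        _, s2 = tss_enrichment(scaled, [("chrT", 5000, "+")], self.SIZES)
        assert s1 == pytest.approx(s2, rel=0.01)

    def test_no_usable_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_enrichment([_end_at("chrT", 5)], [("chrT", 100, "+")], self.SIZES)

    def test_paused_library_summit_and_score(
        self, paused_index, unpaused_index, annotation50
    ):
        tss_set = [(g.chrom, g.tss_5prime, g.strand) for g in annotation50.genes]
        profile, score = tss_enrichment(paused_index, tss_set, annotation50.chrom_sizes)
        summit = int(np.argmax(profile)) - 2000
        assert 20 <= summit <= 120
        _, score0 = tss_enrichment(unpaused_index, tss_set, annotation50.chrom_sizes)
        assert score > score0


class TestFrif:
    SIZES = {"chrT": 10_000}

    def test_single_promoter_point(self):
        cls = {"promoter": FeatureClass("promoter", [("chrT", 1000, 2000)])}
        alns = [_end_at("chrT", 1500 + i, name=f"r{i}") for i in range(10)]
        curves = cumulative_frif(alns, cls)
        assert curves["promoter"].points == [(pytest.approx(3.0), pytest.approx(1.0))]

    def test_unhit_class_plateaus_at_zero(self):
        cls = {"enhancer": FeatureClass("enhancer", [("chrT", 8000, 8200)])}
        alns = [_end_at("chrT", 100)]
        assert cumulative_frif(alns, cls)["enhancer"].final_fraction() == 0.0

    def test_fraction_nondecreasing_and_final_le_one(self, paused_index, annotation50):
        curves = cumulative_frif(paused_index, annotation50.features)
        for curve in curves.values():
            fracs = [y for _, y in curve.points]
            assert fracs == sorted(fracs)
            assert fracs[-1] <= 1.0 + 1e-12

    def test_final_fraction_matches_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(11)
        alns = [
            _end_at("chrT", int(p), "+" if s else "-")
            for p, s in zip(rng.integers(0, 10_000, 1000), rng.integers(0, 2, 1000))
        ]
        intervals = []
        for _ in range(30):
            s = int(rng.integers(0, 9_800))
            intervals.append(("chrT", s, s + int(rng.integers(20, 200))))
        cls = {"f": FeatureClass("f", intervals)}
        final = cumulative_frif(alns, cls)["f"].final_fraction()
        oracle = sum(
            1
            for a in alns
            for (_, s, e) in intervals
            if s <= a.three_prime < e
        ) / len(alns)
        assert final == pytest.approx(oracle)

    def test_disjoint_classes_sum_to_any_class_fraction(self):
        rng = np.random.default_rng(12)
        alns = [_end_at("chrT", int(p)) for p in rng.integers(0, 10_000, 500)]
        tiles = [("chrT", s, s + 500) for s in range(0, 10_000, 500)]
        classes = {
            f"tile{i}": FeatureClass(f"tile{i}", [iv])
            for i, iv in enumerate(tiles)
        }
        curves = cumulative_frif(alns, classes)
        assert sum(c.final_fraction() for c in curves.values()) == pytest.approx(1.0)

    def test_noncumulative_whole_genome_is_zero(self):
        alns = [AlignedRead("chrT", 100, 130, "+"), AlignedRead("chrT", 500, 530, "-")]
        cls = FeatureClass("all", [("chrT", 0, 10_000)])
        assert noncumulative_frif(alns, cls, 10_000) == pytest.approx(0.0)

    def test_noncumulative_tenfold_enrichment(self):
        cls = FeatureClass("c", [("chrT", 0, 1000)])
        alns = [AlignedRead("chrT", i * 30, i * 30 + 30, "+") for i in range(20)]
        assert noncumulative_frif(alns, cls, 10_000) == pytest.approx(1.0)

    def test_noncumulative_matches_per_base_oracle(self, annotation5):
        lib = simulate_library(LibraryParams(n_reads=1000, seed=17), annotation5)
        alns = lib.truth_alignments
        genome_size = sum(annotation5.chrom_sizes.values())
        for name in ("promoter", "exon", "intron"):
            cls = annotation5.features[name]
            is_class = {
                chrom: np.zeros(size, dtype=bool)
                for chrom, size in annotation5.chrom_sizes.items()
            }
            for chrom, s, e in cls.intervals:
                is_class[chrom][s:e] = True
            observed = sum(
                int(is_class[a.chrom][a.start : a.end].sum()) for a in alns
            )
            total = sum(a.length for a in alns)
            merged_size = cls.merged_size()
            expected = total * merged_size / genome_size
            oracle = math.log10(observed / expected) if observed else -math.inf
            assert noncumulative_frif(alns, cls, genome_size) == pytest.approx(oracle)

    def test_zero_size_class_rejected(self):
        with pytest.raises(ValueError):
            noncumulative_frif([_end_at("chrT", 1)], FeatureClass("e", []), 100)


class TestComplexity:
    @staticmethod
    def _reads(sequences):
        return [Read(f"r{i}", s, [30] * len(s)) for i, s in enumerate(sequences)]

    @staticmethod
    def _seq(i, width=10):
        # unique fixed-width base-4 encoding of i over {A,C,G,T}
        return "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(width))

    def test_all_unique_on_diagonal(self):
        reads = self._reads(self._seq(i) for i in range(100))
        assert len({r.sequence for r in reads}) == 100
        curve, pct = complexity_points(reads, umi_length=8, seed=0)
        assert (curve["n_unique"] == curve["n_sampled"]).all()
        assert pct == pytest.approx(100.0)

    def test_exact_double_duplication_gives_half(self):
        seqs = [self._seq(i) for i in range(50)]
        reads = self._reads(seqs + seqs)
        curve, pct = complexity_points(reads, umi_length=8, seed=0)
        assert pct == pytest.approx(50.0)

    def test_recovers_generator_duplication(self, annotation5):
        lib = simulate_library(
            LibraryParams(n_reads=1000, duplication_rate=0.25, seed=3), annotation5
        )
        _, pct = complexity_points(lib.reads1, umi_length=8, seed=5)
        assert pct == pytest.approx(75.0)

    def test_requires_umi(self):
        with pytest.raises(ValueError, match="UMI"):
            complexity_points(self._reads(["ACGT"]), umi_length=0)


class TestGeneCounts:
    def test_sense_only_and_zero(self):
        gene = _two_exon_gene()
        alns = [_end_at("chrT", 10 + i) for i in range(15)]
        alns += [_end_at("chrT", 10 + i, "-") for i in range(4)]
        empty_gene = GeneModel("g2", "chrT", "+", (5000, 6000), [5000],
                               [(5000, 5100), (5900, 6000)])
        table = gene_counts({"s1": alns}, [gene, empty_gene])
        assert table.loc["g", "s1"] == 15
        assert table.loc["g2", "s1"] == 0

    def test_doubled_signal_doubles_normalized_count(self):
        gene_a = _two_exon_gene("ga")
        gene_b = GeneModel("gb", "chrT", "+", (5000, 6200), [5000],
                           [(5000, 5100), (6100, 6200)])
        s1 = [_end_at("chrT", 10 + i % 1000, name=f"a{i}") for i in range(100)]
        s1 += [_end_at("chrT", 5010 + i % 1000, name=f"b{i}") for i in range(100)]
        # condition 2: gene gb doubled, library depth doubled elsewhere too
        s2 = s1 + [_end_at("chrT", 5010 + i % 1000, name=f"c{i}") for i in range(100)]
        table = gene_counts({"s1": s1, "s2": s2}, [gene_a, gene_b])
        cpm = table / table.sum(axis=0) * 1e6
        assert cpm.loc["gb", "s2"] / cpm.loc["gb", "s1"] == pytest.approx(4 / 3)
        assert table.loc["gb", "s2"] / table.loc["gb", "s1"] == pytest.approx(2.0)

    def test_duplicate_gene_ids_rejected(self):
        gene = _two_exon_gene()
        with pytest.raises(ValueError, match="duplicate"):
            gene_counts({"s": []}, [gene, gene])


def test_refflat_round_trip(annotation5, tmp_path):
    path = tmp_path / "genes.refflat"
    write_gene_models_refflat(annotation5.genes, path)
    back = load_gene_models_refflat(path)
    orig = {g.gene_id: g for g in annotation5.genes}
    assert set(orig) == {g.gene_id for g in back}
    for gene in back:
        ref = orig[gene.gene_id]
        assert gene.strand == ref.strand
        assert gene.span == ref.span
        assert gene.tss_list == sorted(ref.tss_list)
        assert gene.exons == ref.exons
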