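"""Window construction, read counting (vs brute-force oracle), ratio algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bivalency.io import GeneAnnotation, ReadSet
from bivalency.signal import (
    WindowSpec,
    array_enrichment,
    bivalency_ratio,
    count_reads_in_windows,
    default_pseudocount,
    normalize_rpm,
    score_genes,
    tss_window,
)
from conftest import brute_force_counts


class TestTssWindow:
    @pytest.mark.parametrize(
        "tss,strand,up,down,expected",
        [
            (10_000, "+", 3000, 3000, (7000, 13_000)),
            (10_000, "-", 4000, 1000, (9000, 14_000)),  # strand reflection
            (10_000, "+", 4000, 1000, (6000, 11_000)),
            (1000, "+", 3000, 3000, (0, 4000)),  # clipped at chromosome start
        ],
    )
    def test_window_placement(self, tss, strand, up, down, expected):
        gene = GeneAnnotation("G1", "chr16", tss, strand)
        chrom, start, end = tss_window(gene, WindowSpec(up, down))
        assert (start, end) == expected

    @settings(derandomize=True, max_examples=100)
    @given(
        tss=st.integers(min_value=0, max_value=10**8),
        half=st.integers(min_value=1, max_value=10**5),
    )
    def test_symmetric_windows_are_strand_independent(self, tss, half):
        spec = WindowSpec(half, half)
        plus = tss_window(GeneAnnotation("G", "chr1", tss, "+"), spec)
        minus = tss_window(GeneAnnotation("G", "chr1", tss, "-"), spec)
        assert plus == minus

    def test_zero_width_window_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(0, 0)


def _random_instance(rng, n_reads=1000, n_windows=50, span=100_000):
    starts = rng.integers(0, span, size=n_reads)
    lengths = rng.integers(1, 200, size=n_reads)
    reads = ReadSet("m", [("chr1", int(s), int(s + l)) for s, l in zip(starts, lengths)])
    ws = rng.integers(0, span, size=n_windows)
    wl = rng.integers(1, 5000, size=n_windows)
    windows = [("chr1", int(a), int(a + b)) for a, b in zip(ws, wl)]
    return reads, windows


class TestCountReads:
    def test_empty_readset_all_zero(self):
        counts = count_reads_in_windows(ReadSet("m", []), [("chr1", 0, 100)])
        assert counts.tolist() == [0]

    def test_half_open_boundary_overlap(self):
        """A read ending exactly where a window starts does not overlap, but
        one sharing a single base does."""
        reads = ReadSet("m", [("chr1", 100, 136)])
        assert count_reads_in_windows(reads, [("chr1", 135, 200)])[0] == 1
        assert count_reads_in_windows(reads, [("chr1", 136, 200)])[0] == 0

    def test_missing_chromosome_counts_zero(self):
        reads = ReadSet("m", [("chr1", 0, 50)])
        assert count_reads_in_windows(reads, [("chr7", 0, 100)])[0] == 0

    def test_chr_prefix_insensitive_matching(self):
        reads = ReadSet("m", [("1", 10, 40)])
        assert count_reads_in_windows(reads, [("chr1", 0, 100)])[0] == 1

    def test_unknown_overlap_rule_rejected(self):
        with pytest.raises(ValueError, match="overlap_rule"):
            count_reads_in_windows(ReadSet("m", []), [], overlap_rule="centre")

    @pytest.mark.parametrize("rule", ["any", "midpoint", "five_prime"])
    def test_matches_brute_force_oracle(self, rule):
        """Randomised fixtures: searchsorted counting equals a per-read scan."""
        rng = np.random.default_rng(1234)
        for _ in range(20):
            reads, windows = _random_instance(rng, n_reads=300, n_windows=30)
            fast = count_reads_in_windows(reads, windows, overlap_rule=rule)
            slow = brute_force_counts(reads, windows, rule=rule)
            np.testing.assert_array_equal(fast, slow)

    def test_counts_additive_over_pooling(self):
        """Pooling two libraries sums window counts exactly — the property
        underpinning the cell-mixture model."""
        rng = np.random.default_rng(7)
        a, windows = _random_instance(rng, n_reads=200, n_windows=20)
        b, _ = _random_instance(rng, n_reads=150, n_windows=1)
        pooled = a + b
        np.testing.assert_array_equal(
            count_reads_in_windows(pooled, windows),
            count_reads_in_windows(a, windows) + count_reads_in_windows(b, windows),
        )


class TestNormalisation:
    @pytest.mark.parametrize(
        "count,lib,expected", [(0, 5, 0.0), (5, 1_000_000, 5.0), (7, 3_500_000, 2.0)]
    )
    def test_rpm_values(self, count, lib, expected):
        assert normalize_rpm(count, lib) == expected

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            normalize_rpm(1, 0)

    def test_default_pseudocount_is_one_read_in_smaller_library(self):
        k4 = ReadSet("H3K4me3", [("chr1", 0, 1)] * 4)
        k27 = ReadSet("H3K27me3", [("chr1", 0, 1)] * 2)
        assert default_pseudocount(k4, k27) == 1e6 / 2


class TestBivalencyRatio:
    @pytest.mark.parametrize(
        "k4,k27,eps,ratio", [(10, 10, 0, 1.0), (0, 0, 0.5, 1.0), (6, 2, 1, 7 / 3)]
    )
    def test_ratio_values(self, k4, k27, eps, ratio):
        r, lr = bivalency_ratio(k4, k27, eps)
        assert r == pytest.approx(ratio)
        assert lr == pytest.approx(math.log2(ratio))

    def test_zero_denominator_without_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            bivalency_ratio(5, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=0, max_value=1e6),
        b=st.floats(min_value=0, max_value=1e6),
        eps=st.floats(min_value=1e-6, max_value=10),
    )
    def test_reciprocal_symmetry(self, a, b, eps):
        r_ab, _ = bivalency_ratio(a, b, eps)
        r_ba, _ = bivalency_ratio(b, a, eps)
        assert r_ab * r_ba == pytest.approx(1.0, rel=1e-9)


class TestScoreGenes:
    def test_strand_flip_leaves_symmetric_counts_unchanged(self, small_dataset):
        _, genes, _, _, k4, k27 = small_dataset
        flipped = [
            GeneAnnotation(g.gene_id, g.chrom, g.tss, "-" if g.strand == "+" else "+")
            for g in genes
        ]
        a = score_genes(genes, k4, k27)
        b = score_genes(flipped, k4, k27)
        np.testing.assert_array_equal(a["k4_count"], b["k4_count"])
        np.testing.assert_array_equal(a["k27_count"], b["k27_count"])

    def test_raw_counts_path_uses_unit_pseudocount(self, small_dataset):
        _, genes, _, _, k4, k27 = small_dataset
        df = score_genes(genes, k4, k27, raw_counts=True)
        assert (df["pseudocount"] == 1.0).all()
        row = df.iloc[0]
        assert row["ratio"] == pytest.approx(
            (row["k4_count"] + 1) / (row["k27_count"] + 1)
        )


class TestArrayEnrichment:
    def test_identical_tracks_give_unit_enrichment(self):
        track = np.array([1.0, 3.0, 7.0, 2.0])
        np.testing.assert_allclose(array_enrichment(track, track), 1.0)

    def test_doubled_chip_without_normalisation(self):
        inp = np.array([1.0, 2.0, 4.0])
        out = array_enrichment(2 * inp, inp, normalise=False)
        np.testing.assert_allclose(out, 2.0)

    def test_scale_invariance_under_global_normalisation(self):
        """Multiplying either track by a constant leaves enrichment unchanged."""
        rng = np.random.default_rng(3)
        chip = rng.uniform(0.5, 10, size=100)
        inp = rng.uniform(0.5, 10, size=100)
        base = array_enrichment(chip, inp)
        np.testing.assert_allclose(array_enrichment(7.3 * chip, inp), base, rtol=1e-12)
        np.testing.assert_allclose(array_enrichment(chip, 0.11 * inp), base, rtol=1e-12)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            array_enrichment(np.ones(3), np.zeros(3))
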