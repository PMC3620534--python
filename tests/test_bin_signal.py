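"""Bin-level signal statistics against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histodiff.bin_signal import (
    BinCounts,
    BinGrid,
    call_dynamic_bins,
    call_dynamic_bins_matrix,
    dedup_reads,
    extend_and_count,
    fdr_correct,
    filter_covered_bins,
    log2_ratio,
    normalize_equal_counts,
    poisson_enrichment,
    quantile_normalize,
)

from conftest import make_reads


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def poisson_sf_series(k: int, lam: float, tol: float = 1e-14) -> float:
    """P(X >= k) for X ~ Poisson(lam) by direct summation of the pmf."""
    if k <= 0:
        return 1.0
    # sum the lower tail and subtract; terms computed by recurrence
    term = np.exp(-lam)
    cdf = term
    for i in range(1, k):
        term *= lam / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg from the step-up definition, no vectorized tricks."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return q


def count_by_base_enumeration(reads, grid, extension):
    """Per-bin counts by enumerating, per read, every base of its extended
    interval and collecting the set of bins touched."""
    counts = np.zeros(grid.n_bins(), dtype=int)
    for r in reads.itertuples(index=False):
        size = grid.chrom_sizes[r.chrom]
        five = r.start if r.strand == "+" else r.end
        lo, hi = (five, five + extension) if r.strand == "+" else (five - extension, five)
        touched = set()
        for base in range(max(0, lo), min(size, hi)):
            touched.add(int(grid.bin_index(r.chrom, base)))
        for b in touched:
            counts[b] += 1
    return counts


# ---------------------------------------------------------------------------
# grid and counting
# ---------------------------------------------------------------------------

class TestBinGrid:
    def test_bins_tile_chromosome_with_short_last_bin(self):
        grid = BinGrid({"chr1": 1200}, width=500)
        df = grid.to_dataframe()
        assert list(df["start"]) == [0, 500, 1000]
        assert list(df["end"]) == [500, 1000, 1200]

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            BinGrid({"chr1": 1000}, width=0)


class TestExtendAndCount:
    def test_no_reads_gives_all_zero_counts(self, small_grid):
        bc = extend_and_count(make_reads([]), small_grid)
        assert bc.total == 0
        assert not bc.counts.any()

    def test_plus_read_spanning_bin_boundary_increments_both(self, small_grid):
        # + read with 5' end 480 extends to [480, 680): bins 0 and 1
        bc = extend_and_count(make_reads([("chr1", 480, 516, "+")]), small_grid)
        assert bc.counts[0] == 1 and bc.counts[1] == 1
        assert bc.counts[2:].sum() == 0

    def test_minus_read_extends_leftward_from_five_prime(self, small_grid):
        # - read with 5' end 510 extends to [310, 510): last covered base 509
        # sits in bin 1, so both bins are incremented (coverage counting)
        bc = extend_and_count(make_reads([("chr1", 474, 510, "-")]), small_grid)
        assert bc.counts[0] == 1 and bc.counts[1] == 1
        assert bc.counts[2:].sum() == 0

    def test_minus_read_half_open_five_prime_boundary(self, small_grid):
        # - read with 5' end exactly at 500 covers [300, 500): bin 0 only,
        # because the half-open interval excludes base 500
        bc = extend_and_count(make_reads([("chr1", 464, 500, "-")]), small_grid)
        assert bc.counts[0] == 1
        assert bc.counts[1:].sum() == 0

    def test_extension_clipped_at_chromosome_end(self, small_grid):
        bc = extend_and_count(make_reads([("chr1", 9990, 9999, "+")]), small_grid)
        assert bc.counts[-1] == 1 and bc.total == 1

    def test_unknown_chromosome_raises_or_skips(self, small_grid):
        reads = make_reads([("chrX", 0, 36, "+")])
        with pytest.raises(ValueError, match="chrX"):
            extend_and_count(reads, small_grid)
        bc = extend_and_count(reads, small_grid, on_unknown_chrom="skip")
        assert bc.total == 0

    def test_matches_per_base_enumeration_oracle(self, rng):
        grid = BinGrid({"chr1": 3000, "chr2": 2200}, width=500)
        for _ in range(5):
            n = int(rng.integers(1, 50))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            fives = np.array([rng.integers(0, grid.chrom_sizes[c]) for c in chroms])
            strands = rng.choice(["+", "-"], size=n)
            starts = np.where(strands == "+", fives, np.maximum(0, fives - 36))
            ends = np.where(strands == "+", fives + 36, fives)
            keep = ends > starts
            reads = make_reads(
                list(zip(chroms[keep], starts[keep], ends[keep], strands[keep]))
            )
            got = extend_and_count(reads, grid, extension=200)
            expected = count_by_base_enumeration(reads, grid, extension=200)
            np.testing.assert_array_equal(got.counts, expected)

    def test_dedup_collapses_identical_five_prime_records(self):
        reads = make_reads([("chr1", 100, 136, "+"), ("chr1", 100, 136, "+"),
                            ("chr1", 100, 136, "-")])
        assert len(dedup_reads(reads)) == 2


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestEqualCountNormalization:
    @pytest.mark.parametrize(
        "totals, expected",
        [([100, 100], [1.0, 1.0]), ([100, 200], [1.0, 0.5]), ([100], [1.0])],
    )
    def test_scale_factors(self, totals, expected):
        samples = [
            BinCounts((f"s{i}",), np.array([t])) for i, t in enumerate(totals)
        ]
        np.testing.assert_allclose(normalize_equal_counts(samples), expected)

    def test_zero_total_sample_named_in_error(self):
        samples = [BinCounts(("good",), np.array([10])), BinCounts(("empty",), np.array([0]))]
        with pytest.raises(ValueError, match="empty"):
            normalize_equal_counts(samples)


# ---------------------------------------------------------------------------
# Poisson enrichment
# ---------------------------------------------------------------------------

class TestPoissonEnrichment:
    def test_zero_chip_count_has_p_one(self):
        _, p = poisson_enrichment(0, 5, 1.0, 0.5)
        assert p == 1.0

    def test_hand_summed_tail_chip3_lambda1(self):
        # P(X >= 3) = 1 - e^{-1}(1 + 1 + 1/2)
        _, p = poisson_enrichment(3, 1, 1.0, 1e-12)
        assert p == pytest.approx(1 - np.exp(-1) * 2.5, abs=1e-12)

    def test_hand_summed_tail_chip10_lambda10(self):
        _, p = poisson_enrichment(10, 10, 1.0, 1e-12)
        assert p == pytest.approx(poisson_sf_series(10, 10.0), abs=1e-12)
        assert p == pytest.approx(0.542, abs=5e-4)

    def test_matches_series_summation_oracle(self):
        for chip in [0, 1, 2, 5, 17, 40, 100]:
            for lam in [0.1, 0.5, 1.0, 3.7, 10.0, 55.0]:
                _, p = poisson_enrichment(chip, 1, lam, lam)
                assert p == pytest.approx(poisson_sf_series(chip, lam), abs=1e-10)

    def test_lambda_floor_applies_when_control_empty(self):
        fc, p = poisson_enrichment(5, 0, 1.0, 2.0)
        assert p == pytest.approx(poisson_sf_series(5, 2.0), abs=1e-12)
        assert fc == pytest.approx(6 / 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_enrichment(-1, 0, 1.0, 1.0)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

class TestFdrCorrect:
    def test_hand_bh_computation(self):
        np.testing.assert_allclose(fdr_correct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_of_one(self):
        np.testing.assert_allclose(fdr_correct([1.0]), [1.0])

    def test_empty_input_gives_empty_output(self):
        assert fdr_correct([]).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100), st.integers(0, 2**31 - 1))
    def test_matches_stepup_oracle_and_preserves_rank_order(self, p, _seed):
        p = np.asarray(p)
        q = fdr_correct(p)
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
        # monotone: rank order of q follows rank order of p
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all()


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_hand_rank_mean_computation(self):
        X = np.array([[1, 2], [2, 4], [3, 6]], dtype=float)
        out = quantile_normalize(X)
        np.testing.assert_allclose(out[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.0, 4.5])

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0, 3.0])
        out = quantile_normalize(np.column_stack([col, col]))
        np.testing.assert_allclose(out, np.column_stack([col, col]))

    def test_ties_receive_mean_of_rank_means(self):
        X = np.array([[1, 10], [1, 20], [5, 30]], dtype=float)
        out = quantile_normalize(X)
        rank_means = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out[0, 0] == pytest.approx(rank_means[:2].mean())
        assert out[1, 0] == pytest.approx(rank_means[:2].mean())
        assert out[2, 0] == pytest.approx(rank_means[2])

    def test_sorted_columns_identical_after_normalization(self, rng):
        # tie-free columns: every column's sorted values equal the rank means
        X = rng.random((200, 5))
        out = quantile_normalize(X)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)

    def test_within_column_rank_order_preserved(self, rng):
        X = rng.random((100, 3))
        out = quantile_normalize(X)
        for j in range(3):
            assert (np.argsort(X[:, j], kind="mergesort")
                    == np.argsort(out[:, j], kind="mergesort")).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones((5, 1)))


# ---------------------------------------------------------------------------
# dynamic bins and coverage filter
# ---------------------------------------------------------------------------

class TestDynamicBinCalls:
    @pytest.mark.parametrize(
        "fcs, direction, n",
        [
            ([0.3, 0.25, 0.21, -0.1], "increased", 3),
            ([0.3, 0.25, -0.3, -0.25], "unchanged", 2),
            ([-0.21, -0.5, -0.9, -0.3], "decreased", 4),
            ([0.2, 0.2, 0.2, 0.2], "unchanged", 0),  # threshold is strict
        ],
    )
    def test_three_of_four_donor_rule(self, fcs, direction, n):
        got_dir, got_n = call_dynamic_bins(fcs)
        assert got_dir == direction
        assert got_n == n

    def test_fewer_donors_than_required_rejected(self):
        with pytest.raises(ValueError):
            call_dynamic_bins([0.3, 0.3])

    def test_matrix_version_agrees_with_scalar(self, rng):
        fc = rng.normal(0, 0.4, size=(50, 4))
        table = call_dynamic_bins_matrix(fc)
        for i in range(50):
            d, n = call_dynamic_bins(fc[i])
            assert table["direction"][i] == d

    def test_directions_mutually_exclusive(self, rng):
        fc = rng.normal(0, 1.0, size=(200, 4))
        table = call_dynamic_bins_matrix(fc, min_donors=2)
        up = (fc > 0.2).sum(axis=1) >= 2
        down = (fc < -0.2).sum(axis=1) >= 2
        both = up & down
        assert (table.loc[both, "direction"] == "unchanged").all()


class TestCoverageFilter:
    def test_all_below_threshold_empty(self):
        assert not filter_covered_bins(np.full((5, 3), 199)).any()

    def test_exactly_200_kept(self):
        mask = filter_covered_bins(np.array([[200, 0], [199, 199]]))
        assert mask.tolist() == [True, False]

    def test_zero_threshold_keeps_everything(self):
        assert filter_covered_bins(np.zeros((4, 2)), min_reads=0).all()


def test_log2_ratio_pseudocount_symmetry():
    assert log2_ratio(0, 0) == 0.0
    assert log2_ratio(100, 100) == 0.0
    assert log2_ratio(4000, 1000) == pytest.approx(2.0, abs=0.01)
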