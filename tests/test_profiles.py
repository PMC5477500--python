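"""Binned RPKM profiles, expression grouping and lowess smoothing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ire_screen.io_formats import CoverageTrack, GenomicInterval
from ire_screen.peaks import Peak
from ire_screen.profiles import (
    binned_rpkm,
    expression_groups,
    group_average_profile,
    lowess_smooth,
    profile_matrix,
    sort_rows_by_expression,
)


def track_from(cov, chrom="c", total_reads=None):
    return CoverageTrack.from_array(chrom, np.asarray(cov),
                                    total_reads=total_reads)


class TestBinnedRpkm:
    def test_zero_coverage(self):
        track = track_from(np.zeros(100), total_reads=1e6)
        v = binned_rpkm(track, GenomicInterval("c", 0, 100), 20)
        assert np.all(v == 0)

    def test_formula_forced(self):
        """20-bp bin holding 2 counts in a 1e6-read library -> RPKM 100."""
        cov = np.zeros(100)
        cov[5] = 2
        track = track_from(cov, total_reads=1e6)
        v = binned_rpkm(track, GenomicInterval("c", 0, 20), 20)
        assert v[0] == pytest.approx(100.0)

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(0, 10, size=1000)
        track = track_from(cov)
        window = GenomicInterval("c", 40, 840)
        got = binned_rpkm(track, window, 20)
        for i in range(len(got)):
            count = cov[40 + 20 * i: 40 + 20 * (i + 1)].sum()
            expect = count / (20 / 1000) / (track.total_reads / 1e6)
            assert got[i] == pytest.approx(expect, abs=1e-12)

    def test_conservation_identity(self):
        """Sum of RPKM*bin_kb*lib_millions over bins = window coverage, exact."""
        rng = np.random.default_rng(1)
        cov = rng.integers(0, 7, size=500)
        track = track_from(cov)
        window = GenomicInterval("c", 100, 400)
        v = binned_rpkm(track, window, 10)
        recovered = (v * (10 / 1000) * (track.total_reads / 1e6)).sum()
        assert recovered == pytest.approx(cov[100:400].sum(), abs=1e-9)

    def test_scale_equivariance(self):
        """Doubling coverage and library size leaves RPKM unchanged."""
        rng = np.random.default_rng(2)
        cov = rng.integers(0, 5, size=300)
        w = GenomicInterval("c", 0, 300)
        v1 = binned_rpkm(track_from(cov), w, 30)
        v2 = binned_rpkm(track_from(2 * cov), w, 30)
        np.testing.assert_allclose(v1, v2)

    def test_zero_library_rejected(self):
        track = track_from(np.zeros(10), total_reads=0)
        with pytest.raises(ValueError):
            binned_rpkm(track, GenomicInterval("c", 0, 10), 10)

    def test_indivisible_bin_rejected(self):
        track = track_from(np.ones(10))
        with pytest.raises(ValueError):
            binned_rpkm(track, GenomicInterval("c", 0, 10), 3)


def peak_at(summit, chrom="c", name="p"):
    return Peak(GenomicInterval(chrom, max(0, summit - 100), summit + 100),
                score=1.0, summit=summit, name=name)


class TestProfileMatrix:
    def test_single_peak_shape(self):
        track = track_from(np.ones(10000))
        m = profile_matrix([peak_at(5000)], track, flank=2000, bin_size=20)
        assert m.values.shape == (1, 200)

    def test_identical_peaks_identical_rows(self):
        track = track_from(np.arange(10000) % 17)
        m = profile_matrix([peak_at(5000, name="a"), peak_at(5000, name="b")],
                           track, flank=1000, bin_size=10)
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_row_sums_match_brute_force(self):
        rng = np.random.default_rng(3)
        cov = rng.integers(0, 6, size=50000)
        track = track_from(cov)
        peaks = [peak_at(int(s), name=f"p{i}")
                 for i, s in enumerate(rng.integers(3000, 47000, size=50))]
        m = profile_matrix(peaks, track, flank=2000, bin_size=20)
        for i, p in enumerate(peaks):
            s = p.summit
            window_count = cov[s - 2000: s + 2000].sum()
            recovered = (m.values[i] * (20 / 1000)
                         * (track.total_reads / 1e6)).sum()
            assert recovered == pytest.approx(window_count, abs=1e-6)

    def test_clipped_window_is_masked_not_dropped(self):
        track = track_from(np.ones(10000))
        m = profile_matrix([peak_at(500)], track, flank=2000, bin_size=20)
        assert m.n_rows == 1
        # bins covering [-1500, 0) are masked
        assert m.valid[0, :75].sum() == 0
        assert m.valid[0, 75:].all()
        assert np.all(m.values[0, :75] == 0)


class TestSortAndGroup:
    def _matrix(self, genes, expr):
        track = track_from(np.ones(100000))
        peaks = [peak_at(5000 + 3000 * i, name=f"p{i}")
                 for i in range(len(genes))]
        return profile_matrix(peaks, track, flank=1000, bin_size=100,
                              target_genes=genes, expression=expr)

    def test_descending_order(self):
        expr = {"a": 3.0, "b": 1.0, "c": 2.0}
        m = self._matrix(["a", "b", "c"], expr)
        sorted_m, dropped = sort_rows_by_expression(m)
        assert dropped == 0
        assert list(sorted_m.row_meta["target_gene"]) == ["a", "c", "b"]

    def test_reversed_input_reversed(self):
        expr = {g: float(i) for i, g in enumerate("abcde")}
        m = self._matrix(list("abcde"), expr)
        sorted_m, _ = sort_rows_by_expression(m)
        assert list(sorted_m.row_meta["target_gene"]) == list("edcba")

    def test_random_permutation_matches_argsort_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        expr = {g: float(v) for g, v in zip(genes, rng.normal(size=20))}
        order = rng.permutation(20)
        m = self._matrix([genes[i] for i in order], expr)
        sorted_m, _ = sort_rows_by_expression(m)
        oracle = sorted(genes, key=lambda g: (-expr[g], g))
        assert list(sorted_m.row_meta["target_gene"]) == oracle

    def test_rows_without_targets_dropped_and_counted(self):
        m = self._matrix(["a", None, "b"], {"a": 1.0, "b": 2.0})
        sorted_m, dropped = sort_rows_by_expression(m)
        assert dropped == 1
        assert sorted_m.n_rows == 2


class TestExpressionGroups:
    def test_one_to_nine(self):
        labels = expression_groups(np.arange(1, 10))
        assert list(labels[:3]) == ["low"] * 3
        assert list(labels[3:6]) == ["intermediate"] * 3
        assert list(labels[6:]) == ["high"] * 3

    def test_all_equal_stable_split(self):
        labels = expression_groups(np.ones(10))
        counts = {k: (labels == k).sum() for k in set(labels)}
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_hundred_random_values(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=100)
        labels = expression_groups(values)
        counts = sorted(((labels == k).sum() for k in
                         ("low", "intermediate", "high")), reverse=True)
        assert counts == [34, 33, 33]
        # rank consistency: every high value >= every low value
        assert values[labels == "high"].min() >= values[labels == "low"].max()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            expression_groups([1.0, 2.0])


class TestGroupAverage:
    def _matrix_from_values(self, values, valid=None):
        import pandas as pd
        from ire_screen.profiles import ProfileMatrix
        values = np.asarray(values, dtype=float)
        if valid is None:
            valid = np.ones_like(values, dtype=bool)
        meta = pd.DataFrame({
            "peak": [f"p{i}" for i in range(len(values))],
            "target_gene": [None] * len(values),
            "expression": np.nan,
        })
        return ProfileMatrix(values, valid, flank=len(values[0]) * 5,
                             bin_size=10, row_meta=meta)

    def test_single_row_group(self):
        m = self._matrix_from_values([[1.0, 2.0], [5.0, 6.0]])
        avg = group_average_profile(m, ["a", "b"])
        np.testing.assert_array_equal(avg["a"], [1.0, 2.0])

    def test_two_row_mean(self):
        m = self._matrix_from_values([[0.0, 0.0], [2.0, 2.0]])
        avg = group_average_profile(m, ["g", "g"])
        np.testing.assert_array_equal(avg["g"], [1.0, 1.0])

    def test_masked_bins_excluded(self):
        valid = np.array([[False, True], [True, True]])
        m = self._matrix_from_values([[9.0, 2.0], [4.0, 4.0]], valid)
        avg = group_average_profile(m, ["g", "g"])
        np.testing.assert_array_equal(avg["g"], [4.0, 3.0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.random((12, 8))
        labels = rng.choice(["x", "y", "z"], size=12)
        m = self._matrix_from_values(values)
        avg = group_average_profile(m, labels)
        for name in "xyz":
            rows = [values[i] for i in range(12) if labels[i] == name]
            expect = np.mean(rows, axis=0)
            np.testing.assert_allclose(avg[name], expect)

    def test_misaligned_labels_raise(self):
        m = self._matrix_from_values([[1.0, 2.0]])
        with pytest.raises(ValueError):
            group_average_profile(m, ["a", "b"])


def lowess_oracle(y, f):
    """Direct-summation local linear regression, written independently."""
    import math
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = min(n, max(2, math.ceil(f * n)))
    out = []
    for i in range(n):
        dists = sorted((abs(j - i), j) for j in range(n))
        h = dists[k - 1][0]
        if h == 0:
            out.append(y[i])
            continue
        sw = sx = sy = sxx = sxy = 0.0
        for j in range(n):
            d = abs(j - i) / h
            if d >= 1:
                continue
            w = (1 - d**3) ** 3
            sw += w
            sx += w * j
            sy += w * y[j]
            sxx += w * j * j
            sxy += w * j * y[j]
        denom = sw * sxx - sx * sx
        if denom <= 0:
            out.append(sy / sw)
        else:
            b = (sw * sxy - sx * sy) / denom
            a = (sy - b * sx) / sw
            out.append(a + b * i)
    return np.array(out)


class TestLowess:
    def test_constant_reproduced(self):
        y = np.full(40, 3.25)
        np.testing.assert_allclose(lowess_smooth(y, 0.3), y, atol=1e-9)

    def test_linear_exact_at_full_span(self):
        y = 0.5 * np.arange(30) - 2.0
        np.testing.assert_allclose(lowess_smooth(y, 1.0), y, atol=1e-9)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 4 * np.pi, 80)
        y = np.sin(x) + rng.normal(0, 0.3, size=80)
        got = lowess_smooth(y, 0.3)
        expect = lowess_oracle(y, 0.3)
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lowess_smooth([1.0], 0.3)
        with pytest.raises(ValueError):
            lowess_smooth([1.0, 2.0], 0.0)
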