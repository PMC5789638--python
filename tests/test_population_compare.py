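"""Per-individual ROH summaries and channel comparison statistics."""

import itertools

import numpy as np
import pytest

from rohcompare import (
    ROHCallSet,
    ROHSegment,
    compare_channels,
    comparison_matrices,
    length_class_sums,
    mww_test,
    pearson_r,
    summarize_individuals,
)

from oracles import mww_oracle


def make_callset(lengths_by_individual, population="P", h=1):
    """Callset with the given per-individual segment lengths (Mb)."""
    segments = []
    for iid, lengths in lengths_by_individual.items():
        pos = 1
        for k, mb in enumerate(lengths):
            length = int(mb * 1e6)
            segments.append(
                ROHSegment(iid, (k % 22) + 1, pos, pos + length - 1,
                           max(50, length // 10_000), 0)
            )
            pos += length + 2_000_000
    return ROHCallSet(segments=segments, population=population, het_tolerance=h)


class TestSummaries:
    def test_threshold_arithmetic(self):
        cs = make_callset({"a": [1.2, 2.0, 0.8]})
        row = summarize_individuals(cs).iloc[0]
        assert row["nroh"] == 2
        assert row["mean_size_mb"] == pytest.approx(1.6)
        assert row["sroh_mb"] == pytest.approx(3.2)

    def test_individual_without_segments_reports_zero(self):
        cs = make_callset({"a": [2.0]})
        table = summarize_individuals(cs, individuals=["a", "b"])
        b = table.set_index("individual_id").loc["b"]
        assert b["nroh"] == 0 and b["sroh_mb"] == 0.0
        assert np.isnan(b["mean_size_mb"])

    def test_matches_filter_and_aggregate_oracle(self, rng):
        for _ in range(15):
            lengths = {
                f"i{k}": list(rng.uniform(0.3, 12, size=rng.integers(0, 8)))
                for k in range(5)
            }
            table = summarize_individuals(
                make_callset(lengths), individuals=sorted(lengths)
            ).set_index("individual_id")
            for iid, ls in lengths.items():
                # the builder snaps lengths to whole bp; mirror that
                qual = [int(x * 1e6) / 1e6 for x in ls if int(x * 1e6) / 1e6 > 1.0]
                assert table.loc[iid, "nroh"] == len(qual)
                assert table.loc[iid, "sroh_mb"] == pytest.approx(sum(qual))
                if qual:
                    assert table.loc[iid, "mean_size_mb"] == pytest.approx(
                        np.mean(qual)
                    )

    def test_sroh_equals_nroh_times_mean(self, rng):
        lengths = {f"i{k}": list(rng.uniform(1.1, 9, size=4)) for k in range(6)}
        table = summarize_individuals(make_callset(lengths))
        np.testing.assert_allclose(
            table["sroh_mb"], table["nroh"] * table["mean_size_mb"], atol=1e-9
        )


class TestMWW:
    def test_identical_samples_give_p_one(self):
        assert mww_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_fully_separated_triples_exact_p(self):
        # U = 0; 2 of the 20 orderings are as extreme (two-sided)
        assert mww_test([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)
        assert mww_oracle([1, 2, 3], [10, 20, 30]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mww_test([], [1.0])

    def test_symmetric_under_sample_swap(self, rng):
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(loc=0.5, size=rng.integers(3, 15))
            assert mww_test(a, b) == pytest.approx(mww_test(b, a), rel=1e-12)

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(8):
            a = list(rng.normal(size=5))
            b = list(rng.normal(loc=0.8, size=4))
            assert mww_test(a, b) == pytest.approx(mww_oracle(a, b), abs=1e-12)

    def test_asymptotic_close_to_enumeration_at_n10(self, rng):
        a = list(rng.normal(size=10))
        b = list(rng.normal(loc=0.3, size=10))
        exact = mww_oracle(a, b)  # 184k label assignments
        # a duplicated value introduces a tie, forcing the asymptotic path
        approx = mww_test(a[:9] + [a[0]], b)
        assert abs(approx - mww_oracle(a[:9] + [a[0]], b)) < 0.02
        from scipy.stats import mannwhitneyu

        asym = float(
            mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        assert abs(asym - exact) < 0.01


class TestPearson:
    def test_perfect_and_inverse_correlation(self):
        r, p = pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_summation(self, rng):
        a = rng.normal(size=30)
        b = 0.4 * a + rng.normal(size=30)
        r, p = pearson_r(a, b)
        # textbook formula, computed independently
        am, bm = a - a.mean(), b - b.mean()
        r_direct = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert r == pytest.approx(float(r_direct), abs=1e-12)
        from scipy.stats import t as t_dist

        t_stat = r_direct * np.sqrt(28 / (1 - r_direct**2))
        assert p == pytest.approx(float(2 * t_dist.sf(abs(t_stat), df=28)), rel=1e-9)

    def test_zero_variance_is_absent(self):
        assert pearson_r([1, 1, 1], [1, 2, 3]) is None


class TestCompareChannels:
    def test_identical_processes_not_significant(self, rng):
        lengths = {
            f"i{k}": list(rng.uniform(1.1, 9, size=rng.integers(2, 8)))
            for k in range(12)
        }
        array_cs = make_callset(lengths)
        wgs_css = {1: make_callset(lengths), 3: make_callset(lengths)}
        res = compare_channels(array_cs, wgs_css, sorted(lengths))
        assert (res["mww_p"] == 1.0).all()
        np.testing.assert_allclose(res["pearson_r"], 1.0, atol=1e-9)

    def test_unknown_individuals_rejected(self):
        array_cs = make_callset({"a": [2.0], "b": [3.0], "c": [1.5]})
        with pytest.raises(ValueError, match="outside the common cohort"):
            compare_channels(array_cs, {1: array_cs}, ["a", "b"])

    def test_matrix_pivot_shapes(self, rng):
        lengths = {f"i{k}": list(rng.uniform(1.1, 9, size=5)) for k in range(8)}
        res = compare_channels(
            make_callset(lengths),
            {h: make_callset(lengths) for h in (1, 2, 3)},
            sorted(lengths),
        )
        mats = comparison_matrices(res)
        assert set(mats) == {
            f"{s}_{q}" for s, q in itertools.product(
                ("nroh", "mean_size", "sroh"), ("pearson_r", "mww_p")
            )
        }
        assert mats["nroh_mww_p"].shape == (1, 3)


class TestLengthClasses:
    def test_one_segment_per_class(self):
        cs = make_callset({"a": [0.5, 3.0, 9.0]})
        row = length_class_sums(cs).iloc[0]
        assert row["short"] == pytest.approx(0.5)
        assert row["medium"] == pytest.approx(3.0)
        assert row["long"] == pytest.approx(9.0)

    def test_empty_callset_all_zero(self):
        table = length_class_sums(ROHCallSet(segments=[]), individuals=["a"])
        assert table[["short", "medium", "long", "total"]].to_numpy().sum() == 0

    def test_partition_identity(self, rng):
        lengths = {f"i{k}": list(rng.uniform(0.31, 15, size=6)) for k in range(5)}
        cs = make_callset(lengths)
        table = length_class_sums(cs)
        np.testing.assert_allclose(
            table["short"] + table["medium"] + table["long"], table["total"],
            atol=1e-9,
        )
        for iid, ls in lengths.items():
            expected = sum(int(x * 1e6) / 1e6 for x in ls if int(x * 1e6) / 1e6 >= 0.3)
            got = table.set_index("individual_id").loc[iid, "total"]
            assert got == pytest.approx(expected)
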