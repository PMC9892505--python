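import numpy as np
import pytest
from scipy import stats as sps

from audioshape.core import Audiogram
from audioshape.normalization import NormalizedDataset
from audioshape.stat_selection import (
    FAIL,
    REJECT,
    correlation_t_test,
    f_variance_test,
    paired_t_test,
    select_normalizations,
)


def _f_test_oracle(x, y):
    """Two-sided variance-ratio p-value straight from the F distribution."""
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    f = v1 / v2
    p = 2.0 * min(
        sps.f.sf(f, len(x) - 1, len(y) - 1), sps.f.cdf(f, len(x) - 1, len(y) - 1)
    )
    return min(p, 1.0)


class TestPairedT:
    def test_identical_vectors_fail_to_reject(self):
        x = np.arange(10.0)
        res = paired_t_test(x, x.copy())
        assert res.p_value == 1.0 and res.decision == FAIL
        assert res.statistic == 0.0

    def test_constant_nonzero_shift_rejects_certainly(self):
        x = np.arange(10.0)
        res = paired_t_test(x + 3.0, x)
        assert res.p_value == 0.0 and res.decision == REJECT

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            m = rng.integers(5, 481)
            a = rng.normal(size=m)
            b = a + rng.normal(0.1, 0.5, size=m)
            res = paired_t_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert res.df == (m - 1,)

    def test_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelationT:
    def test_perfect_linear_relation_is_significant(self):
        x = np.arange(10.0)
        res = correlation_t_test(x, 2 * x + 1)
        assert res.extra["r"] == pytest.approx(1.0)
        assert res.p_value < 1e-50 and res.decision == REJECT

    def test_exactly_orthogonal_vectors_fail(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = correlation_t_test(x, y)
        assert res.statistic == 0.0 and res.decision == FAIL

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = rng.integers(5, 61)
            x = rng.normal(size=m)
            y = 0.4 * x + rng.normal(size=m)
            res = correlation_t_test(x, y)
            ref = sps.pearsonr(x, y)
            assert res.extra["r"] == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlation_t_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFVariance:
    def test_identical_samples_give_unit_f(self):
        x = np.arange(10.0)
        res = f_variance_test(x, x.copy())
        assert res.statistic == 1.0 and res.decision == FAIL

    def test_tenfold_scaling_gives_f_hundred(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 10, size=30)
        y = 10.0 * (x - x.mean()) + x.mean()
        res = f_variance_test(x, y)
        assert res.statistic == pytest.approx(100.0)
        assert res.decision == REJECT

    def test_larger_variance_always_in_numerator(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = rng.normal(scale=3.0, size=25)
        assert f_variance_test(x, y).statistic >= 1.0
        assert f_variance_test(y, x).statistic >= 1.0

    def test_matches_f_distribution_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(5, 60, size=2)
            x = rng.normal(scale=rng.uniform(0.5, 2.0), size=n1)
            y = rng.normal(scale=rng.uniform(0.5, 2.0), size=n2)
            res = f_variance_test(x, y)
            assert res.p_value == pytest.approx(_f_test_oracle(x, y), abs=1e-10)
            # decision via critical value agrees with the p-value rule
            assert (res.decision == REJECT) == (res.p_value < res.alpha)

    def test_both_variances_zero_is_degenerate_equality(self):
        res = f_variance_test([2.0, 2.0, 2.0], [5.0, 5.0])
        assert res.statistic == 1.0 and res.p_value == 1.0 and res.decision == FAIL


def _dataset(name, matrix):
    return NormalizedDataset(
        method_name=name,
        audiograms=[Audiogram(levels=row, id=f"a{i}") for i, row in enumerate(matrix)],
    )


def _gate_fixture(rng, n=12):
    """20 methods built so the gates remove 6, then 4, then 0 -> retain 10.

    Base data plays the z-score reference role.  Six methods are noisy
    zero-mean-difference copies (removed by the paired t-test), four are
    constant shifts (mean differs, variance identical: removed by the
    F-test), and nine are proper affine rescalings (retained with the
    reference itself).
    """
    base = rng.normal(50, 15, size=(n, 8))
    datasets = [_dataset("z_score", base)]
    for i in range(6):
        noise = rng.normal(0, 0.5, size=base.shape)
        datasets.append(_dataset(f"redundant_mean_{i}", base + noise - noise.mean()))
    for i in range(4):
        datasets.append(_dataset(f"same_variance_{i}", base + 5.0 * (i + 1)))
    for i in range(9):
        datasets.append(_dataset(f"affine_{i}", (2.0 + i) * base + 10.0 * i + 40.0))
    return datasets


class TestSelectNormalizations:
    def test_twenty_methods_give_190_pairwise_records(self):
        rng = np.random.default_rng(8)
        report = select_normalizations(_gate_fixture(rng), reference="z_score")
        assert len(report.all_pairwise) == 190

    def test_constructed_gates_remove_six_four_zero(self):
        rng = np.random.default_rng(8)
        report = select_normalizations(_gate_fixture(rng), reference="z_score")
        assert len(report.removed_by_mean_test) == 6
        assert all(m.startswith("redundant_mean") for m in report.removed_by_mean_test)
        assert len(report.removed_by_variance_test) == 4
        assert all(m.startswith("same_variance") for m in report.removed_by_variance_test)
        assert report.removed_by_correlation_test == []
        assert len(report.retained) == 10

    def test_removed_and_retained_partition_the_methods(self):
        rng = np.random.default_rng(9)
        datasets = _gate_fixture(rng)
        report = select_normalizations(datasets, reference="z_score")
        removed = (
            report.removed_by_mean_test
            + report.removed_by_variance_test
            + report.removed_by_correlation_test
        )
        assert sorted(removed + report.retained) == sorted(d.method_name for d in datasets)
        assert not set(removed) & set(report.retained)

    def test_duplicate_of_reference_removed_at_mean_gate(self):
        rng = np.random.default_rng(10)
        base = rng.normal(50, 15, size=(10, 8))
        datasets = [
            _dataset("z_score", base),
            _dataset("copycat", base.copy()),
            _dataset("affine", 2.0 * base + 5.0),
        ]
        report = select_normalizations(datasets, reference="z_score")
        assert report.removed_by_mean_test == ["copycat"]
        assert set(report.retained) == {"z_score", "affine"}

    def test_negatively_correlated_method_removed_at_correlation_gate(self):
        rng = np.random.default_rng(11)
        base = rng.normal(50, 15, size=(10, 8))
        datasets = [
            _dataset("z_score", base),
            _dataset("mirror", -3.0 * base),  # shape inverted
        ]
        report = select_normalizations(datasets, reference="z_score")
        assert report.removed_by_correlation_test == ["mirror"]

    def test_pairwise_records_symmetric_up_to_sign(self):
        rng = np.random.default_rng(12)
        base = rng.normal(50, 15, size=(8, 8))
        datasets = [
            _dataset("z_score", base),
            _dataset("b", 2.0 * base + 1.0),
            _dataset("c", base + rng.normal(0, 1, size=base.shape)),
        ]
        report = select_normalizations(datasets, reference="z_score")
        by_pair = {(t.method_a, t.method_b): t for t in report.all_pairwise}
        for (a, b), t in by_pair.items():
            flipped = paired_t_test(
                np.concatenate([x.levels for x in datasets[[d.method_name for d in datasets].index(b)].audiograms]),
                np.concatenate([x.levels for x in datasets[[d.method_name for d in datasets].index(a)].audiograms]),
            )
            assert flipped.statistic == pytest.approx(-t.statistic, abs=1e-12)
            assert flipped.p_value == pytest.approx(t.p_value, abs=1e-12)

    def test_unknown_reference_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="reference"):
            select_normalizations(_gate_fixture(rng), reference="nope")
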