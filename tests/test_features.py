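import numpy as np
import pytest

from audioshape.core import Audiogram
from audioshape.features import (
    BASE_FEATURE_NAMES,
    NESTED_FEATURE_SPEC,
    FeatureVector,
    ResidualMap,
    base_features,
    final_arrangement,
    fit_nested,
    fit_residual_map,
    nested_features,
    polynomial_residual,
    reduce_all,
    reduce_features,
)
from tests.conftest import random_audiograms


class TestBaseFeatures:
    def test_exactly_39_features(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        assert len(fv) == 39
        assert fv.names == BASE_FEATURE_NAMES
        assert np.all(np.isfinite(fv.values))

    def test_worked_example_values(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        assert fv["A1"] == pytest.approx(38.125)  # mean of the 8 levels
        assert fv["A2"] == pytest.approx((20 + 35 + 35 + 40) / 4)
        assert fv["A3"] == pytest.approx((45 + 50 + 70) / 3)
        assert fv["SS1"] == pytest.approx((35 - 70) / 4.5)
        assert fv["SS2"] == pytest.approx((35 - 45) / 2)
        assert fv["SS3"] == pytest.approx((20 - 40) / 1.5)
        assert fv["min"] == 10 and fv["max"] == 70 and fv["range"] == 60
        assert fv["median"] == pytest.approx(37.5)
        assert fv["std"] == pytest.approx(np.std(worked_audiogram.levels, ddof=1))
        # range equals 60 dB exactly: the steep rule requires strictly more
        assert fv["steep_flag"] == 0.0

    def test_steep_flag_strictly_exceeds_60(self, grid, refs):
        levels = np.array([10.0, 20, 35, 35, 40, 45, 50, 75])  # range 65
        fv = base_features(Audiogram(levels=levels, grid=grid), refs)
        assert fv["steep_flag"] == 1.0

    def test_reference_variance_definition(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        for key in ("N1", "S3"):
            expected = np.sum((worked_audiogram.levels - refs[key].levels) ** 2) / 7.0
            assert fv[f"var_{key}"] == pytest.approx(expected)

    def test_correlation_features_match_pearson(self, worked_audiogram, refs):
        from scipy.stats import pearsonr

        fv = base_features(worked_audiogram, refs)
        for key in ("N1", "N4", "S2"):
            assert fv[f"r_{key}"] == pytest.approx(
                pearsonr(worked_audiogram.levels, refs[key].levels).statistic, abs=1e-12
            )

    def test_constant_audiogram_error_names_feature(self, grid, refs):
        flat = Audiogram(levels=np.full(8, 40.0), id="flat", grid=grid)
        with pytest.raises(ValueError, match="r_N1"):
            base_features(flat, refs)

    def test_translation_shifts_levels_not_shape(self, refs):
        rng = np.random.default_rng(21)
        (a,) = random_audiograms(1, rng)
        b = a.replace(levels=a.levels + 12.5)
        fa, fb = base_features(a, refs), base_features(b, refs)
        for name in ("A1", "A2", "A3", "min", "max", "median"):
            assert fb[name] == pytest.approx(fa[name] + 12.5)
        for name in ("SS1", "SS2", "SS3", "range", "std", "steep_flag",
                     "r_N1", "r_N5", "r_S2"):
            assert fb[name] == pytest.approx(fa[name], abs=1e-9)

    def test_positive_scaling_scales_spread_features(self, refs):
        rng = np.random.default_rng(22)
        (a,) = random_audiograms(1, rng)
        lam = 1.7
        b = a.replace(levels=lam * a.levels)
        fa, fb = base_features(a, refs), base_features(b, refs)
        for name in ("SS1", "SS2", "SS3", "range", "std"):
            assert fb[name] == pytest.approx(lam * fa[name])
        for name in ("r_N2", "r_S1"):
            assert fb[name] == pytest.approx(fa[name], abs=1e-12)


class TestPolynomialFit:
    def test_exact_quintic_has_zero_residual(self):
        x = np.arange(1, 9, dtype=float)
        levels = 0.01 * x**5 - 0.2 * x**3 + 1.5 * x + 30.0
        _, residual = polynomial_residual(levels, degree=5)
        assert residual <= 1e-18

    def test_residuals_nest_with_degree(self):
        rng = np.random.default_rng(23)
        for a in random_audiograms(40, rng):
            r5 = polynomial_residual(a.levels, 5)[1]
            r4 = polynomial_residual(a.levels, 4)[1]
            r3 = polynomial_residual(a.levels, 3)[1]
            assert r5 <= r4 + 1e-9 and r4 <= r3 + 1e-9


class TestReduction:
    def test_staged_reduction_counts(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        s1 = reduce_features(fv, "drop_variances")
        assert len(s1) == 29
        s2 = reduce_features(s1, "drop_minor")
        assert len(s2) == 24
        s3 = reduce_features(s2, "drop_refs")
        assert len(s3) == 20
        assert reduce_all(fv).names == s3.names

    def test_stage_is_idempotent(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        once = reduce_features(fv, "drop_variances")
        twice = reduce_features(once, "drop_variances")
        assert once.names == twice.names
        np.testing.assert_array_equal(once.values, twice.values)

    def test_dropped_names_are_the_documented_ones(self, worked_audiogram, refs):
        fv = reduce_all(base_features(worked_audiogram, refs))
        gone = {"SS1", "p3", "p2", "p1", "p0", "r_N2", "r_N4", "r_N7", "r_S1"}
        assert not gone & set(fv.names)
        assert not any(n.startswith("var_") for n in fv.names)

    def test_unknown_stage_rejected(self, worked_audiogram, refs):
        fv = base_features(worked_audiogram, refs)
        with pytest.raises(ValueError, match="unknown reduction stage"):
            reduce_features(fv, "drop_everything")


def _toy_training(refs, rng, per_class=3, k=10):
    """Labelled reduced feature vectors: k classes x per_class noisy members."""
    from audioshape.synth import bisgaard_like_archetypes, make_dataset

    specs = bisgaard_like_archetypes(n_samples=per_class, include_normal=False)
    data = make_dataset(specs, seed=int(rng.integers(2**31)))
    return [reduce_all(base_features(a, refs)) for a in data]


class TestNestedFeatures:
    def test_model_stores_ten_interval_definitions(self, refs):
        rng = np.random.default_rng(31)
        model = fit_nested(_toy_training(refs, rng), k=10)
        assert model.classes == tuple(range(1, 11))
        for c, names in NESTED_FEATURE_SPEC.items():
            assert tuple(model.intervals[c]) == names

    def test_intervals_match_brute_force_min_max(self, refs):
        rng = np.random.default_rng(32)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        for c, names in NESTED_FEATURE_SPEC.items():
            members = [fv for fv in train if fv.label == c]
            for name in names:
                vals = [m[name] for m in members]
                assert model.intervals[c][name] == (min(vals), max(vals))

    def test_single_member_class_gives_degenerate_interval(self, refs):
        rng = np.random.default_rng(33)
        train = _toy_training(refs, rng, per_class=1)
        model = fit_nested(train, k=10)
        for c in model.classes:
            (member,) = [fv for fv in train if fv.label == c]
            for name, (lo, hi) in model.intervals[c].items():
                assert lo == hi == member[name]

    def test_empty_class_raises_naming_it(self, refs):
        rng = np.random.default_rng(34)
        train = [fv for fv in _toy_training(refs, rng) if fv.label != 4]
        with pytest.raises(ValueError, match="class 4"):
            fit_nested(train, k=10)

    def test_training_member_inside_own_interval(self, refs):
        rng = np.random.default_rng(35)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        for fv in train:
            bits = nested_features(fv, model)
            assert bits[f"nested_c{fv.label}"] == 1.0

    def test_far_outside_every_interval_gives_all_zero(self, refs, grid):
        rng = np.random.default_rng(36)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        far = train[0]
        far = FeatureVector(names=far.names, values=far.values + 1e6, id="far")
        bits = nested_features(far, model)
        assert all(bits[f"nested_c{c}"] == 0.0 for c in range(1, 11))

    def test_bits_match_brute_force_membership(self, refs):
        rng = np.random.default_rng(37)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        for fv in train[::5]:
            bits = nested_features(fv, model)
            for c in range(1, 11):
                expected = all(
                    model.intervals[c][n][0] <= fv[n] <= model.intervals[c][n][1]
                    for n in model.intervals[c]
                )
                assert bits[f"nested_c{c}"] == float(expected)


class TestResidualMapAndFinal:
    def test_identity_coefficients_pass_residual_through(self, refs):
        rng = np.random.default_rng(41)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        rmap = ResidualMap(coefficients=(0.0, 1.0, 0.0))
        out = final_arrangement(train[0], model, rmap)
        assert out["mapped_residual"] == pytest.approx(train[0]["residual"])

    def test_quadratic_evaluation(self):
        rmap = ResidualMap(coefficients=(2.0, -1.0, 0.5))
        assert rmap(3.0) == pytest.approx(2 * 9 - 3 + 0.5)

    def test_fitted_map_is_least_squares_quadratic(self, refs):
        rng = np.random.default_rng(42)
        train = _toy_training(refs, rng)
        rmap = fit_residual_map(train)
        residuals = np.array([fv["residual"] for fv in train])
        labels = np.array([float(fv.label) for fv in train])
        expected = np.polyfit(residuals, labels, deg=2)
        np.testing.assert_allclose(rmap.coefficients, expected, rtol=1e-9)

    def test_final_arrangement_has_31_features(self, refs):
        rng = np.random.default_rng(43)
        train = _toy_training(refs, rng)
        model = fit_nested(train, k=10)
        rmap = fit_residual_map(train)
        out = final_arrangement(train[0], model, rmap)
        assert len(out) == 31
        assert out.names[-1] == "mapped_residual"
        assert sum(n.startswith("nested_c") for n in out.names) == 10

    def test_unfitted_model_rejected(self, refs):
        rng = np.random.default_rng(44)
        train = _toy_training(refs, rng)
        with pytest.raises(ValueError, match="fitted"):
            final_arrangement(train[0], None, None)
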