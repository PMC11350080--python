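import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from stemftir.group_stats import (
    area_weighted_mean,
    compare_clusters,
    effect_size_d,
    mann_whitney,
    pearson,
    qad,
    r2_from_d,
    relative_difference_pct,
)


def _brute_force_mw(x, y):
    """Independent oracle: direct pair counting + full enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    u_obs = sum(
        1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
    )
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    mu = nx * len(y) / 2.0
    hits = total = 0
    for comb in itertools.combinations(range(n), nx):
        xs = pooled[list(comb)]
        ys = pooled[[i for i in range(n) if i not in comb]]
        u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


class TestMannWhitney:
    def test_fully_separated_samples(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_identical_samples_symmetric(self):
        U, p = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert U == pytest.approx(4.5)  # n^2/2 with ties counted half
        assert p == 1.0

    def test_exact_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(12)
        for nx, ny in [(3, 5), (4, 4), (6, 2), (7, 7)]:
            x, y = rng.normal(size=nx), rng.normal(size=ny)
            U, p = mann_whitney(x, y, mode="exact")
            res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert U == pytest.approx(float(res.statistic))
            assert p == pytest.approx(float(res.pvalue), abs=1e-12)

    def test_exact_equals_brute_force_with_ties(self):
        x, y = [1.0, 2.0, 2.0], [2.0, 3.0]
        U, p = mann_whitney(x, y, mode="exact")
        U_bf, p_bf = _brute_force_mw(x, y)
        assert U == pytest.approx(U_bf)
        assert p == pytest.approx(p_bf)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        _, p_exact = mann_whitney(x, y, mode="exact")
        _, p_normal = mann_whitney(x, y, mode="normal")
        assert abs(p_exact - p_normal) < 0.02

    def test_auto_switches_on_size_and_ties(self):
        rng = np.random.default_rng(4)
        small = rng.normal(size=8)
        assert mann_whitney(small, small + 10, "auto")[1] == (
            mann_whitney(small, small + 10, "exact")[1]
        )
        big = rng.normal(size=20)
        assert mann_whitney(big, big + 0.1, "auto")[1] == (
            mann_whitney(big, big + 0.1, "normal")[1]
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])


class TestEffectSize:
    def test_hand_computed_example(self):
        # means 4 and 5, pooled SD 2 -> D = 0.5
        assert effect_size_d([2, 4, 6], [3, 5, 7]) == pytest.approx(0.5)

    def test_identical_samples_give_zero(self):
        assert effect_size_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_linear_growth_in_shift(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        s = x.std(ddof=1)
        d1 = effect_size_d(x, x + 1.0 * s)
        d2 = effect_size_d(x, x + 2.0 * s)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_zero_pooled_sd_unequal_means_is_flagged_infinite(self):
        with pytest.warns(RuntimeWarning, match="inf"):
            assert np.isinf(effect_size_d([1.0, 1.0], [2.0, 2.0]))

    @pytest.mark.parametrize(
        "d, expected", [(2.0, 0.5), (0.0, 0.0), (0.8, 0.64 / 4.64)]
    )
    def test_r2_closed_form(self, d, expected):
        assert r2_from_d(d) == pytest.approx(expected, abs=1e-12)

    def test_r2_strictly_increasing_and_threshold_equivalence(self):
        ladder = np.linspace(0.0, 5.0, 40)
        values = [r2_from_d(d) for d in ladder]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert r2_from_d(2.0 + 1e-9) > 0.5 > r2_from_d(2.0 - 1e-9)


class TestDescriptives:
    @pytest.mark.parametrize(
        "x, expected", [([1, 2, 3], 1.0), ([5, 5, 5], 0.0), ([1, 1, 1, 9], 0.0)]
    )
    def test_qad(self, x, expected):
        assert qad(x) == expected

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        st.floats(-1e3, 1e3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_qad_nonnegative_and_translation_invariant(self, x, shift):
        assert qad(x) >= 0.0
        assert qad(np.asarray(x) + shift) == pytest.approx(qad(x), abs=1e-6)

    @pytest.mark.parametrize(
        "a, b, expected", [(177.0, 100.0, 77.0), (5.0, 5.0, 0.0), (50.0, 100.0, -50.0)]
    )
    def test_relative_difference(self, a, b, expected):
        assert relative_difference_pct(a, b) == pytest.approx(expected)

    def test_relative_difference_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_difference_pct(1.0, 0.0)

    def test_area_weighted_mean(self):
        assert area_weighted_mean([10.0, 20.0], [1.0, 3.0]) == pytest.approx(17.5)
        assert area_weighted_mean([4.0, 8.0], [2.0, 2.0]) == pytest.approx(6.0)
        assert area_weighted_mean([3.3], [7.0]) == pytest.approx(3.3)
        with pytest.raises(ValueError):
            area_weighted_mean([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            area_weighted_mean([1.0], [0.0])


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_value_matches_t_distribution(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, p = pearson(x, y)
        t = r * np.sqrt(8 / (1 - r * r))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df=8), rel=1e-9)


def _toy_comparison(shift=0.0, seed=0, n=60):
    """Two tiny single-cluster 'cubes' built directly from arrays."""
    from stemftir.clustering import ClusterResult
    from stemftir.emsc import CubeFit

    rng = np.random.default_rng(seed)
    rows = cols = int(np.sqrt(n))
    shape = (rows, cols)
    mask = np.ones(shape, dtype=bool)

    def make_fit(mu):
        rel = np.stack(
            [
                rng.normal(mu, 0.01, shape),
                rng.normal(0.5, 0.01, shape),
            ],
            axis=2,
        )
        return CubeFit(
            names=["target", "other"],
            relative_absorbance=rel,
            chemical_loadings=rel.copy(),
            scale=np.ones(shape),
            residual_rms=np.zeros(shape),
            mask=mask,
            n_degenerate=0,
        )

    labels = np.ones(shape, dtype=int)
    clusters = ClusterResult(labels, 1, None, np.zeros((1, 2)), np.array([rows * cols]), 11.0)
    return make_fit(0.3 + shift), make_fit(0.3), clusters


class TestCompareClusters:
    def test_identical_distributions_not_significant(self):
        fit_a, fit_b, clusters = _toy_comparison(shift=0.0)
        records = compare_clusters(fit_a, fit_b, clusters, clusters)
        assert all(r.verdict == "not_significant" for r in records)
        assert all(abs(r.rel_diff_pct) < 5.0 for r in records)

    def test_planted_shift_flagged_with_correct_sign(self):
        fit_a, fit_b, clusters = _toy_comparison(shift=0.15)
        records = compare_clusters(fit_a, fit_b, clusters, clusters)
        target = next(r for r in records if r.component == "target")
        other = next(r for r in records if r.component == "other")
        assert target.verdict == "significant"
        assert target.rel_diff_pct > 30.0
        assert other.verdict == "not_significant"

    def test_group_swap_flips_sign_and_preserves_p_and_d(self):
        fit_a, fit_b, clusters = _toy_comparison(shift=0.15)
        fwd = compare_clusters(fit_a, fit_b, clusters, clusters)
        rev = compare_clusters(fit_b, fit_a, clusters, clusters)
        for f, r in zip(fwd, rev):
            assert f.D == pytest.approx(r.D)
            assert f.p == pytest.approx(r.p)
            assert np.sign(f.rel_diff_pct) == -np.sign(r.rel_diff_pct) or (
                f.rel_diff_pct == r.rel_diff_pct == 0.0
            )

    def test_rank_statistics_invariant_under_monotone_rescaling(self):
        fit_a, fit_b, clusters = _toy_comparison(shift=0.1)
        base = compare_clusters(fit_a, fit_b, clusters, clusters)
        for fit in (fit_a, fit_b):
            fit.relative_absorbance = np.exp(3.0 * fit.relative_absorbance)
        rescaled = compare_clusters(fit_a, fit_b, clusters, clusters)
        for a, b in zip(base, rescaled):
            assert a.U == pytest.approx(b.U)
            assert a.p == pytest.approx(b.p)

    def test_r2_identity_holds_in_records(self):
        fit_a, fit_b, clusters = _toy_comparison(shift=0.05, seed=2)
        for r in compare_clusters(fit_a, fit_b, clusters, clusters):
            assert r.r2_d == pytest.approx(r.D**2 / (r.D**2 + 4.0), abs=1e-12)
            assert 0.0 <= r.r2_d < 1.0
            assert 0.0 <= r.U <= r.n_a * r.n_b
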