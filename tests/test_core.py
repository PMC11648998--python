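"""The four-stage learning pipeline: table, binning, moments, curve, integral."""

import numpy as np
import pytest

from hicvst import (BaseAuxTable, apply_transform, build_base_aux,
                    derive_transform, fit_mean_sd_curve, learn_transform,
                    moment_oracle, nb_closed_form, rescale_log_converge,
                    sort_and_bin)
from hicvst.core import (BinnedMoments, TransformFunction, asinh_grid,
                         estimate_moments, pool_base_aux)


class TestBuildBaseAux:
    def test_intra_flattens_upper_triangle_with_diagonal(self, intra_pair):
        m1, m2 = intra_pair
        tab = build_base_aux(m1, m2, "all_pairs")
        assert tab.bp == 3
        assert set(zip(tab.base, tab.aux)) == {(4, 3), (2, 1), (6, 7)}

    def test_inter_flattens_whole_matrix(self, inter_pair):
        m1, m2 = inter_pair
        assert build_base_aux(m1, m2, "all_pairs").bp == 6

    def test_union_nonzero_drops_double_zeros(self, intra_pair):
        m1, m2 = intra_pair
        # zero cell (0, 1) in both replicates
        z1 = m1.with_values(np.where((m1.bin1 == 0) & (m1.bin2 == 1), 0, m1.value))
        z2 = m2.with_values(np.where((m2.bin1 == 0) & (m2.bin2 == 1), 0, m2.value))
        assert build_base_aux(z1, z2, "union_nonzero").bp == 2

    def test_mismatched_dimensions_raise(self, intra_pair, inter_pair):
        with pytest.raises(ValueError):
            build_base_aux(intra_pair[0], inter_pair[0])


class TestSortAndBin:
    def test_bin_count_is_ceiling_of_bp_over_s(self):
        tab = BaseAuxTable(np.arange(5.0), np.arange(5.0))
        mom = sort_and_bin(tab, 2)
        assert mom.b == 3
        assert sorted(mom.counts.tolist()) == [1, 2, 2]

    def test_sorted_input_binning_is_stable(self):
        base = np.arange(10.0)
        aux = np.arange(10.0) * 2
        mom = sort_and_bin(BaseAuxTable(base, aux), 5)
        # already sorted: bins are the first and second halves of aux
        assert mom.mu[0] == pytest.approx(aux[:5].mean())
        assert mom.mu[1] == pytest.approx(aux[5:].mean())

    def test_membership_matches_independent_sort(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 5, 200).astype(float)  # heavy ties
        aux = rng.random(200)
        s = 7
        mom = sort_and_bin(BaseAuxTable(base, aux), s)
        # brute-force reference: stable sort of (base, original index) pairs
        order = sorted(range(200), key=lambda i: (base[i], i))
        ref = [aux[i] for i in order]
        bins = [ref[k:k + s] for k in range(0, 200, s)]
        ref_mu = sorted(float(np.mean(b)) for b in bins)
        assert np.allclose(sorted(mom.mu), ref_mu)

    @pytest.mark.parametrize("s", [0, 1, 300])
    def test_invalid_bin_size_raises(self, s):
        tab = BaseAuxTable(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            sort_and_bin(tab, s)


class TestEstimateMoments:
    def test_population_divisor_example(self):
        mom = sort_and_bin(BaseAuxTable(np.array([0.0, 1.0]),
                                        np.array([2.0, 4.0])), 2)
        assert mom.mu[0] == pytest.approx(3.0)
        assert mom.sigma[0] == pytest.approx(1.0)  # ((2-3)^2+(4-3)^2)/2 = 1

    def test_constant_bin_has_zero_sigma(self):
        mom = sort_and_bin(BaseAuxTable(np.arange(3.0),
                                        np.array([5.0, 5.0, 5.0])), 3)
        assert mom.sigma[0] == 0.0

    def test_matches_two_pass_oracle_on_random_bins(self):
        rng = np.random.default_rng(5)
        n_bins, s = 1000, 8
        aux = rng.gamma(2.0, 3.0, n_bins * s)
        mom = estimate_moments(BinnedMoments(
            s, np.empty(0), np.empty(0),
            np.full(n_bins, s), sorted_aux=aux))
        # independent two-pass computation per bin
        ref_mu = np.empty(n_bins)
        ref_sd = np.empty(n_bins)
        for b in range(n_bins):
            chunk = aux[b * s:(b + 1) * s]
            m = sum(chunk) / s
            ref_mu[b] = m
            ref_sd[b] = (sum((x - m) ** 2 for x in chunk) / s) ** 0.5
        order = np.argsort(ref_mu, kind="stable")
        assert np.allclose(mom.mu, ref_mu[order], rtol=1e-10)
        assert np.allclose(mom.sigma, ref_sd[order], rtol=1e-10, atol=1e-12)


def _moments(mu, sigma, count=100):
    mu = np.asarray(mu, dtype=float)
    return BinnedMoments(count, mu, np.asarray(sigma, dtype=float),
                         np.full(len(mu), count))


class TestFitMeanSdCurve:
    def test_constant_points_give_constant_curve(self):
        mu = np.linspace(1, 50, 30)
        curve = fit_mean_sd_curve(_moments(mu, np.full(30, 2.5)))
        assert np.allclose(curve(np.linspace(2, 49, 17)), 2.5, rtol=1e-6)

    def test_recovers_sqrt_law_within_ten_percent(self):
        rng = np.random.default_rng(2)
        mu = np.linspace(0.5, 100, 80)
        sigma = np.sqrt(mu) * (1 + rng.normal(0, 0.03, 80))
        curve = fit_mean_sd_curve(_moments(mu, sigma))
        interior = np.linspace(2, 95, 50)
        rel = np.abs(curve(interior) - np.sqrt(interior)) / np.sqrt(interior)
        assert rel.max() < 0.10

    def test_floor_clip_keeps_curve_positive(self):
        mu = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sigma = np.array([0.0, 0.0, 0.0, 1.0, 2.0])
        curve = fit_mean_sd_curve(_moments(mu, sigma), floor_eps=0.05)
        assert np.all(curve(np.linspace(1, 5, 30)) >= 0.05)

    def test_too_few_support_points_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_mean_sd_curve(_moments([1.0, 1.0, 2.0, 3.0],
                                       [1.0, 1.0, 1.0, 1.0]))

    def test_constant_extension_outside_support(self):
        mu = np.linspace(1, 10, 20)
        curve = fit_mean_sd_curve(_moments(mu, np.sqrt(mu)))
        assert curve(0.0) == pytest.approx(float(curve(1.0)))
        assert curve(1e6) == pytest.approx(float(curve(10.0)))


class TestDeriveTransform:
    def test_unit_curve_gives_identity(self):
        t = derive_transform(lambda x: np.ones_like(np.asarray(x, float)), 100.0)
        assert np.allclose(t.values, t.grid, atol=1e-9)

    def test_sqrt_curve_gives_anscombe_root(self):
        t = derive_transform(lambda x: np.sqrt(np.maximum(x, 1e-12)), 300.0)
        rel = np.abs(t.values[1:] - 2 * np.sqrt(t.grid[1:])) / (2 * np.sqrt(t.grid[1:]))
        assert rel.max() < 1e-6

    @pytest.mark.parametrize("alpha", [0.1, 0.25, 1.0])
    def test_nb_curve_matches_closed_form(self, alpha):
        h = lambda x: np.sqrt(np.maximum(x + alpha * x ** 2, 1e-12))
        t = derive_transform(h, 300.0)
        ref = nb_closed_form(alpha)
        sel = t.grid > 0
        rel = np.abs(t.values[sel] - ref(t.grid[sel])) / ref(t.grid[sel])
        assert rel.max() < 0.01

    def test_result_is_strictly_increasing(self):
        oracle = moment_oracle(0.3)
        t = derive_transform(lambda mu: np.maximum(oracle(mu), 1e-8), 50.0)
        assert np.all(np.diff(t.values) > 0)
        assert t.values[0] == 0.0

    @pytest.mark.parametrize("kwargs", [{"x_max": -1.0}, {"x_max": 10.0, "n_grid": 10}])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            derive_transform(lambda x: np.ones_like(np.asarray(x, float)), **kwargs)


class TestApplyTransform:
    def test_identity_transform_is_identity(self, nb_pair):
        m1, _, _ = nb_pair
        t = derive_transform(lambda x: np.ones_like(np.asarray(x, float)),
                             float(m1.value.max()))
        out = apply_transform(t, m1)
        assert np.allclose(out.value, m1.value, atol=1e-9)

    def test_rank_order_preserved_exactly(self, nb_pair):
        from scipy.stats import rankdata
        m1, m2, _ = nb_pair
        t = learn_transform(m1, m2)
        out = apply_transform(t, m1)
        assert np.array_equal(rankdata(out.value), rankdata(m1.value))

    def test_knot_evaluation_returns_tabulated_values(self):
        oracle = moment_oracle(0.5)
        t = derive_transform(lambda mu: np.maximum(oracle(mu), 1e-8), 20.0)
        assert np.allclose(t(t.grid), t.values, atol=1e-12)

    def test_extrapolation_uses_final_slope(self):
        t = derive_transform(lambda x: np.ones_like(np.asarray(x, float)), 10.0)
        assert t(np.array([25.0]))[0] == pytest.approx(25.0, rel=1e-9)

    def test_negative_input_rejected(self):
        t = derive_transform(lambda x: np.ones_like(np.asarray(x, float)), 10.0)
        with pytest.raises(ValueError, match="non-negative"):
            t(np.array([-1.0]))


class TestRescaleLogConverge:
    def _log_tail_transform(self):
        grid = asinh_grid(100.0, 500)
        values = np.log1p(grid) * 2 + 3  # strictly increasing, 2*ln-like tail
        return TransformFunction(grid, values)

    def test_log_tail_is_fixed_point(self):
        grid = asinh_grid(100.0, 500)
        t = TransformFunction(grid, np.log(grid + 1e-3))
        out = rescale_log_converge(t, tail_quantile=0.5)
        assert out.params["log_converge_a"] == pytest.approx(1.0, abs=0.02)
        assert out.params["log_converge_b"] == pytest.approx(0.0, abs=0.05)

    def test_affine_inversion(self):
        grid = asinh_grid(100.0, 500)
        tail = grid >= np.quantile(grid, 0.5)
        vals = np.where(grid > 0, 2 * np.log(np.maximum(grid, 1e-9)) + 3, -40.0)
        vals = np.maximum.accumulate(vals + np.arange(len(grid)) * 1e-9)
        t = TransformFunction(grid, vals)
        out = rescale_log_converge(t, tail_quantile=0.5)
        assert out.params["log_converge_a"] == pytest.approx(0.5, abs=1e-6)
        assert out.params["log_converge_b"] == pytest.approx(-1.5, abs=1e-4)
        assert np.all(np.diff(out.values) > 0)

    def test_least_squares_beats_unrescaled(self, nb_pair):
        m1, m2, _ = nb_pair
        t = learn_transform(m1, m2)
        out = rescale_log_converge(t, tail_quantile=0.5)
        sel = (t.grid >= np.quantile(t.grid, 0.5)) & (t.grid > 0)
        target = np.log(t.grid[sel])
        rss_rescaled = np.sum((out.values[sel] - target) ** 2)
        rss_raw = np.sum((t.values[sel] - target) ** 2)
        assert rss_rescaled <= rss_raw + 1e-9

    def test_degenerate_tail_raises(self):
        t = derive_transform(lambda x: np.ones_like(np.asarray(x, float)), 10.0)
        with pytest.raises(ValueError):
            rescale_log_converge(t, tail_quantile=1.5)


class TestLearnTransform:
    def test_equals_manual_stage_chaining(self, nb_pair):
        from hicvst.core import effective_bin_rows
        m1, m2, _ = nb_pair
        t = learn_transform(m1, m2)
        tab = pool_base_aux(m1, m2, "union_nonzero")
        mom = sort_and_bin(tab, effective_bin_rows(tab.bp))
        curve = fit_mean_sd_curve(mom)
        x_max = float(max(tab.base.max(), tab.aux.max()))
        ref = derive_transform(curve, x_max)
        assert np.allclose(t.values, ref.values)

    def test_pooling_duplicate_table_keeps_bin_means(self):
        rng = np.random.default_rng(0)
        base = rng.random(600) * 20  # continuous: no ties, so the doubled
        aux = rng.poisson(10, 600).astype(float)  # table sorts to adjacent twins
        one = BaseAuxTable(base, aux)
        two = BaseAuxTable(np.tile(base, 2), np.tile(aux, 2))
        m_one = sort_and_bin(one, 50)
        m_two = sort_and_bin(two, 100)
        assert np.allclose(np.sort(m_one.mu), np.sort(m_two.mu))
        assert np.allclose(np.sort(m_one.sigma), np.sort(m_two.sigma))
        assert np.array_equal(m_two.counts, m_one.counts * 2)

    def test_transform_fixes_zero_and_nonnegative(self, nb_pair):
        m1, m2, _ = nb_pair
        t = learn_transform(m1, m2)
        assert t.values[0] == 0.0
        assert np.all(t.values >= 0)
        assert np.all(np.diff(t.values) > 0)

    def test_tsv_round_trip(self, tmp_path, nb_pair):
        m1, m2, _ = nb_pair
        t = learn_transform(m1, m2)
        p = tmp_path / "t.tsv"
        t.to_tsv(p)
        back = TransformFunction.from_tsv(p)
        assert np.allclose(back.grid, t.grid)
        assert np.allclose(back.values, t.values)
        assert back.c == t.c
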