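import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from monodom.boundary import (SEMICIRCLE_OBLIQUITY, assign_quadrants,
                              bootstrap_rate, fit_all_quadrants,
                              fit_movement_model, match_vertices,
                              movement_permutation_test,
                              pairing_permutation_test, radial_displacement,
                              radial_movement_test, radial_rate_from_group_mean)

YEARS = (1995.0, 2007.0)


def circle_vertices(n, R=50.0, center=(0.0, 0.0), jitter=0.0, rng=None):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.c_[center[0] + R * np.cos(theta), center[1] + R * np.sin(theta)]
    if jitter:
        v = v + rng.normal(0, jitter, v.shape)
    return v


def pairs_frame(v3, v1):
    return pd.DataFrame({"x3": v3[:, 0], "y3": v3[:, 1],
                         "x1": v1[:, 0], "y1": v1[:, 1]})


class TestMatchVertices:
    def test_identical_lists_self_pair(self):
        v = circle_vertices(24)
        m = match_vertices(v, v, max_reuse=2)
        assert np.allclose(m["dist"], 0.0)
        np.testing.assert_allclose(m[["x1", "y1"]].to_numpy(), v)

    def test_rigid_translation_recovered(self):
        v1 = circle_vertices(30)
        v3 = v1 + [5.0, 0.0]
        m = match_vertices(v3, v1, max_reuse=2)
        assert np.allclose(m["dist"], 5.0)
        # matches the unconstrained nearest map (brute force)
        brute = v1[np.argmin(np.linalg.norm(v3[:, None] - v1[None], axis=2), axis=1)]
        np.testing.assert_allclose(m[["x1", "y1"]].to_numpy(), brute)

    def test_descending_distance_schedule(self):
        # 3 late vertices, 2 early, reuse cap 2: the farthest late vertex is
        # processed first and claims the shared early vertex
        v1 = np.array([[0.0, 0.0], [10.0, 0.0]])
        v3 = np.array([[0.0, 1.0], [0.0, 6.0], [10.0, 1.0]])
        m = match_vertices(v3, v1, max_reuse=2)
        # hand-simulated schedule: order by distance desc = [v3_1 (6), v3_0/2 (1)]
        # v3_1 -> v1_0 (dist 6), v3_0 -> v1_0 (second use), v3_2 -> v1_1
        assert m.loc[1, ["x1", "y1"]].tolist() == [0.0, 0.0]
        assert m.loc[0, ["x1", "y1"]].tolist() == [0.0, 0.0]
        assert m.loc[2, ["x1", "y1"]].tolist() == [10.0, 0.0]

    def test_reuse_cap_respected_and_infeasible(self):
        rng = np.random.default_rng(0)
        v1 = rng.uniform(0, 100, (10, 2))
        v3 = rng.uniform(0, 100, (28, 2))
        m = match_vertices(v3, v1, max_reuse=3)
        assert m.groupby("i1").size().max() <= 3
        with pytest.raises(ValueError, match="infeasible"):
            match_vertices(v3, v1, max_reuse=2)

    def test_capped_total_distance_dominates_unconstrained(self):
        rng = np.random.default_rng(1)
        v1 = rng.uniform(0, 50, (8, 2))
        v3 = rng.uniform(0, 50, (15, 2))
        capped = match_vertices(v3, v1, max_reuse=2)["dist"].sum()
        free = np.linalg.norm(
            v3 - v1[np.argmin(np.linalg.norm(v3[:, None] - v1[None], axis=2), axis=1)],
            axis=1).sum()
        assert capped >= free - 1e-12

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        v1 = rng.uniform(0, 50, (20, 2))
        v3 = rng.uniform(0, 50, (30, 2))
        a = match_vertices(v3, v1, 2)
        b = match_vertices(v3, rng.permutation(v1), 2)
        assert a["dist"].sum() == pytest.approx(b["dist"].sum())


class TestQuadrants:
    @pytest.mark.parametrize("offset,ew,ns", [
        ((10, 10), "E", "N"),
        ((-1, -400), "W", "S"),
        ((0, 5), "E", "N"),      # meridian tie resolves east
        ((5, 0), "E", "N"),      # parallel tie resolves north
    ])
    def test_labels(self, offset, ew, ns):
        c = (100.0, 250.0)
        v3 = np.array([[c[0] + offset[0], c[1] + offset[1]]])
        m = assign_quadrants(pairs_frame(v3, v3), c)
        assert m.loc[0, "ew"] == ew and m.loc[0, "ns"] == ns


class TestMovementModel:
    def test_no_movement_slope_zero(self):
        v = circle_vertices(20)
        model = fit_movement_model(pairs_frame(v, v), "northing", YEARS)
        assert model.beta1 == 0.0
        assert model.delta == 1.0

    def test_rigid_shift_saturated_fit(self):
        v1 = circle_vertices(16) + [0.0, 100.0]
        v3 = v1 + [6.0, 0.0]
        model = fit_movement_model(pairs_frame(v3, v1), "easting", YEARS)
        assert model.beta1 == pytest.approx(6.0 / 12.0, abs=1e-12)
        # both strata are translations of the same ring: sd ratio is one
        assert model.delta == pytest.approx(1.0)

    def test_closed_form_equals_group_mean_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v1 = rng.normal(0, 5, (12, 2)) + [50, 50]
            v3 = rng.normal(0, 9, (12, 2)) + [53, 48]
            m = fit_movement_model(pairs_frame(v3, v1), "northing", YEARS)
            expected = (v3[:, 1].mean() - v1[:, 1].mean()) / 12.0
            assert m.beta1 == pytest.approx(expected, rel=1e-12)
            assert m.delta == pytest.approx(v3[:, 1].std() / v1[:, 1].std())

    def test_matches_statsmodels_weighted_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        v1 = rng.normal(0, 4, (15, 2))
        v3 = rng.normal(0, 7, (15, 2)) + [2, 5]
        model = fit_movement_model(pairs_frame(v3, v1), "northing", YEARS)
        y = np.concatenate([v1[:, 1], v3[:, 1]])
        year = np.concatenate([np.full(15, YEARS[0]), np.full(15, YEARS[1])])
        # any per-stratum weights give the group-mean solution here
        w = np.concatenate([np.full(15, 1.0), np.full(15, 1 / model.delta ** 2)])
        fit = sm.WLS(y, sm.add_constant(year), weights=w).fit()
        assert model.beta1 == pytest.approx(fit.params[1], rel=1e-9)
        assert model.beta0 == pytest.approx(fit.params[0], rel=1e-9)

    def test_single_year_rejected(self):
        v = circle_vertices(10)
        with pytest.raises(ValueError):
            fit_movement_model(pairs_frame(v, v), "northing", (2007.0, 2007.0))

    def test_quadrant_responses(self):
        rng = np.random.default_rng(5)
        v1 = circle_vertices(40, jitter=1.0, rng=rng)
        v3 = circle_vertices(40, R=53.0, jitter=1.0, rng=rng)
        m = assign_quadrants(match_vertices(v3, v1, 2), (0.0, 0.0))
        models = fit_all_quadrants(m, YEARS)
        assert models["N"].response == "northing"
        assert models["E"].response == "easting"
        assert models["N"].beta1 > 0 > models["S"].beta1


class TestBootstrap:
    def test_identical_displacements_zero_width(self):
        v1 = circle_vertices(10)
        v3 = v1 + [0.0, 3.0]
        mean, lo, hi = bootstrap_rate(pairs_frame(v3, v1), "northing", YEARS,
                                      n_boot=200, seed=0)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.25, abs=1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        v1 = rng.normal(0, 3, (20, 2))
        v3 = v1 + rng.normal(2, 1, (20, 2))
        a = bootstrap_rate(pairs_frame(v3, v1), "easting", YEARS, 500, seed=9)
        b = bootstrap_rate(pairs_frame(v3, v1), "easting", YEARS, 500, seed=9)
        assert a == b

    def test_bca_reduces_to_percentile_when_symmetric(self):
        # with zero bias and acceleration the BCa endpoints equal the
        # percentile endpoints; verify numerically on a symmetric problem
        rng = np.random.default_rng(7)
        d = rng.normal(3.0, 1.0, 41)
        v1 = np.c_[np.zeros(41), np.zeros(41)]
        v3 = np.c_[np.zeros(41), d]
        pairs = pairs_frame(v3, v1)
        mean, lo, hi = bootstrap_rate(pairs, "northing", YEARS, 4000, seed=1)
        # symmetric-case percentile interval from an independent resampler
        rng2 = np.random.default_rng(2)
        reps = np.array([d[rng2.integers(0, 41, 41)].mean() / 12 for _ in range(4000)])
        plo, phi = np.quantile(reps, [0.025, 0.975])
        assert lo == pytest.approx(plo, abs=0.01)
        assert hi == pytest.approx(phi, abs=0.01)

    def test_too_few_pairs_rejected(self):
        v = circle_vertices(2)
        with pytest.raises(ValueError):
            bootstrap_rate(pairs_frame(v, v), "northing", YEARS, 100, seed=0)


class TestPairingPermutation:
    def test_structured_boundary_is_nonrandom(self):
        rng = np.random.default_rng(8)
        v1 = circle_vertices(60, jitter=0.5, rng=rng)
        v3 = circle_vertices(70, R=54.0, jitter=0.5, rng=rng)
        res = pairing_permutation_test(v3, v1, (0.0, 0.0), YEARS, 2, 200, seed=0)
        # nearest pairing is far from random reassignment in every quadrant
        assert set(res) == set("NESW")
        for q in res:
            assert res[q].p == pytest.approx(1 / 201)

    def test_add_one_rule_floor(self):
        rng = np.random.default_rng(9)
        v1 = circle_vertices(40, jitter=0.5, rng=rng)
        v3 = circle_vertices(40, R=51.0, jitter=0.5, rng=rng)
        res = pairing_permutation_test(v3, v1, (0.0, 0.0), YEARS, 2, 99, seed=1)
        for q in res:
            assert res[q].p >= 1 / 100
            assert 0 < res[q].p <= 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        v1 = circle_vertices(30, jitter=1.0, rng=rng)
        v3 = circle_vertices(30, R=52.0, jitter=1.0, rng=rng)
        a = pairing_permutation_test(v3, v1, (0, 0), YEARS, 2, 100, seed=5)
        b = pairing_permutation_test(v3, v1, (0, 0), YEARS, 2, 100, seed=5)
        for q in a:
            assert a[q].p == b[q].p
            np.testing.assert_array_equal(a[q].null, b[q].null)


class TestMovementPermutation:
    def test_median_statistic_one_sided_half(self):
        rng = np.random.default_rng(11)
        x = np.zeros(41)
        d = rng.normal(0, 2, 41)
        pairs = pairs_frame(np.c_[x, d], np.c_[x, np.zeros(41)])
        res = movement_permutation_test(pairs, "northing", YEARS, 2000, seed=0,
                                        alternative="greater")
        # observed mean sits near the null's centre
        assert 0.2 < res.p <= 0.9

    def test_extreme_observation_hits_floor(self):
        x = np.zeros(12)
        pairs = pairs_frame(np.c_[x, np.full(12, 8.0)], np.c_[x, np.zeros(12)])
        res = movement_permutation_test(pairs, "northing", YEARS, 500, seed=0)
        # all displacements positive: only the all-plus flip ties the observed
        assert res.p <= (1 + 500 / 2 ** 11) / 501 + 0.01

    def test_calibrated_on_independent_pairs(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(120):
            x = rng.uniform(0, 100, 25)
            d = rng.normal(0, 2, 25)
            pairs = pairs_frame(np.c_[x, d], np.c_[x, np.zeros(25)])
            ps.append(movement_permutation_test(pairs, "northing", YEARS,
                                                199, rng).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_block_flips_reduce_to_blocks(self):
        rng = np.random.default_rng(13)
        x = np.linspace(0, 100, 30)
        d = rng.normal(1, 0.5, 30)
        pairs = pairs_frame(np.c_[x, d], np.c_[x, np.zeros(30)])
        res = movement_permutation_test(pairs, "northing", YEARS, 400, seed=0,
                                        n_blocks=5)
        assert len(np.unique(np.round(res.null, 12))) <= 2 ** 5


class TestRadial:
    def test_radial_projection_of_uniform_expansion(self):
        v1 = circle_vertices(36, R=50.0, center=(10.0, 20.0))
        v3 = circle_vertices(36, R=56.0, center=(10.0, 20.0))
        m = match_vertices(v3, v1, 2)
        d = radial_displacement(m, (10.0, 20.0))
        np.testing.assert_allclose(d, 6.0, atol=0.05)
        res = radial_movement_test(m, (10.0, 20.0), YEARS, 300, seed=0)
        assert res.observed == pytest.approx(0.5, abs=0.01)

    def test_obliquity_factor(self):
        # exact semicircle mean of sin: 2/pi
        theta = np.linspace(1e-6, np.pi - 1e-6, 20000)
        assert np.sin(theta).mean() == pytest.approx(2 / np.pi, abs=1e-4)
        assert radial_rate_from_group_mean(2 / np.pi) == pytest.approx(1.0, abs=1e-4)
        assert SEMICIRCLE_OBLIQUITY == pytest.approx(np.pi / 2)
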