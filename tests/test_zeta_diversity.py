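import math

import numpy as np
import pandas as pd
import pytest

from forelandeco import synthetic_data as sd
from forelandeco import zeta_diversity as zd


class TestZetaOrder:
    def test_worked_three_site_example(self, worked_incidence):
        inc = worked_incidence
        assert zd.zeta_order(inc, 1).mean == pytest.approx(3.0)
        assert zd.zeta_order(inc, 2).mean == pytest.approx(5 / 3)
        assert zd.zeta_order(inc, 2, normalization="jaccard").mean == \
            pytest.approx(0.4)
        assert zd.zeta_order(inc, 3).mean == pytest.approx(1.0)
        assert zd.zeta_order(inc, 3, normalization="jaccard").mean == \
            pytest.approx(0.2)

    def test_identical_sites_jaccard_one(self):
        pres = pd.DataFrame(True, index=list("abcd"), columns=["x", "y", "z"])
        inc = zd.IncidenceMatrix(pres)
        for i in (1, 2, 3):
            assert zd.zeta_order(inc, i, normalization="jaccard").mean == 1.0

    def test_disjoint_sites_zeta2_zero(self):
        pres = pd.DataFrame(np.eye(3, dtype=bool), index=list("abc"),
                            columns=["x", "y", "z"])
        inc = zd.IncidenceMatrix(pres)
        assert zd.zeta_order(inc, 2).mean == 0.0

    def test_order_bounds(self, worked_incidence):
        with pytest.raises(ValueError):
            zd.zeta_order(worked_incidence, 0)
        with pytest.raises(ValueError):
            zd.zeta_order(worked_incidence, 4)

    def test_zeta1_equals_mean_richness(self):
        inc = sd.random_incidence(40, 8, p=0.4, seed=11)
        expected = inc.presence.sum(axis=0).mean()
        assert zd.zeta_order(inc, 1).mean == pytest.approx(expected)

    @pytest.mark.parametrize("i", [2, 3, 4])
    def test_monte_carlo_matches_exhaustive(self, i):
        inc = sd.niche_gradient_incidence(50, 10, seed=3)
        ex = zd.zeta_order(inc, i, mode="exhaustive",
                           normalization="jaccard")
        mc = zd.zeta_order(inc, i, mode="monte_carlo", n_subsamples=1000,
                           normalization="jaccard", seed=7)
        se = mc.sd / math.sqrt(mc.n_evaluated)
        assert abs(mc.mean - ex.mean) <= 3 * se

    def test_raw_zeta_non_increasing(self):
        inc = sd.random_incidence(60, 9, p=0.5, seed=2)
        means = [zd.zeta_order(inc, i).mean for i in range(1, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))

    def test_taxon_and_site_relabel_invariance(self):
        inc = sd.niche_gradient_incidence(30, 8, seed=9)
        shuffled = inc.presence.sample(frac=1, random_state=0)
        inc2 = zd.IncidenceMatrix(shuffled)
        for i in (1, 2, 3):
            assert zd.zeta_order(inc2, i).mean == \
                pytest.approx(zd.zeta_order(inc, i).mean)


class TestZetaDecline:
    def test_exact_power_law_selected(self):
        # a decline that IS a power law must select power with slope -1
        i = np.arange(1, 7, dtype=float)
        z = 10.0 * i ** -1.0
        fits = {}
        for model, x in (("exponential", i), ("power", np.log(i))):
            slope, intercept, resid = zd._ols(x, np.log(z))
            fits[model] = (slope, zd._gaussian_aic(resid))
        assert fits["power"][1] < fits["exponential"][1]
        assert fits["power"][0] == pytest.approx(-1.0)

    def test_exact_exponential_selected(self):
        i = np.arange(1, 7, dtype=float)
        z = 10.0 * np.exp(-0.5 * i)
        fits = {}
        for model, x in (("exponential", i), ("power", np.log(i))):
            slope, intercept, resid = zd._ols(x, np.log(z))
            fits[model] = (slope, zd._gaussian_aic(resid))
        assert fits["exponential"][1] < fits["power"][1]
        assert fits["exponential"][0] == pytest.approx(-0.5)

    def test_assembly_model_contrast(self):
        # niche-gradient incidence -> power law; random placement ->
        # exponential (majority over seeds)
        niche = sum(
            zd.zeta_decline(sd.niche_gradient_incidence(seed=s),
                            i_max=6).selected_model == "power"
            for s in range(30))
        rand = sum(
            zd.zeta_decline(sd.random_incidence(seed=s),
                            i_max=6).selected_model == "exponential"
            for s in range(30))
        assert niche > 15
        assert rand > 15

    def test_orders_table_shape(self):
        inc = sd.random_incidence(40, 8, p=0.5, seed=1)
        decline = zd.zeta_decline(inc, i_max=5)
        assert decline.orders["order"].tolist() == [1, 2, 3, 4, 5]
        assert decline.orders["zeta_jaccard"].between(0, 1).all()
        assert decline.selected_model in decline.fits


class TestDistanceDecay:
    def test_identical_composition_flat(self):
        pres = pd.DataFrame(True, index=list("abcde"),
                            columns=[f"s{i}" for i in range(6)])
        coords = pd.DataFrame({"lat": np.zeros(6),
                               "lon": np.arange(6) * 0.01},
                              index=pres.columns)
        decay = zd.zeta_distance_decay(zd.IncidenceMatrix(pres, coords), 2)
        assert decay.slope_per_km == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(decay.r2)

    def test_colocated_sites_error(self):
        pres = pd.DataFrame(np.eye(4, dtype=bool), columns=list("wxyz"))
        coords = pd.DataFrame({"lat": [1.0] * 4, "lon": [2.0] * 4},
                              index=list("wxyz"))
        with pytest.raises(ValueError, match="co-located"):
            zd.zeta_distance_decay(zd.IncidenceMatrix(pres, coords), 2)

    def test_monte_carlo_recovers_exhaustive_slope(self):
        # oracle equivalence: subsampled slope within 5% of the
        # all-combinations slope
        inc4 = sd.niche_gradient_incidence(80, 12, seed=5)
        ex4 = zd.zeta_distance_decay(inc4, 4, n_subsamples=10_000, seed=1)
        assert ex4.records.shape[0] == math.comb(12, 4)
        mc4 = zd.zeta_distance_decay(inc4, 4, n_subsamples=400, seed=3)
        assert mc4.slope_per_km == pytest.approx(ex4.slope_per_km, rel=0.05)

    def test_pairwise_decay_steeper_than_four_way(self):
        # narrow contiguous ranges: higher-order zeta is near zero
        # everywhere, so its decay coefficient is flatter
        steeper = 0
        for s in range(10):
            inc = sd.niche_gradient_incidence(60, 15, max_width=8, seed=s)
            b2 = zd.zeta_distance_decay(inc, 2, 1000, seed=s).slope_per_km
            b4 = zd.zeta_distance_decay(inc, 4, 1000, seed=s).slope_per_km
            steeper += abs(b2) > abs(b4)
        assert steeper >= 8


class TestVarpart:
    def _incidence_with_env(self, seed=0, noise_group2=True):
        inc = sd.niche_gradient_incidence(60, 12, seed=seed)
        rng = np.random.default_rng(seed + 100)
        env = pd.DataFrame({
            "position": np.arange(12, dtype=float),
            "noise1": rng.normal(size=12),
            "noise2": rng.normal(size=12),
        }, index=inc.presence.columns)
        return zd.IncidenceMatrix(inc.presence, inc.coords, env)

    def test_fractions_sum_to_one(self):
        inc = self._incidence_with_env()
        res = zd.zeta_varpart(inc, ["position"], ["noise1", "noise2"])
        assert sum(res.raw_fractions.values()) == pytest.approx(1.0,
                                                                abs=1e-9)
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_structured_group_captures_variance(self):
        # group 2 is pure noise: its pure fraction is ~0 and the pure
        # group-1 fraction carries ~all explained variance
        inc = self._incidence_with_env(seed=1)
        res = zd.zeta_varpart(inc, ["position"], ["noise1", "noise2"])
        assert res.raw_fractions["a"] > 0.2
        assert abs(res.raw_fractions["c"]) < 0.1
        assert res.raw_fractions["a"] == pytest.approx(res.adj_r2_full,
                                                       abs=0.1)

    def test_shared_copies_land_in_b(self):
        inc = self._incidence_with_env(seed=2)
        env = inc.env.copy()
        env["position_copy"] = env["position"]
        inc2 = zd.IncidenceMatrix(inc.presence, inc.coords, env)
        res = zd.zeta_varpart(inc2, ["position"], ["position_copy"])
        assert res.raw_fractions["b"] == pytest.approx(res.adj_r2_full,
                                                       abs=1e-9)
        assert res.raw_fractions["a"] == pytest.approx(0.0, abs=1e-9)
        assert res.raw_fractions["c"] == pytest.approx(0.0, abs=1e-9)

    def test_no_structure_unexplained(self):
        pres = sd.random_incidence(60, 12, p=0.4, seed=3).presence
        rng = np.random.default_rng(7)
        env = pd.DataFrame({"u": rng.normal(size=12),
                            "v": rng.normal(size=12)},
                           index=pres.columns)
        inc = zd.IncidenceMatrix(pres, env=env)
        res = zd.zeta_varpart(inc, ["u"], ["v"])
        assert res.fractions["d"] > 0.8

    def test_internally_collinear_group_rejected(self):
        inc = self._incidence_with_env(seed=4)
        env = inc.env.copy()
        env["pos2"] = env["position"]
        inc2 = zd.IncidenceMatrix(inc.presence, inc.coords, env)
        with pytest.raises(ValueError, match="collinearity_filter"):
            zd.zeta_varpart(inc2, ["position", "pos2"], ["noise1"])
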