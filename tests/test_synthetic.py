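"""Generators: determinism, ground-truth responses, thinning, movement modes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forageq.rasters import GridSpec, RasterStack
from forageq.synthetic import (EnvScenario, TruthParams, generate_bird_metadata,
                               generate_env, sample_prey_presences,
                               simulate_tracks, true_suitability)

from conftest import constant_stacks


class TestGenerateEnv:
    def test_seeded_determinism(self, small_scenario, truth):
        a = generate_env(small_scenario, truth, seed=5)
        b = generate_env(small_scenario, truth, seed=5)
        for v in a:
            for day in a[v].days:
                np.testing.assert_array_equal(a[v].layers[day], b[v].layers[day])

    def test_bathymetry_static_over_dates(self, small_stacks):
        b = small_stacks["bathy"]
        first = b.layers[b.days[0]]
        for day in b.days[1:]:
            np.testing.assert_array_equal(b.layers[day], first)

    def test_all_values_finite(self, small_stacks):
        for st in small_stacks.values():
            for lay in st.layers.values():
                assert np.isfinite(lay).all()

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GridSpec(0, 0, 1000.0, 1, 40)

    def test_chla_improvement_nondecreasing_high_quality_fraction(self, truth):
        """With positive improvement rate, the fraction of cells at or above
        the chlorophyll plateau trends upward; checked against a direct
        per-day recount of cells above threshold."""
        sc = EnvScenario(grid=GridSpec(0, 0, 1000.0, 40, 40), years=(2015,),
                         days=tuple(range(120, 181, 4)),
                         colony_xy=(20_000.0, 33_000.0))
        stacks = generate_env(sc, truth, seed=3)
        chla = stacks["chla"]
        fracs = []
        for day in chla.days:
            lay = chla.layers[day]
            count = sum(1 for v in lay.ravel() if v >= truth.chla_plateau)
            fracs.append(count / lay.size)
        slope = np.polyfit(range(len(fracs)), fracs, 1)[0]
        assert slope > 0
        assert fracs[-1] > fracs[0]


class TestTrueSuitability:
    def test_plateau_flat_above_threshold(self, truth):
        lo = true_suitability(31.0, truth.chla_plateau, 30.0, -12.0, truth)
        hi = true_suitability(31.0, 2 * truth.chla_plateau, 30.0, -12.0, truth)
        assert lo == hi

    def test_cold_water_tail_near_zero(self, truth):
        s = true_suitability(25.0, 50.0, 30.0, -12.0, truth)
        assert s <= 0.05

    def test_matches_closed_form_product(self, truth):
        rng = np.random.default_rng(0)
        sst = rng.uniform(26, 36, 200)
        chla = rng.uniform(0, 30, 200)
        sal = rng.uniform(20, 40, 200)
        bathy = rng.uniform(-40, 5, 200)
        got = true_suitability(sst, chla, sal, bathy, truth)
        # independent recomputation of each response factor
        lo, hi = truth.sst_rise_range
        r1 = 1 / (1 + np.exp(-(sst - (lo + hi) / 2) / ((hi - lo) / 8)))
        u = np.minimum(chla / truth.chla_plateau, 1.0)
        r2 = 3 * u ** 2 - 2 * u ** 3
        r3 = 0.7 + 0.3 * np.exp(-((sal - truth.sal_opt) / truth.sal_scale) ** 2)
        r4 = 0.7 + 0.3 * np.exp(-((bathy - truth.bathy_opt) / truth.bathy_scale) ** 2)
        r5 = 1 / (1 + np.exp(bathy / 1.5))
        np.testing.assert_allclose(got, r1 * r2 * r3 * r4 * r5, atol=1e-12)
        assert ((got >= 0) & (got <= 1)).all()


class TestPreySampling:
    def test_zero_n_gives_empty(self, small_stacks, truth):
        assert len(sample_prey_presences(small_stacks, truth, 0, seed=0)) == 0

    def test_constant_high_suitability_uniform_over_domain(self, truth):
        # fields at the optimum of every response -> suitability ~ 1, so
        # accepted points should be uniform (quadrat chi-square GOF)
        stacks = constant_stacks({"sst": 40.0, "chla": 25.0, "sal": truth.sal_opt,
                                  "bathy": truth.bathy_opt})
        pts = sample_prey_presences(stacks, truth, 2000, seed=1)
        qx = np.digitize(pts["x"], np.linspace(0, 20_000, 5)[1:-1])
        qy = np.digitize(pts["y"], np.linspace(0, 20_000, 5)[1:-1])
        counts = pd.crosstab(qx, qy).to_numpy().ravel()
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_two_level_field_thinning_ratio(self, truth):
        # two SST halves chosen so the suitability ratio is exactly 4:1
        grid = GridSpec(0, 0, 1000.0, 20, 20)
        lo_mid = 31.0 + 0.25 * np.log(0.2 / 0.8)
        hi_mid = 31.0 + 0.25 * np.log(0.8 / 0.2)
        sst = np.full((20, 20), lo_mid)
        sst[:, 10:] = hi_mid
        stacks = constant_stacks({"chla": 25.0, "sal": truth.sal_opt,
                                  "bathy": truth.bathy_opt}, grid=grid)
        stacks["sst"] = RasterStack("sst", grid, {2015120: sst})
        n = 5000
        pts = sample_prey_presences(stacks, truth, n, seed=2)
        frac_hi = (pts["x"] > 10_000).mean()
        expect = 0.8 / (0.8 + 0.2)
        sd = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac_hi - expect) < 3 * sd

    def test_zero_suitability_fails_fast(self, truth):
        stacks = constant_stacks({"sst": 0.0, "chla": 0.0, "sal": 30.0,
                                  "bathy": -12.0})
        with pytest.raises(RuntimeError, match="identically zero"):
            sample_prey_presences(stacks, truth, 10, seed=0)


@pytest.fixture(scope="module")
def fixes(small_scenario, truth, small_stacks):
    return simulate_tracks(small_scenario, truth, small_stacks, 3,
                           lambda t: 2.0, seed=7)


class TestSimulateTracks:
    def test_round_trips_start_and_end_at_colony(self, fixes, small_scenario):
        cx, cy = small_scenario.colony_xy
        for (b, y, d), sub in fixes.groupby(["bird_id", "year", "day"]):
            for idx in (0, -1):
                r = np.hypot(sub["x"].iloc[idx] - cx, sub["y"].iloc[idx] - cy)
                assert r < 500.0

    def test_fix_interval_exactly_900s(self, fixes, truth):
        for _, sub in fixes.groupby(["bird_id", "year", "day"]):
            dt = sub["timestamp"].diff().dropna().dt.total_seconds()
            assert (dt == truth.fix_interval).all()

    def test_ars_slower_and_more_tortuous_than_transit(self, fixes):
        for (b, y, d), sub in fixes.groupby(["bird_id", "year", "day"]):
            xy = sub[["x", "y"]].to_numpy()
            steps = np.hypot(*np.diff(xy, axis=0).T)
            head = np.arctan2(*np.diff(xy, axis=0).T[::-1])
            turn = np.abs(np.angle(np.exp(1j * np.diff(head))))
            mode = sub["mode"].to_numpy()
            seg_mode = mode[1:]
            ars = seg_mode == "ars"
            tra = seg_mode == "transit"
            if ars.sum() > 3 and tra.sum() > 3:
                assert steps[ars].mean() < steps[tra].mean()
                t_ars = turn[ars[:-1] & (seg_mode[1:] == "ars")]
                t_tra = turn[tra[:-1] & (seg_mode[1:] == "transit")]
                if len(t_ars) > 3 and len(t_tra) > 3:
                    assert t_ars.mean() > t_tra.mean()

    def test_zero_preference_matches_uniform_destination_oracle(
            self, small_scenario, small_stacks):
        """With preference 0, ARS-bout suitability should match the mean over
        reachable water (the uniform-sampling oracle) within Monte Carlo error."""
        from forageq.synthetic import suitability_field
        # disable the central-place range taper so destination choice is
        # uniform over reachable water
        truth = TruthParams(range_scale_start=1e12, range_scale_end=1e12)
        fx = simulate_tracks(small_scenario, truth, small_stacks, 6,
                             lambda t: 0.0, seed=21)
        g = small_scenario.grid
        cx, cy = small_scenario.colony_xy
        key = small_stacks["sst"].days[0]
        vals = []
        for (b, y, d), sub in fx.groupby(["bird_id", "year", "day"]):
            a = sub[sub["mode"] == "ars"]
            if len(a) == 0:
                continue
            row, col = g.cell_index(a["x"].mean(), a["y"].mean())
            k = int(y) * 1000 + int(d)
            vals.append(suitability_field(small_stacks, k, truth)[row, col])
        vals = np.array(vals, float)
        # oracle: average suitability over reachable water cells and days
        bathy = small_stacks["bathy"].layers[key]
        X, Y = np.meshgrid(g.xcenters, g.ycenters)
        dist = np.hypot(X - cx, Y - cy)
        budget = 14 * 3600 - truth.ars_duration_range[1] - 2 * truth.fix_interval
        reach = (bathy < 0) & (dist > truth.min_trip_dist) & (dist < 0.45 * budget * truth.transit_speed)
        means = [suitability_field(small_stacks, k, truth)[reach].mean()
                 for k in small_stacks["sst"].days]
        expect = np.mean(means)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 4 * se + 0.02

    def test_colony_outside_extent_rejected(self, truth):
        with pytest.raises(ValueError, match="colony"):
            EnvScenario(grid=GridSpec(0, 0, 1000.0, 10, 10),
                        colony_xy=(50_000.0, 50_000.0))


class TestBirdMetadata:
    def test_masses_within_configured_range(self):
        md = generate_bird_metadata(200, seed=0)
        assert md["mass_g"].between(2600, 4330).all()

    def test_seeded_determinism(self):
        a = generate_bird_metadata(20, seed=4)
        b = generate_bird_metadata(20, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_allometry_exactly_cubic(self):
        md = generate_bird_metadata(30, seed=1, noise_sd=0.0)
        ratio = md["mass_g"] / md["tarsus_mm"] ** 3
        for _, sub in md.groupby("sex"):
            r = sub["mass_g"] / sub["tarsus_mm"] ** 3
            np.testing.assert_allclose(r, r.iloc[0], rtol=1e-12)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_bird_metadata(0, seed=0)
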