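import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulsetrack import parturition, scenarios, synth


class TestLandscape:
    def test_expected_layers_present(self, landscape):
        names = set(landscape.names())
        assert {
            "canopy",
            "shrub",
            "forb",
            "ruggedness",
            "elevation",
            "slope",
            "aspect",
            "veg_class",
            "dist_road",
            "dist_water",
        } <= names
        for name in names - {"veg_class"}:
            assert np.isfinite(landscape.layers[name]).all()

    def test_vegetation_has_four_classes_near_configured_proportions(self, landscape):
        veg = landscape.layers["veg_class"]
        vals, counts = np.unique(veg, return_counts=True)
        assert set(vals) == {0.0, 1.0, 2.0, 3.0}
        props = counts / veg.size
        for got, want in zip(props, [0.35, 0.30, 0.25, 0.10]):
            assert abs(got - want) < 0.02  # quantile cut on a smooth field

    def test_zero_smoothing_scale_gives_white_noise_at_configured_mean(self):
        cfg = synth.LandscapeConfig(
            extent=3000.0,
            seed=5,
            layer_params={"canopy": synth.LayerSpec(40.0, 5.0, 0.0, (None, None))},
        )
        land = synth.generate_landscape(cfg)
        arr = land.layers["canopy"]
        assert abs(arr.mean() - 40.0) < 0.5
        # no spatial correlation: neighboring cells nearly uncorrelated
        r = np.corrcoef(arr[:, :-1].ravel(), arr[:, 1:].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_fixed_seed_bit_identical(self):
        cfg = synth.LandscapeConfig(extent=1500.0, seed=42)
        a = synth.generate_landscape(cfg)
        b = synth.generate_landscape(synth.LandscapeConfig(extent=1500.0, seed=42))
        for name in a.names():
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    @pytest.mark.parametrize("bad", [{"extent": -1.0}, {"cell_size": 0.0}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.LandscapeConfig(**bad)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.LandscapeConfig(veg_proportions={"open_forest": 0.5, "other": 0.4})


def daily_mcps(traj):
    """MCP area per calendar day of one animal's fixes."""
    days = pd.DatetimeIndex(traj["t"]).floor("D")
    return {
        day: parturition.mcp_area(grp[["x", "y"]].to_numpy())
        for day, grp in traj.groupby(days)
        if len(grp) >= 3
    }


class TestPrey:
    def test_localization_radius_is_a_hard_postcondition(self, elk_sim):
        fixes, events = elk_sim
        for row in events.itertuples():
            grp = fixes[fixes["animal_id"] == row.animal_id]
            seg = grp[
                (grp["t"] >= row.event_time)
                & (grp["t"] <= row.event_time + pd.Timedelta(hours=144))
            ]
            d = np.hypot(seg["x"] - row.x, seg["y"] - row.y)
            assert (d <= 50.0 + 1e-9).all()

    def test_localized_daily_mcp_under_one_hectare(self, elk_sim):
        fixes, events = elk_sim
        row = events.iloc[0]
        grp = fixes[fixes["animal_id"] == row.animal_id]
        seg = grp[
            (grp["t"] >= row.event_time + pd.Timedelta(hours=1))
            & (grp["t"] <= row.event_time + pd.Timedelta(hours=144))
        ]
        for area in daily_mcps(seg).values():
            assert area < 1.0  # 50-m disc is at most ~0.79 ha

    def test_prepartum_daily_mcp_exceeds_30ha_for_95pct_of_animal_days(self, elk_sim):
        fixes, events = elk_sim
        ev = {r.animal_id: r.event_time for r in events.itertuples()}
        areas = []
        for aid, grp in fixes.groupby("animal_id"):
            pre = grp[grp["t"] < ev[aid] - pd.Timedelta(hours=24)]
            areas.extend(daily_mcps(pre).values())
        assert len(areas) > 50
        frac = np.mean(np.asarray(areas) > 30.0)
        assert frac >= 0.95

    def test_zero_birth_sd_gives_one_birth_day(self, landscape):
        cfg = scenarios.elk_prey_config(birth_doy_sd=0.0)
        _, events = synth.simulate_prey(cfg, landscape, 6, seed=3, duration_d=60)
        assert pd.DatetimeIndex(events["event_time"]).dayofyear.nunique() == 1

    def test_oversized_localization_radius_rejected(self, landscape):
        cfg = scenarios.elk_prey_config(localization_radius_m=5000.0)
        with pytest.raises(ValueError, match="radius"):
            synth.simulate_prey(cfg, landscape, 1, seed=0)

    def test_fixed_seed_identical(self, landscape):
        cfg = scenarios.elk_prey_config()
        a, ea = synth.simulate_prey(cfg, landscape, 3, seed=9, duration_d=40)
        b, eb = synth.simulate_prey(cfg, landscape, 3, seed=9, duration_d=40)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ea, eb)

    def test_timestamps_strictly_increasing(self, elk_sim):
        fixes, _ = elk_sim
        for _, grp in fixes.groupby("animal_id"):
            assert (grp["t"].diff().dropna() > pd.Timedelta(0)).all()


@pytest.fixture(scope="module")
def big_landscape():
    """Large arena so boundary truncation of candidate sets is rare."""
    return synth.generate_landscape(synth.LandscapeConfig(extent=8000.0, seed=8))


class TestPredator:
    def test_uniform_choice_when_indifferent(self, big_landscape):
        """With no selection the chosen candidate rank is uniform
        (among steps whose full candidate set stayed in bounds)."""
        cfg = synth.PredatorBehaviorConfig(
            beta_true={}, beta_enc=0.0, fix_interval_min=5.0, step_scale_m=150.0
        )
        _, diag = synth.simulate_predator(
            cfg, big_landscape, None, None, 1, seed=17, duration_d=55.0, return_diagnostics=True
        )
        full = diag[diag["n_in_bounds"] == cfg.n_candidates]
        assert len(full) >= 10_000
        counts = np.bincount(full["chosen_rank"], minlength=cfg.n_candidates)
        stat, p = stats.chisquare(counts)
        assert p > 0.01

    def test_kernel_fidelity_of_chosen_step_lengths(self, big_landscape):
        cfg = synth.PredatorBehaviorConfig(beta_true={}, fix_interval_min=5.0, step_scale_m=150.0)
        _, diag = synth.simulate_predator(
            cfg, big_landscape, None, None, 1, seed=23, duration_d=55.0, return_diagnostics=True
        )
        lengths = diag.loc[diag["n_in_bounds"] == cfg.n_candidates, "step_length"].to_numpy()
        assert len(lengths) >= 10_000
        shape, _, scale = stats.gamma.fit(lengths, floc=0)
        assert abs(shape - cfg.step_shape) / cfg.step_shape < 0.05
        assert abs(scale - cfg.step_scale_m) / cfg.step_scale_m < 0.05

    def test_strong_attraction_increases_time_near_prey(self, landscape):
        """beta_enc = 10 with a stationary parturient female pulls the
        predator within 200 m far more often than indifference does."""
        t = pd.date_range("2021-05-01", periods=2000, freq="30min", tz="UTC")
        prey = pd.DataFrame(
            {
                "animal_id": "e_stat",
                "species": "elk",
                "sex": "F",
                "t": t,
                "x": 1000.0,
                "y": 1000.0,
            }
        )
        events = pd.DataFrame(
            {
                "animal_id": ["e_stat"],
                "event_time": [pd.Timestamp("2021-05-01", tz="UTC")],
                "method": ["truth"],
                "x": [1000.0],
                "y": [1000.0],
            }
        )

        def near_frac(beta_enc, seed):
            cfg = synth.PredatorBehaviorConfig(beta_true={}, beta_enc=beta_enc)
            fixes = synth.simulate_predator(
                cfg, landscape, prey, events, 2, seed=seed, duration_d=30.0
            )
            d = np.hypot(fixes["x"] - 1000.0, fixes["y"] - 1000.0)
            return (d <= 200.0).mean()

        assert near_frac(10.0, 31) > near_frac(0.0, 31)

    def test_empty_prey_with_attraction_rejected(self, landscape):
        cfg = synth.PredatorBehaviorConfig(beta_enc=1.0)
        with pytest.raises(ValueError, match="prey"):
            synth.simulate_predator(cfg, landscape, None, None, 1, seed=0)

    def test_fixed_seed_identical(self, landscape):
        cfg = scenarios.cougar_config(beta_enc=0.0)
        a = synth.simulate_predator(cfg, landscape, None, None, 2, seed=5, duration_d=20)
        b = synth.simulate_predator(cfg, landscape, None, None, 2, seed=5, duration_d=20)
        pd.testing.assert_frame_equal(a, b)


class TestSampleSitesByWeight:
    def test_sites_concentrate_where_weight_is_high(self, landscape):
        pts = synth.sample_sites_by_weight(landscape, {"canopy": 2.0}, 500, seed=2)
        canopy = landscape.sample(pts["x"].to_numpy(), pts["y"].to_numpy(), "canopy")
        assert canopy.mean() > landscape.layers["canopy"].mean()

    def test_uniform_when_no_weight(self, landscape):
        pts = synth.sample_sites_by_weight(landscape, {}, 4000, seed=3)
        # quadrant counts roughly equal
        half = landscape.extent[2] / 2
        q = (pts["x"] > half).astype(int) * 2 + (pts["y"] > half).astype(int)
        counts = np.bincount(q, minlength=4)
        stat, p = stats.chisquare(counts)
        assert p > 0.01
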