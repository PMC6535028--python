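"""MCMC apportionment of the PP-C fraction."""

import datetime as dt

import numpy as np
import pytest

import fluvial14c as f14
from conftest import fixed_endmembers

CFG = f14.MCMCConfig(iterations=50_000, burn_in=5_000, thinning=10, seed=5)


class TestSeasons:
    @pytest.mark.parametrize(
        "date, season",
        [
            (dt.date(2009, 5, 30), "spring"),
            (dt.date(2009, 6, 1), "spring"),
            (dt.date(2009, 7, 1), "summer_fall"),
            (dt.date(2009, 10, 31), "summer_fall"),
            (dt.date(2009, 11, 1), "winter"),
            (dt.date(2009, 4, 30), "winter"),
            (dt.date(2009, 1, 15), "winter"),
        ],
    )
    def test_assignment(self, date, season):
        assert f14.assign_season(date) == season

    def test_sample_season_derived_from_date(self):
        s = f14.RiverSample("Ob", dt.date(2010, 5, 3), "DOC", 50.0)
        assert s.season == "spring" and s.collection_year == 2010


class TestRiverSampleValidation:
    def test_rejects_bad_fields(self):
        with pytest.raises(ValueError):
            f14.RiverSample("Ob", dt.date(2010, 1, 1), "TOC", 0.0)
        with pytest.raises(ValueError):
            f14.RiverSample("Ob", dt.date(2010, 1, 1), "DOC", -1000.0)
        with pytest.raises(ValueError):
            f14.RiverSample("Ob", dt.date(2010, 1, 1), "DOC", 0.0, flux_weight=-1)


class TestMCMCConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            f14.MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            f14.MCMCConfig(thinning=0)

    def test_retained_draw_count(self):
        rec, ppc = fixed_endmembers()
        post = f14.apportion(-143.0, rec, ppc, CFG, obs_sd=20.0)
        assert post.draws.size == (CFG.iterations - CFG.burn_in) // CFG.thinning

    def test_scaled_down_variant(self):
        cfg = f14.MCMCConfig().scaled_down()
        assert cfg.iterations == 100_000 and cfg.burn_in <= 10_000


class TestApportion:
    def test_observation_at_recent_endmember_gives_near_zero_fraction(self):
        rec, ppc = fixed_endmembers()
        post = f14.apportion(97.0, rec, ppc, CFG, obs_sd=5.0)
        assert post.mean < 0.05
        assert np.quantile(post.draws, 0.5) < 0.02

    def test_midpoint_observation_recovers_half(self):
        """Δ_obs exactly between the endmembers: posterior mean f ≈ 0.5,
        checked against a grid-integration oracle."""
        rec, ppc = fixed_endmembers(97.0, -383.0)
        post = f14.apportion(-143.0, rec, ppc, CFG, obs_sd=20.0)
        grid = np.linspace(0, 1, 2001)
        mix = grid * -383.0 + (1 - grid) * 97.0
        like = np.exp(-((-143.0 - mix) ** 2) / (2 * 20.0**2))
        oracle = float(np.sum(grid * like) / np.sum(like))
        assert post.mean == pytest.approx(oracle, abs=0.02)
        assert post.mean == pytest.approx(0.5, abs=0.02)

    def test_posterior_mean_monotone_in_observation_age(self):
        """Older carbon (lower Δ¹⁴C) never decreases the inferred fraction."""
        rec, ppc = fixed_endmembers()
        means = [
            f14.apportion(obs, rec, ppc, CFG, obs_sd=20.0).mean
            for obs in np.linspace(97.0, -383.0, 9)
        ]
        assert np.all(np.diff(means) > -0.01)

    def test_observation_above_recent_endmember(self):
        """Prior support keeps mean f > 0 but the mode collapses to 0."""
        rec, ppc = fixed_endmembers()
        post = f14.apportion(160.0, rec, ppc, CFG, obs_sd=30.0)
        assert post.mean > 0.0
        near_zero = np.mean(post.draws < 0.02)
        next_band = np.mean((post.draws >= 0.02) & (post.draws < 0.04))
        assert near_zero > next_band  # density decreasing away from 0

    def test_deterministic_given_seed(self):
        rec, ppc = fixed_endmembers()
        a = f14.apportion(-143.0, rec, ppc, CFG, obs_sd=20.0)
        b = f14.apportion(-143.0, rec, ppc, CFG, obs_sd=20.0)
        assert np.array_equal(a.draws, b.draws)

    def test_group_pooling_tightens_posterior(self, recent):
        ppc = f14.scenario_endmember("Ob", "best_estimate", n_draws=20_000, seed=3)
        one = f14.apportion(-143.0, recent, ppc, CFG, obs_sd=20.0)
        group = f14.apportion([-143.0] * 20, recent, ppc, CFG, obs_sd=20.0)
        assert group.sd < one.sd

    def test_input_validation(self, recent):
        _, ppc = fixed_endmembers()
        with pytest.raises(ValueError):
            f14.apportion(float("nan"), recent, ppc, CFG)
        with pytest.raises(ValueError):
            f14.apportion(-143.0, recent, ppc, CFG, obs_sd=0.0)
        with pytest.raises(ValueError):
            f14.apportion([], recent, ppc, CFG)


class TestAggregation:
    def test_single_posterior_returns_own_summary(self):
        rng = np.random.default_rng(0)
        post = f14.PosteriorFraction("x", rng.uniform(0.2, 0.4, 5000))
        mean, sd = f14.aggregate_fractions([post], [1.0], seed=0)
        assert mean == pytest.approx(post.mean * 100, abs=0.5)
        assert sd == pytest.approx(post.sd * 100, abs=0.5)

    def test_point_masses_weighted_mean(self):
        posts = [
            f14.PosteriorFraction.point_mass("a", 0.2),
            f14.PosteriorFraction.point_mass("b", 0.6),
        ]
        mean, sd = f14.aggregate_fractions(posts, [1.0, 3.0], seed=0)
        assert mean == pytest.approx(50.0)
        assert sd == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            f14.aggregate_fractions([], [])

    def test_combine_posteriors_point_masses(self):
        posts = [
            f14.PosteriorFraction.point_mass("a", 0.2),
            f14.PosteriorFraction.point_mass("b", 0.6),
        ]
        group = f14.combine_posteriors(posts, [1.0, 3.0], "g", seed=1)
        assert group.mean == pytest.approx(0.5)

    def test_apportion_each_is_deterministic(self, recent):
        _, ppc = fixed_endmembers()
        samples = [
            f14.RiverSample("Ob", dt.date(2010, 5, 3), "DOC", d)
            for d in (-100.0, -200.0)
        ]
        cfg = f14.MCMCConfig(iterations=20_000, burn_in=2_000, seed=11)
        a = f14.apportion_each(samples, recent, ppc, cfg)
        b = f14.apportion_each(samples, recent, ppc, cfg)
        assert all(np.array_equal(x.draws, y.draws) for x, y in zip(a, b))
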