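"""Source pools and composite PP-C endmember construction."""

import numpy as np
import pytest

import fluvial14c as f14
from fluvial14c.endmembers import pools_by_name


class TestDefaultPools:
    @pytest.mark.parametrize(
        "name, mean, sd, n",
        [
            ("recent_production", 97.0, 124.8, 58),
            ("active_layer", -197.5, 148.4, 60),
            ("holocene_deposits", -567.5, 156.7, 138),
            ("pleistocene_deposits", -954.8, 65.8, 329),
        ],
    )
    def test_pool_values(self, pools, name, mean, sd, n):
        pool = pools_by_name(pools)[name]
        assert (pool.delta14c_mean, pool.delta14c_sd, pool.n) == (mean, sd, n)

    def test_four_pools(self, pools):
        assert len(pools) == 4

    def test_invalid_pools_rejected(self):
        with pytest.raises(ValueError):
            f14.SourcePool("x", 0.0, 0.0, 5)
        with pytest.raises(ValueError):
            f14.SourcePool("x", -1000.0, 10.0, 5)
        with pytest.raises(ValueError):
            f14.SourcePool("x", 0.0, 10.0, 0)


class TestCompositeEndmember:
    def test_single_pool_reduces_to_pool_distribution(self, pools):
        al = pools_by_name(pools)["active_layer"]
        comp = f14.composite_ppc_endmember([al], n_draws=100_000, seed=1)
        se = al.delta14c_sd / np.sqrt(100_000)
        assert comp.summary_mean == pytest.approx(al.delta14c_mean, abs=3 * se)
        assert comp.summary_sd == pytest.approx(al.delta14c_sd, rel=0.02)
        assert comp.pools == ("active_layer",)

    def test_two_pool_composite_matches_closed_forms(self, west_pools):
        """Flat-Dirichlet composite: mean of pool means; inflated variance
        (σ₁²+σ₂²)/3 + (μ₁−μ₂)²/12."""
        comp = f14.composite_ppc_endmember(west_pools, n_draws=200_000, seed=2)
        mu1, mu2 = (p.delta14c_mean for p in west_pools)
        s1, s2 = (p.delta14c_sd for p in west_pools)
        exp_mean = (mu1 + mu2) / 2
        exp_sd = np.sqrt((s1**2 + s2**2) / 3 + (mu1 - mu2) ** 2 / 12)
        se = exp_sd / np.sqrt(200_000)
        assert comp.summary_mean == pytest.approx(exp_mean, abs=3 * se)
        assert comp.summary_sd == pytest.approx(exp_sd, rel=0.02)
        cm, cs = f14.composite_moments(west_pools)
        assert cm == pytest.approx(exp_mean) and cs == pytest.approx(exp_sd)

    @pytest.mark.parametrize(
        "names",
        [
            ("active_layer",),
            ("active_layer", "holocene_deposits"),
            ("active_layer", "holocene_deposits", "pleistocene_deposits"),
        ],
    )
    def test_composite_mean_is_mean_of_pool_means(self, pools, names):
        members = [pools_by_name(pools)[n] for n in names]
        comp = f14.composite_ppc_endmember(members, n_draws=100_000, seed=3)
        expected = np.mean([p.delta14c_mean for p in members])
        se = comp.summary_sd / np.sqrt(comp.draws.size)
        # Pleistocene truncation at -1000‰ biases the mean by < 1‰
        assert comp.summary_mean == pytest.approx(expected, abs=3 * se + 1.0)

    def test_composite_sd_exceeds_fixed_weight_sd(self, pools):
        """Compositional uncertainty inflates the spread beyond both the
        per-pool σ/√k floor and the fixed equal-weight mixture SD."""
        for names in (
            ("active_layer", "holocene_deposits"),
            ("active_layer", "holocene_deposits", "pleistocene_deposits"),
        ):
            members = [pools_by_name(pools)[n] for n in names]
            comp = f14.composite_ppc_endmember(members, n_draws=100_000, seed=4)
            k = len(members)
            sds = np.array([p.delta14c_sd for p in members])
            assert comp.summary_sd >= sds.max() / np.sqrt(3) - 1e-9
            fixed_sd = np.sqrt(np.sum(sds**2)) / k
            assert comp.summary_sd > fixed_sd

    def test_deterministic_given_seed(self, west_pools):
        a = f14.composite_ppc_endmember(west_pools, n_draws=10_000, seed=9)
        b = f14.composite_ppc_endmember(west_pools, n_draws=10_000, seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_preconditions(self, pools):
        with pytest.raises(ValueError):
            f14.composite_ppc_endmember([], n_draws=10_000)
        with pytest.raises(ValueError):
            f14.composite_ppc_endmember(pools[:1], n_draws=100)

    def test_untruncated_pool_mean_is_unbiased(self, pools):
        """The oldest pool keeps its stated mean: no truncation bias from
        the −1000‰ floor (which would shift it by ≈ +27‰)."""
        pl = pools_by_name(pools)["pleistocene_deposits"]
        comp = f14.composite_ppc_endmember([pl], n_draws=100_000, seed=5)
        se = pl.delta14c_sd / np.sqrt(100_000)
        assert comp.summary_mean == pytest.approx(pl.delta14c_mean, abs=3 * se)


class TestScenarios:
    @pytest.mark.parametrize(
        "river, scenario, expected_pools",
        [
            ("Ob", "best_estimate", ("active_layer", "holocene_deposits")),
            ("Yenisey", "best_estimate", ("active_layer", "holocene_deposits")),
            ("Lena", "best_estimate",
             ("active_layer", "holocene_deposits", "pleistocene_deposits")),
            ("Kolyma", "best_estimate",
             ("active_layer", "holocene_deposits", "pleistocene_deposits")),
            ("Ob", "minimum", ("holocene_deposits",)),
            ("Kolyma", "minimum", ("pleistocene_deposits",)),
            ("Lena", "maximum", ("active_layer",)),
        ],
    )
    def test_pool_dispatch(self, river, scenario, expected_pools):
        comp = f14.scenario_endmember(river, scenario, n_draws=10_000, seed=6)
        assert comp.pools == expected_pools

    def test_kolyma_best_estimate_mean(self):
        comp = f14.scenario_endmember("Kolyma", "best_estimate",
                                      n_draws=200_000, seed=7)
        expected = (-197.5 - 567.5 - 954.8) / 3
        se = comp.summary_sd / np.sqrt(comp.draws.size)
        assert comp.summary_mean == pytest.approx(expected, abs=3 * se + 1.0)

    def test_ob_minimum_is_holocene_distribution(self):
        comp = f14.scenario_endmember("Ob", "minimum", n_draws=100_000, seed=8)
        assert comp.summary_mean == pytest.approx(-567.5, abs=2.0)
        assert comp.summary_sd == pytest.approx(156.7, rel=0.02)

    def test_unknown_river_or_scenario(self):
        with pytest.raises(KeyError):
            f14.scenario_endmember("Amazon", "best_estimate", n_draws=10_000)
        with pytest.raises(ValueError):
            f14.scenario_endmember("Ob", "middling", n_draws=10_000)


class TestPoolDatabase:
    def test_yaml_round_trip(self, pools, tmp_path):
        path = tmp_path / "pools.yaml"
        f14.endmembers.write_pools(pools, path)
        loaded = f14.endmembers.load_pools(path)
        assert loaded == pools

    def test_recent_pool_required(self, pools, tmp_path):
        path = tmp_path / "pools.yaml"
        f14.endmembers.write_pools(pools[1:], path)
        with pytest.raises(ValueError):
            f14.endmembers.load_pools(path)
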