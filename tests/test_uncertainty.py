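import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tal_biorefinery.config import apply_overrides
from tal_biorefinery.uncertainty import (
    ParameterDistribution,
    lhs_sample,
    monte_carlo,
    grid_map,
    scenario,
    spearman_screen,
)


def uniform01(name="u", path="prices.csl_usd_per_kg"):
    return ParameterDistribution(
        name=name, shape="uniform", lower=0.0, upper=1.0, mode=None,
        baseline=0.5, path=path,
    )


class TestLhs:
    def test_one_sample_per_quartile(self):
        table = lhs_sample([uniform01()], n=4, seed=0)
        values = np.sort(table.samples.iloc[:, 0].to_numpy())
        for i, v in enumerate(values):
            assert i / 4 <= v < (i + 1) / 4

    @pytest.mark.parametrize("n", [1, 7, 64, 301])
    def test_stratification_exact_for_any_n(self, n):
        tri = ParameterDistribution(
            name="t", shape="triangular", lower=2.0, upper=10.0, mode=3.0,
            baseline=3.0, path="x",
        )
        table = lhs_sample([uniform01(), tri], n=n, seed=123)
        u = np.sort(table.samples["prices.csl_usd_per_kg"].to_numpy())
        assert all(i / n <= v < (i + 1) / n for i, v in enumerate(u))
        # triangular strata checked through the CDF
        c = (3.0 - 2.0) / (10.0 - 2.0)
        q = np.sort(stats.triang.cdf(table.samples["x"], c, loc=2.0, scale=8.0))
        assert all(i / n <= v < (i + 1) / n + 1e-12 for i, v in enumerate(q))

    def test_same_seed_reproduces_table(self):
        a = lhs_sample([uniform01()], n=50, seed=99).samples
        b = lhs_sample([uniform01()], n=50, seed=99).samples
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_mean_near_half(self):
        table = lhs_sample([uniform01()], n=10_000, seed=5)
        assert abs(table.samples.iloc[:, 0].mean() - 0.5) < 0.01

    def test_invalid_bounds_name_the_parameter(self):
        with pytest.raises(ValueError, match="bad_param"):
            ParameterDistribution(
                name="bad_param", shape="uniform", lower=1.0, upper=0.0,
                mode=None, baseline=0.5, path="x",
            )


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(n=st.integers(min_value=1, max_value=200), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_stratification_holds_for_arbitrary_n_and_seed(n, seed):
        table = lhs_sample([uniform01()], n=n, seed=seed)
        u = np.sort(table.samples.iloc[:, 0].to_numpy())
        assert all(i / n <= v < (i + 1) / n for i, v in enumerate(u))

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


class TestMonteCarlo:
    def test_constant_model_collapses_percentiles(self):
        table = lhs_sample([uniform01()], n=40, seed=1)
        mc = monte_carlo(lambda s: {"y": 3.14}, table)
        summary = mc.summaries["y"]
        assert all(v == pytest.approx(3.14) for v in summary.percentiles.values())
        assert summary.baseline == pytest.approx(3.14)

    def test_percentiles_ordered(self):
        table = lhs_sample([uniform01()], n=100, seed=2)
        mc = monte_carlo(lambda s: {"y": list(s.values())[0] ** 2}, table)
        p = mc.summaries["y"].percentiles
        assert p[5] <= p[25] <= p[50] <= p[75] <= p[95]

    def test_percentiles_match_sort_based_oracle(self):
        table = lhs_sample([uniform01()], n=100, seed=3)
        mc = monte_carlo(lambda s: {"y": list(s.values())[0]}, table)
        y = np.sort(mc.indicators["y"].to_numpy())

        def oracle(q):  # linear interpolation between order statistics
            h = (len(y) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(y) - 1)
            return y[lo] + (h - lo) * (y[hi] - y[lo])

        for q, v in mc.summaries["y"].percentiles.items():
            assert v == pytest.approx(oracle(q), abs=1e-12)

    def test_failures_recorded_and_flagged(self):
        table = lhs_sample([uniform01()], n=50, seed=4)

        def flaky(s):
            if list(s.values())[0] > 0.9:
                raise RuntimeError("boom")
            return {"y": 1.0}

        with pytest.warns(RuntimeWarning, match="failed"):
            mc = monte_carlo(flaky, table)
        assert mc.n_failed == int(mc.indicators["y"].isna().sum())
        assert mc.flagged


class TestSpearman:
    def test_strictly_monotone_gives_plus_minus_one(self):
        table = lhs_sample([uniform01()], n=60, seed=6)
        x = table.samples.iloc[:, 0]
        up = spearman_screen(table, np.exp(3 * x)).table
        down = spearman_screen(table, -(x**3)).table
        assert up.rho.iloc[0] == pytest.approx(1.0)
        assert up.significant.iloc[0]
        assert down.rho.iloc[0] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_correlation(self):
        """Midrank-tie rank correlation recomputed from first principles."""
        rng = np.random.default_rng(11)
        for n in (10, 57, 200):
            x = rng.integers(0, 12, size=n).astype(float)  # ties likely
            y = np.round(rng.normal(size=n), 1) + 0.3 * x
            dist = uniform01()
            table = lhs_sample([dist], n=n, seed=1)
            table.samples.iloc[:, 0] = x
            res = spearman_screen(table, y).table
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            brute = np.corrcoef(rx, ry)[0, 1]
            assert res.rho.iloc[0] == pytest.approx(brute, abs=1e-12)

    def test_constant_output_reported_as_zero_with_note(self):
        table = lhs_sample([uniform01()], n=20, seed=7)
        res = spearman_screen(table, np.ones(20))
        assert res.table.rho.iloc[0] == 0.0
        assert not res.table.significant.iloc[0]
        assert res.notes

    def test_null_false_flag_rate_matches_dual_threshold(self):
        """Independent noise at n = 6000: the |rho| >= 0.10 requirement makes
        the dual-threshold false-flag probability numerically zero."""
        rng = np.random.default_rng(42)
        n, reps, n_params = 6000, 100, 3
        flags = 0
        dists = [uniform01(name=f"p{i}", path=f"p{i}") for i in range(n_params)]
        for _ in range(reps):
            table = lhs_sample(dists, n=n, seed=int(rng.integers(2**31)))
            y = rng.uniform(size=n)
            res = spearman_screen(table, y).table
            flags += int(res.significant.sum())
        # nominal level: P(|rho| >= 0.10) at n=6000 is ~1e-14 per parameter
        assert flags == 0

    def test_small_sample_rejected(self):
        table = lhs_sample([uniform01()], n=5, seed=8)
        with pytest.raises(ValueError):
            spearman_screen(table, np.arange(5.0))


class TestGridAndScenario:
    def test_grid_cell_count_and_infeasible_wedge(self, cfg):
        g = grid_map(
            ("fermentation.yield_fraction_of_theoretical", np.linspace(0.1, 0.99, 6)),
            ("fermentation.titer_g_per_L", np.linspace(5.0, 100.0, 6)),
            cfg,
        )
        assert len(g) == 36
        # low-yield/high-titer corner is infeasible, high-yield corner is not
        corner = g[(g.x == g.x.min()) & (g.y == g.y.max())]
        assert not corner.feasible.iloc[0]
        best = g[(g.x == g.x.max()) & (g.y == g.y.min())]
        assert best.feasible.iloc[0]

    def test_mpsp_nonincreasing_in_yield_at_fixed_titer(self, cfg):
        g = grid_map(
            ("fermentation.yield_fraction_of_theoretical", np.linspace(0.3, 0.9, 5)),
            ("fermentation.titer_g_per_L", [30.0, 35.9]),
            cfg,
        )
        for _, row in g.groupby("y"):
            vals = row.sort_values("x")["mpsp_usd_per_kg"].dropna().tolist()
            assert vals == sorted(vals, reverse=True)

    def test_grid_baseline_cell_matches_plain_pipeline(self, cfg, baseline_run):
        g = grid_map(
            ("fermentation.yield_fraction_of_theoretical", [0.3, 0.405]),
            ("fermentation.titer_g_per_L", [30.0, 35.9]),
            cfg,
        )
        cell = g[(g.x == 0.405) & (g.y == 35.9)]
        assert cell.mpsp_usd_per_kg.iloc[0] == pytest.approx(
            baseline_run["mpsp_usd_per_kg"], rel=1e-9
        )

    def test_axis_resolution_must_be_at_least_two(self, cfg):
        with pytest.raises(ValueError):
            grid_map(("fermentation.titer_g_per_L", [35.9]),
                     ("fermentation.yield_fraction_of_theoretical", [0.4, 0.5]), cfg)

    def test_empty_overrides_reproduce_baseline(self, cfg, baseline_run):
        out = scenario(cfg, {})
        assert out["mpsp_usd_per_kg"] == pytest.approx(
            baseline_run["mpsp_usd_per_kg"], rel=1e-12
        )
        assert out["delta_mpsp_usd_per_kg"] == pytest.approx(0.0, abs=1e-9)

    def test_improved_fermentation_lowers_mpsp(self, cfg):
        out = scenario(
            cfg,
            {"fermentation.yield_fraction_of_theoretical": 0.73,
             "fermentation.titer_g_per_L": 68.0},
        )
        assert out["delta_mpsp_usd_per_kg"] < 0.0

    def test_unknown_override_path_rejected(self, cfg):
        with pytest.raises(Exception, match="not found"):
            scenario(cfg, {"fermentation.does_not_exist": 1.0})

    def test_operation_capacity_map_has_6400_cells(self, cfg):
        g = grid_map(
            ("operation.days_per_year", np.linspace(120.0, 330.0, 80)),
            ("operation.capacity_factor", np.linspace(0.5, 3.0, 80)),
            cfg,
        )
        assert len(g) == 6400
        assert g.feasible.all()  # schedule/capacity cannot make titer infeasible

    def test_combined_improvement_scenario_cuts_mpsp_by_over_30_percent(self, cfg, baseline_run):
        """Better fermentation (73% of theoretical yield, 68 g/L titer),
        sorghum-extended operation (240 d) and pH-11 separation together."""
        out = scenario(
            cfg,
            {
                "fermentation.yield_fraction_of_theoretical": 0.73,
                "fermentation.titer_g_per_L": 68.0,
                "operation.days_per_year": 240.0,
                "separation.maintained_pH": 11.0,
            },
        )
        base = baseline_run["mpsp_usd_per_kg"]
        assert out["mpsp_usd_per_kg"] < 0.7 * base
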