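"""Climatology grids, IDW interpolation, stability and its transforms."""

import numpy as np
import pandas as pd
import pytest

from tfstability import env_context as env
from tfstability import synthetic as syn

DEG_PER_KM = 180.0 / (np.pi * env.EARTH_RADIUS_KM)  # along a meridian


def tiny_grid(values, lats, lons, depths=(0.0,), parameter="temperature", units="degC"):
    """Grid with the same node values in all 12 months."""
    arr = np.broadcast_to(
        np.asarray(values, dtype=float)[:, :, None, None],
        (len(lats), len(lons), len(depths), 12),
    ).copy()
    return env.GriddedClimatology(parameter, units, lats, lons, depths, arr)


class TestIDW:
    def test_query_on_grid_node_returns_node_value(self):
        g = tiny_grid([[1.0, 2.0], [3.0, 4.0]], lats=[0.0, 1.0], lons=[10.0, 11.0])
        site = env.SampleSite("s", 1.0, 11.0, 0.0)
        assert env.idw_interpolate(g, site, month=1) == 4.0

    @pytest.mark.parametrize("power", [1.0, 2.0, 3.5])
    def test_equidistant_nodes_average_for_any_power(self, power):
        g = tiny_grid([[10.0], [20.0]], lats=[-1.0, 1.0], lons=[0.0])
        site = env.SampleSite("s", 0.0, 0.0, 0.0)
        got = env.idw_interpolate(g, site, month=3, power=power, k_neighbors=2)
        assert got == pytest.approx(15.0, rel=1e-9)

    def test_hand_evaluated_weighted_sum(self):
        # nodes 1 km and 2 km along the meridian, values 0 and 30, power 2:
        # 30 * (1/4) / (1 + 1/4) = 6
        g = tiny_grid(
            [[30.0], [0.0]], lats=[-2.0 * DEG_PER_KM, 1.0 * DEG_PER_KM], lons=[0.0]
        )
        site = env.SampleSite("s", 0.0, 0.0, 0.0)
        got = env.idw_interpolate(g, site, month=1, power=2.0, k_neighbors=2)
        assert got == pytest.approx(6.0, rel=1e-6)

    def test_site_outside_grid_raises(self):
        g = tiny_grid([[1.0, 2.0], [3.0, 4.0]], lats=[0.0, 1.0], lons=[10.0, 11.0])
        with pytest.raises(ValueError, match="outside"):
            env.idw_interpolate(g, env.SampleSite("s", 5.0, 10.5, 0.0), month=1)

    def test_all_missing_neighbors_signal_no_reliable_interpolation(self):
        g = tiny_grid([[np.nan, np.nan]], lats=[0.0], lons=[10.0, 11.0])
        with pytest.raises(env.InterpolationError):
            env.idw_interpolate(g, env.SampleSite("s", 0.0, 10.5, 0.0), month=1)

    def test_convex_combination_bounds(self, rng):
        vals = rng.uniform(0.0, 10.0, size=(4, 4))
        g = tiny_grid(vals, lats=[0.0, 1, 2, 3], lons=[10.0, 11, 12, 13])
        for _ in range(20):
            site = env.SampleSite("s", rng.uniform(0, 3), rng.uniform(10, 13), 0.0)
            got = env.idw_interpolate(g, site, month=1)
            assert vals.min() - 1e-12 <= got <= vals.max() + 1e-12


class TestMonthlySeriesAndStability:
    def test_constant_grid_gives_constant_series_and_zero_stability(self):
        g = tiny_grid([[7.0]], lats=[0.0], lons=[0.0])
        series = env.monthly_series(g, env.SampleSite("s", 0.0, 0.0, 0.0))
        assert series.available
        assert np.allclose(series.values, 7.0)
        assert env.stability(series) == 0.0

    def test_noise_free_sinusoid_matches_analytic_cycle(self):
        spec = syn.SyntheticSpec(
            lat_range=(-4.0, 4.0), lon_range=(-4.0, 4.0),
            noise_sd={p: 0.0 for p in syn.PARAMETER_DEFAULTS},
            spatial_trend={p: 0.0 for p in syn.PARAMETER_DEFAULTS},
        )
        g = syn.make_climatology(spec, "salinity")
        site = env.SampleSite("s", float(g.latitudes[2]), float(g.longitudes[3]), 0.0)
        series = env.monthly_series(g, site)
        amp, base = spec.amplitude("salinity"), syn.PARAMETER_DEFAULTS["salinity"][1]
        expect = base + amp * np.sin(2 * np.pi * np.arange(1, 13) / 12.0)
        np.testing.assert_allclose(series.values, expect, atol=1e-9)

    def test_series_flagged_unavailable_when_a_month_fails(self):
        arr = np.full((1, 2, 1, 12), 5.0)
        arr[:, :, :, 6] = np.nan  # July missing everywhere
        g = env.GriddedClimatology("temperature", "degC", [0.0], [10.0, 11.0], [0.0], arr)
        series = env.monthly_series(g, env.SampleSite("s", 0.0, 10.5, 0.0))
        assert not series.available
        with pytest.raises(ValueError):
            env.stability(series)

    def test_stability_of_one_to_twelve_is_sqrt_thirteen(self):
        series = env.MonthlySeries("s", "temperature", np.arange(1.0, 13.0))
        assert env.stability(series) == pytest.approx(np.sqrt(13.0), abs=1e-12)

    @pytest.mark.parametrize("c", [0.5, -2.0, 3.0])
    def test_stability_scales_with_amplitude_and_ignores_offset(self, c, rng):
        x = rng.normal(size=12)
        s = env.stability(env.MonthlySeries("s", "t", x))
        assert env.stability(env.MonthlySeries("s", "t", c * x)) == pytest.approx(abs(c) * s)
        assert env.stability(env.MonthlySeries("s", "t", x + 100.0)) == pytest.approx(s)

    def test_composite_sample_series_is_constituent_average(self):
        a = env.MonthlySeries("a", "t", np.full(12, 2.0))
        b = env.MonthlySeries("b", "t", np.full(12, 4.0))
        comp = env.average_composite_series([a, b], "ab")
        assert np.allclose(comp.values, 3.0)
        with pytest.raises(ValueError):
            env.average_composite_series([a, env.MonthlySeries("b", "other", np.ones(12))], "ab")


class TestZScore:
    def test_one_two_three_maps_to_unit_scores(self):
        t = env.StabilityTable(pd.DataFrame({"temperature": [1.0, 2.0, 3.0]}))
        z = env.zscore(t)
        np.testing.assert_allclose(z.data["temperature"], [-1.0, 0.0, 1.0])
        assert z.scored
        assert z.column_stats.loc["temperature", "mean"] == 2.0

    def test_idempotent_to_tolerance(self, rng):
        t = env.StabilityTable(pd.DataFrame(rng.uniform(0, 5, size=(10, 3)), columns=list("abc")))
        z1 = env.zscore(t)
        z2 = env.zscore(z1)
        np.testing.assert_allclose(z1.data.to_numpy(), z2.data.to_numpy(), atol=1e-9)
        assert np.allclose(z2.data.mean(), 0.0, atol=1e-12)
        assert np.allclose(z2.data.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_rejected(self):
        t = env.StabilityTable(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]}))
        with pytest.raises(ValueError, match="zero-variance"):
            env.zscore(t)


class TestPruneCollinear:
    @staticmethod
    def correlated_table(rng, n=40):
        """Eight stability measures with the correlation structure seen in
        ocean climatologies: oxygen tied to temperature, nitrate to
        phosphate, AOU and oxygen saturation to each other and to the
        nutrients."""
        t = rng.normal(size=n)
        p = rng.normal(size=n)
        si = rng.normal(size=n)
        sal = rng.normal(size=n)
        aou = 0.8 * p + 0.8 * si + 0.3 * rng.normal(size=n)
        return pd.DataFrame(
            {
                "temperature": t,
                "salinity": sal,
                "dissolved_oxygen": 0.85 * t + 0.4 * rng.normal(size=n),
                "aou": aou,
                "oxygen_saturation": aou + 0.05 * rng.normal(size=n),
                "phosphate": p,
                "nitrate": 0.9 * p + 0.3 * rng.normal(size=n),
                "silicate": si,
            }
        )

    def test_retains_temperature_salinity_phosphate_silicate(self, rng):
        table = env.StabilityTable(self.correlated_table(rng))
        retained, report = env.prune_collinear(table)
        assert set(retained) == {"temperature", "salinity", "phosphate", "silicate"}
        assert {"parameter_a", "parameter_b", "rho", "p_value"} <= set(report.columns)
        assert len(report) == 8 * 7 // 2

    def test_duplicated_column_dropped_by_priority(self, rng):
        a = rng.normal(size=30)
        df = pd.DataFrame({"A": a, "B": a.copy(), "C": rng.normal(size=30)})
        retained, _ = env.prune_collinear(
            env.StabilityTable(df), priority=["A", "B", "C"]
        )
        assert retained == ["A", "C"]

    def test_result_independent_of_column_order(self, rng):
        df = self.correlated_table(rng)
        shuffled = df[list(df.columns[::-1])]
        r1, _ = env.prune_collinear(env.StabilityTable(df))
        r2, _ = env.prune_collinear(env.StabilityTable(shuffled))
        assert r1 == r2

    def test_independent_columns_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("wxyz"))
        retained, _ = env.prune_collinear(env.StabilityTable(df))
        assert set(retained) == set("wxyz")


class TestValidateInterpolation:
    def test_exact_line_gives_perfect_fit(self):
        x = np.linspace(0, 10, 12)
        pairs = pd.DataFrame({"measured": x, "interpolated": x},
                             index=[f"GS{i:03d}" for i in range(12)])
        rep = env.validate_interpolation(pairs, "temperature")
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.slope == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)

    def test_requires_three_complete_pairs(self):
        pairs = pd.DataFrame({"measured": [1.0, 2.0], "interpolated": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3"):
            env.validate_interpolation(pairs, "salinity")

    def test_exclusions_and_outlier_flagging(self):
        x = np.linspace(0, 10, 10)
        y = x.copy()
        y[3] += 8.0  # planted outlier
        pairs = pd.DataFrame({"measured": x, "interpolated": y},
                             index=[f"GS{i:03d}" for i in range(10)])
        rep = env.validate_interpolation(pairs, "t")
        assert rep.worst_site == "GS003"
        rep2 = env.validate_interpolation(pairs, "t", exclude=["GS003"])
        assert rep2.r_squared == pytest.approx(1.0)
        assert rep2.n == 9


class TestTypesAndIO:
    def test_site_invariants(self):
        with pytest.raises(ValueError):
            env.SampleSite("s", 95.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            env.SampleSite("s", 0.0, 0.0, -5.0)
        with pytest.raises(ValueError):
            env.SampleSite("s", 0.0, 0.0, 0.0, filter_min_um=0.8, filter_max_um=0.1)
        assert env.SampleSite("s", 0.0, 200.0, 0.0).longitude == -160.0
        assert env.SampleSite("s", 0.0, -180.0, 0.0).longitude == 180.0

    def test_grid_axis_and_shape_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            env.GriddedClimatology("t", "u", [1.0, 0.0], [0.0], [0.0], np.zeros((2, 1, 1, 12)))
        with pytest.raises(ValueError, match="shape"):
            env.GriddedClimatology("t", "u", [0.0], [0.0], [0.0], np.zeros((1, 1, 1, 11)))

    def test_climatology_roundtrip(self, tmp_path, rng):
        vals = rng.normal(size=(3, 2, 2, 12))
        vals[0, 0, 0, 0] = np.nan
        g = env.GriddedClimatology("phosphate", "umol/l", [0.0, 1, 2], [5.0, 6], [0.0, 10], vals)
        path = tmp_path / "phos.csv"
        env.write_climatology(g, path)
        back = env.read_climatology(path)
        assert back.parameter == "phosphate" and back.units == "umol/l"
        np.testing.assert_allclose(back.values, g.values, equal_nan=True)

    def test_sites_roundtrip(self, tmp_path):
        sites = [
            env.SampleSite("a", 1.0, 2.0, 3.0, "2004-01-02", "open ocean", 0.1, 0.8, 21.5, None),
            env.SampleSite("b", -1.0, -2.0, 0.0, "2005-06-07", "coastal water"),
        ]
        path = tmp_path / "sites.csv"
        env.write_sites(sites, path)
        back = env.read_sites(path)
        assert [s.sample_id for s in back] == ["a", "b"]
        assert back[0].insitu_temperature == 21.5
        assert back[1].insitu_salinity is None
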