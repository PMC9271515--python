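import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialaccess.access import (
    AccessSurface,
    CostMatrix,
    ImpedanceSpec,
    NationalSeries,
    NoWeighablePopulation,
    compute_national_series,
    compute_surface,
    compute_tai,
    local_dai,
    national_index,
    normalize_to_reference,
)
from trialaccess.grid import (
    GridPoint,
    IncidenceTable,
    KM_PER_DEG,
    PopulationGrid,
    SiteTable,
    TrialSite,
    ValidationError,
)

E = math.e

# closed-form evaluations of n_j / max(log s_i, 1) * max(d, floor)^(-beta)
LOCAL_DAI_CASES = [
    # n, d_km, patients, beta, floor, expected
    (4, 4.0, E**3, 0.5, 1.0, (4 / 3) * 0.5),
    (1, 1.0, E, 0.5, 1.0, 1.0),
    (3, 100.0, E**2, 0.0, 1.0, 1.5),          # beta=0: distance drops out
    (3, 0.001, E**2, 0.0, 1.0, 1.5),
    (2, 0.5, E**4, 0.5, 1.0, 0.5),            # below floor -> floored at 1 km
    (2, 1.0, E**4, 0.5, 1.0, 0.5),
    (5, 4.0, 0.5, 0.5, 1.0, 5 / 2),           # log clamp: s<=1 -> weight 1
    (5, 4.0, 0.0, 0.5, 1.0, 5 / 2),
    (5, 4.0, E, 1.0, 1.0, 5 / 4),             # beta=1 inverse-distance
    (2, 8.0, E**4, 0.5, 2.0, 2 / (4 * math.sqrt(8))),
    (6, 9.0, E**2, 0.5, 1.0, 1.0),
    (7, 16.0, E**0.5, 0.5, 1.0, 7 / 4),       # 0 < log s < 1 clamps to 1
]


class TestLocalDai:
    @pytest.mark.parametrize("n,d,s,beta,floor,expected", LOCAL_DAI_CASES)
    def test_hand_evaluations(self, n, d, s, beta, floor, expected):
        spec = ImpedanceSpec(beta=beta, distance_floor_km=floor)
        assert local_dai(n, d, s, spec) == pytest.approx(expected, rel=1e-12)

    def test_log_base_ten(self):
        spec = ImpedanceSpec(distance_floor_km=1.0, log_base=10.0)
        assert local_dai(3, 1.0, 100.0, spec) == pytest.approx(1.5, rel=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 50),
        d=st.floats(2.0, 5000.0),
        s=st.floats(3.0, 1e8),
        dn=st.integers(1, 10),
        dd=st.floats(1.0, 100.0),
        ds=st.floats(1.0, 100.0),
    )
    def test_monotonicity(self, n, d, s, dn, dd, ds):
        """More trials raise the value; distance and patient volume lower it."""
        spec = ImpedanceSpec(distance_floor_km=1.0)
        base = local_dai(n, d, s, spec)
        assert local_dai(n + dn, d, s, spec) > base
        assert local_dai(n, d + dd, s, spec) < base
        assert local_dai(n, d, s * (1 + ds), spec) <= base

    @given(st.floats(0.0, 10.0))
    def test_flooring_plateau(self, d):
        spec = ImpedanceSpec(distance_floor_km=10.0)
        assert local_dai(3, d, E**2, spec) == local_dai(3, 10.0, E**2, spec)

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            ImpedanceSpec(beta=-0.5)
        with pytest.raises(ValueError):
            ImpedanceSpec(distance_floor_km=0.0)
        with pytest.raises(ValidationError):
            local_dai(0, 1.0, E, ImpedanceSpec(distance_floor_km=1.0))


def _surface(values, weights, weighable=None):
    n = len(values)
    weighable = [True] * n if weighable is None else weighable
    return AccessSurface(
        pd.DataFrame(
            {
                "point_id": [f"p{i}" for i in range(n)],
                "lat": [0.0] * n,
                "lon": [float(i) for i in range(n)],
                "country": ["X"] * n,
                "population": [1000.0] * n,
                "patients": [10.0] * n,
                "local_value": values,
                "weight": weights,
                "weighable": weighable,
                "serving_site_id": ["s"] * n,
                "distance_km": [1.0] * n,
            }
        )
    )


class TestNationalIndex:
    def test_singleton_equals_local_value(self):
        assert national_index(_surface([2.5], [3.0])) == 2.5

    def test_equal_weights_is_plain_mean(self):
        assert national_index(_surface([1.0, 3.0], [2.0, 2.0])) == 2.0

    def test_weighted_mean(self):
        assert national_index(_surface([1.0, 3.0], [1.0, 3.0])) == pytest.approx(2.5)

    def test_containment_between_min_and_max(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.uniform(0, 5, size=8)
            w = rng.uniform(0.5, 4, size=8)
            nat = national_index(_surface(list(v), list(w)))
            assert v.min() - 1e-12 <= nat <= v.max() + 1e-12

    def test_all_points_excluded_raises(self):
        with pytest.raises(NoWeighablePopulation):
            national_index(_surface([1.0], [1.0], weighable=[False]))

    def test_all_zero_surface_aggregates_to_zero(self):
        assert national_index(_surface([0.0, 0.0], [1.0, 2.0])) == 0.0


class TestComputeSurface:
    def test_no_sites_gives_all_zero_values(self, toy_country, unit_spec):
        grid, _, incidence = toy_country
        surf = compute_surface(grid, [], incidence, unit_spec)
        assert (surf.local_values() == 0).all()
        assert national_index(surf) == 0.0

    def test_singleton_matches_local_dai(self, unit_spec):
        grid = PopulationGrid([GridPoint("a", 0, 0, 200_000, "X")])
        site = TrialSite("s", 0, 1.0, 2019, 4, "X")
        incidence = IncidenceTable({"X": 500.0})
        surf = compute_surface(grid, [site], incidence, unit_spec)
        expected = local_dai(4, KM_PER_DEG, 1000.0, unit_spec)
        assert surf.local_values()[0] == pytest.approx(expected, rel=1e-12)

    def test_distance_ratio_through_power_law(self):
        # equal patient volumes; d_B = 4 d_A = 4 floor => value(A)/value(B) = 2
        floor = 50.0
        spec = ImpedanceSpec(distance_floor_km=floor)
        deg = 1.0 / KM_PER_DEG
        grid = PopulationGrid(
            [
                GridPoint("A", 0, 50 * deg, 100_000, "X"),
                GridPoint("B", 0, 200 * deg, 100_000, "X"),
            ]
        )
        incidence = IncidenceTable({"X": 500.0})
        surf = compute_surface(grid, [TrialSite("s", 0, 0, 2019, 3, "X")], incidence, spec)
        vals = dict(zip(surf.frame["point_id"], surf.local_values()))
        assert vals["A"] / vals["B"] == pytest.approx(2.0, rel=1e-12)

    def test_missing_incidence_lists_countries(self, toy_country, unit_spec):
        grid, sites, _ = toy_country
        with pytest.raises(ValidationError, match="Toy"):
            compute_surface(grid, sites, IncidenceTable({"Other": 1.0}), unit_spec)

    def test_unpopulated_points_are_excluded_from_surface(self, unit_spec):
        grid = PopulationGrid(
            [GridPoint("a", 0, 0, 1000.0, "X"), GridPoint("z", 1, 1, 0.0, "X")]
        )
        surf = compute_surface(
            grid, [TrialSite("s", 0, 0, 2019, 1, "X")], IncidenceTable({"X": 500.0}), unit_spec
        )
        assert list(surf.frame["point_id"]) == ["a"]

    def test_within_country_restricts_supply(self, unit_spec):
        grid = PopulationGrid(
            [
                GridPoint("a", 0, 0, 100_000, "A"),
                GridPoint("b", 0, 1, 100_000, "B"),
            ]
        )
        incidence = IncidenceTable({"A": 500.0, "B": 500.0})
        sites = [TrialSite("sb", 0, 1, 2019, 5, "B")]
        cross = compute_surface(grid, sites, incidence, unit_spec)
        assert (cross.local_values() > 0).all()  # A is served across the border
        within = compute_surface(grid, sites, incidence, unit_spec, within_country=True)
        vals = dict(zip(within.frame["point_id"], within.local_values()))
        assert vals["a"] == 0.0 and vals["b"] > 0


class TestTai:
    def test_costs_equal_distances_reproduces_dai(self, toy_country, unit_spec):
        grid, sites, incidence = toy_country
        dai = compute_surface(grid, sites, incidence, unit_spec)
        costs = CostMatrix(
            {
                (r.point_id, s.id): float(r.distance_km)
                for r in dai.frame.itertuples(index=False)
                for s in sites
            }
        )
        tai = compute_tai(grid, sites, incidence, costs, unit_spec)
        np.testing.assert_allclose(tai.local_values(), dai.local_values(), rtol=1e-12)

    def test_scaled_costs_halve_the_index(self, unit_spec):
        # all costs 4x distance and beta=0.5 (floor not binding) -> tAI = dAI/2
        deg = 1.0 / KM_PER_DEG
        grid = PopulationGrid(
            [GridPoint("a", 0, 100 * deg, 200_000, "X"), GridPoint("b", 0, 400 * deg, 200_000, "X")]
        )
        incidence = IncidenceTable({"X": 500.0})
        sites = [TrialSite("s", 0, 0, 2019, 3, "X")]
        dai = compute_surface(grid, sites, incidence, unit_spec)
        costs = CostMatrix(
            {
                (r.point_id, "s"): 4.0 * float(r.distance_km)
                for r in dai.frame.itertuples(index=False)
            }
        )
        tai = compute_tai(grid, sites, incidence, costs, unit_spec)
        np.testing.assert_allclose(tai.local_values(), dai.local_values() / 2.0, rtol=1e-12)

    def test_cost_ranking_can_change_serving_site(self, unit_spec):
        grid = PopulationGrid([GridPoint("p", 0, 0, 200_000, "X")])
        incidence = IncidenceTable({"X": 500.0})
        near = TrialSite("near", 0, 0.5, 2019, 2, "X")
        far = TrialSite("far", 0, 2.0, 2019, 2, "X")
        dai = compute_surface(grid, [near, far], incidence, unit_spec)
        assert dai.frame["serving_site_id"][0] == "near"
        # congestion makes the nearer site costlier
        costs = CostMatrix({("p", "near"): 500.0, ("p", "far"): 300.0})
        tai = compute_tai(grid, [near, far], incidence, costs, unit_spec)
        assert tai.frame["serving_site_id"][0] == "far"

    def test_missing_pair_is_named(self, toy_country, unit_spec):
        grid, sites, incidence = toy_country
        with pytest.raises(ValidationError, match="'a'"):
            compute_tai(grid, sites, incidence, CostMatrix({}), unit_spec)


class TestNormalization:
    def test_reference_against_itself_is_100(self):
        s = NationalSeries("US", {2018: 2.0, 2019: 3.0})
        df = normalize_to_reference([s], "US")
        assert (df["pct_of_reference"] == 100.0).all()

    def test_half_the_reference_is_50(self):
        ref = NationalSeries("US", {2019: 4.0})
        other = NationalSeries("IT", {2019: 2.0})
        df = normalize_to_reference([ref, other], "US")
        assert df.set_index("country").loc["IT", "pct_of_reference"] == 50.0

    def test_window_ratio_equals_ratio_of_period_means(self):
        ref = NationalSeries("US", {2018: 2.0, 2019: 4.0})       # mean 3
        other = NationalSeries("IT", {2018: 1.0, 2019: 2.0})     # mean 1.5
        df = normalize_to_reference([ref, other], "US", window=(2018, 2019))
        assert df.set_index("country").loc["IT", "pct_of_reference"] == pytest.approx(50.0)

    def test_zero_reference_year_flagged_not_dropped(self):
        ref = NationalSeries("US", {2018: 0.0, 2019: 4.0})
        other = NationalSeries("IT", {2018: 1.0, 2019: 2.0})
        df = normalize_to_reference([ref, other], "US")
        row = df[(df["country"] == "IT") & (df["year"] == 2018)].iloc[0]
        assert not row["defined"] and math.isnan(row["pct_of_reference"])
        assert df[(df["country"] == "IT") & (df["year"] == 2019)].iloc[0]["defined"]


class TestNationalSeriesPipeline:
    def test_zero_supply_year_reported_as_zero(self, toy_country, unit_spec):
        grid, sites, incidence = toy_country
        series = compute_national_series(
            grid, SiteTable(sites), incidence, unit_spec, years=[2019, 2020]
        )
        assert series["Toy"].values[2019] > 0
        assert series["Toy"].values[2020] == 0.0
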