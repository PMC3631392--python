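import filecmp

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from nichecast.climate_derive import summarize_monthly
from nichecast.geo_io import ClimateStack, Grid
from nichecast.synthetic_data import (NicheParams, apply_scenario, default_design,
                                      make_climate, make_eoo, make_study_fixture,
                                      make_terrain, sample_species,
                                      true_suitability)


class TestTerrain:
    def test_same_seed_is_identical(self):
        a, b = make_terrain(5, 30, 30), make_terrain(5, 30, 30)
        np.testing.assert_array_equal(a.values, b.values)

    def test_elevation_range(self):
        dem = make_terrain(5, 30, 30)
        assert dem.values.min() >= 0 and dem.values.max() <= 2750

    def test_surface_is_spatially_smooth(self):
        dem = make_terrain(5, 50, 50)
        dx = np.abs(np.diff(dem.values, axis=1)).mean()
        dy = np.abs(np.diff(dem.values, axis=0)).mean()
        assert max(dx, dy) < (dem.values.max() - dem.values.min()) / 5


class TestClimate:
    def test_lapse_rate_exact_without_noise(self):
        dem = make_terrain(1, 20, 20)
        flat = dem.copy_with(np.zeros_like(dem.values))
        high = dem.copy_with(np.full_like(dem.values, 1000.0))
        mc_low = make_climate(flat, 2, lapse_rate=6.5, temp_noise_sd=0.0)
        mc_high = make_climate(high, 2, lapse_rate=6.5, temp_noise_sd=0.0)
        for lo_m, hi_m in zip(mc_low.temp, mc_high.temp):
            np.testing.assert_allclose(lo_m.values - hi_m.values, 6.5)

    def test_precipitation_is_positive(self):
        mc = make_climate(make_terrain(1, 20, 20), 2)
        assert all((g.values > 0).all() for g in mc.precip)

    def test_same_seed_is_identical(self):
        dem = make_terrain(1, 20, 20)
        a, b = make_climate(dem, 2), make_climate(dem, 2)
        for ga, gb in zip(a.temp + a.precip, b.temp + b.precip):
            np.testing.assert_array_equal(ga.values, gb.values)


class TestScenario:
    def test_two_degree_warming_is_exact(self):
        mc = make_climate(make_terrain(1, 15, 15), 2)
        fut = apply_scenario(mc, delta_t=2.0)
        for now, then in zip(mc.temp, fut.temp):
            np.testing.assert_allclose(then.values - now.values, 2.0)

    def test_identity_scenario(self):
        mc = make_climate(make_terrain(1, 15, 15), 2)
        fut = apply_scenario(mc, delta_t=0.0, precip_factor=1.0)
        for now, then in zip(mc.precip, fut.precip):
            np.testing.assert_array_equal(now.values, then.values)

    def test_precip_factor_scales_annual_total(self):
        mc = make_climate(make_terrain(1, 15, 15), 2)
        fut = apply_scenario(mc, delta_t=0.0, precip_factor=0.9)
        p_now = summarize_monthly(mc)["p_ann"].values
        p_fut = summarize_monthly(fut)["p_ann"].values
        np.testing.assert_allclose(p_fut, 0.9 * p_now)

    def test_negative_precip_factor_rejected(self):
        mc = make_climate(make_terrain(1, 15, 15), 2)
        with pytest.raises(ValueError):
            apply_scenario(mc, precip_factor=-0.1)


class TestTrueSuitability:
    def stack(self):
        v = Grid(np.array([[10.0, 13.0], [16.0, 19.0]]), 0, 0, 1.0)
        f = Grid(np.array([[100.0, 50.0], [0.0, 100.0]]), 0, 0, 1.0)
        return ClimateStack({"t_mean": v, "forest_pct": f})

    def test_maximum_at_the_optimum(self):
        niche = NicheParams({"t_mean": 10.0}, {"t_mean": 1.0},
                            forest_dependence=1.0, max_suitability=0.8)
        suit = true_suitability(self.stack(), niche)
        assert suit.values[0, 0] == pytest.approx(0.8)  # at optimum, full forest

    def test_three_tolerances_from_optimum(self):
        niche = NicheParams({"t_mean": 10.0}, {"t_mean": 1.0})
        suit = true_suitability(self.stack(), niche)
        assert suit.values[0, 1] == pytest.approx(np.exp(-4.5))

    def test_forest_independence(self):
        niche = NicheParams({"t_mean": 13.0}, {"t_mean": 5.0}, forest_dependence=0.0)
        suit = true_suitability(self.stack(), niche)
        # forest-free cell (1,0), t = 16: pure Gaussian response
        assert suit.values[1, 0] == pytest.approx(np.exp(-9.0 / 50.0))
        niche_f = NicheParams({"t_mean": 13.0}, {"t_mean": 5.0}, forest_dependence=1.0)
        suit_f = true_suitability(self.stack(), niche_f)
        assert suit_f.values[1, 0] == 0.0  # no forest at all

    def test_missing_covariate_is_an_error(self):
        with pytest.raises(KeyError):
            true_suitability(self.stack(), NicheParams({"p_ann": 1.0}, {"p_ann": 1.0}))


class TestSampleSpecies:
    def test_concentrated_mass_returns_that_cell(self):
        suit = Grid(np.zeros((5, 5)), 0, 0, 1.0)
        suit.values[3, 2] = 1.0
        occ = sample_species(suit, 1, seed=0)
        assert occ.presence_cells == [(3, 2)]

    def test_same_seed_is_identical(self):
        rng = np.random.default_rng(0)
        suit = Grid(rng.uniform(0, 1, (20, 20)), 0, 0, 1.0)
        a = sample_species(suit, 30, seed=4)
        b = sample_species(suit, 30, seed=4)
        assert a.presence_cells == b.presence_cells

    def test_sampling_tracks_suitability_ratio(self):
        vals = np.full((40, 40), 0.2)
        vals[:, :20] = 0.8
        suit = Grid(vals, 0, 0, 1.0)
        counts = np.zeros(2)
        n_rep, n_draw = 100, 5
        for rep in range(n_rep):
            occ = sample_species(suit, n_draw, seed=rep)
            for r, c in occ.presence_cells:
                counts[0 if c < 20 else 1] += 1
        p_high = 0.8 / (0.8 + 0.2)
        total = counts.sum()
        sigma = np.sqrt(total * p_high * (1 - p_high))
        assert abs(counts[0] - total * p_high) <= 3 * sigma

    def test_insufficient_positive_cells_rejected(self):
        suit = Grid(np.zeros((5, 5)), 0, 0, 1.0)
        suit.values[0, 0] = 1.0
        with pytest.raises(ValueError, match="positive suitability"):
            sample_species(suit, 2, seed=0)


class TestMakeEoo:
    def triangle_occ(self, grid):
        from nichecast.geo_io import resolve_occurrences
        cells = [(1, 1), (1, 8), (8, 4)]
        coords = [grid.cell_center(r, c) for r, c in cells]
        return resolve_occurrences("sp", coords, grid)

    def test_unbuffered_hull_is_the_triangle(self):
        grid = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        occ = self.triangle_occ(grid)
        poly = make_eoo(occ, 0, grid.cell_size).geoms[0]
        assert poly.area == pytest.approx(0.5 * 7 * 7)

    def test_buffer_strictly_grows_the_hull(self):
        grid = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        occ = self.triangle_occ(grid)
        small = make_eoo(occ, 0, grid.cell_size).geoms[0]
        big = make_eoo(occ, 2, grid.cell_size).geoms[0]
        assert big.area > small.area

    def test_all_records_inside_polygon(self):
        grid = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        occ = self.triangle_occ(grid)
        poly = make_eoo(occ, 1, grid.cell_size).geoms[0]
        assert all(poly.contains(Point(lon, lat)) for lon, lat in occ.records)

    def test_collinear_records_get_a_rectangle(self):
        grid = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        from nichecast.geo_io import resolve_occurrences
        coords = [grid.cell_center(2, c) for c in (1, 4, 7)]
        occ = resolve_occurrences("sp", coords, grid)
        poly = make_eoo(occ, 1, grid.cell_size).geoms[0]
        assert poly.area > 0


class TestStudyFixture:
    def test_default_design_species_bookkeeping(self, study):
        assert len(study.species) == 17                   # unique species
        assert len(study.design) == 18                    # design rows
        assert len(study.modeled_species()) == 9
        assert len(study.excluded_species()) == 8

    def test_record_counts_match_the_design(self, study):
        by_name = {}
        for _, row in study.design.iterrows():
            by_name[row["species"]] = by_name.get(row["species"], 0) + row["records"]
        for sp in study.species:
            assert sp.n_records == by_name[sp.name]

    def test_eoo_contains_and_exceeds_the_records(self, study):
        for sp in study.modeled_species():
            poly = sp.eoo.union()
            assert all(poly.contains(Point(lon, lat))
                       for lon, lat in sp.occurrences.records)

    def test_serialization_is_byte_identical_across_runs(self, tmp_path):
        design = pd.DataFrame({"species": ["a", "b"], "records": [6, 3]})
        fx1 = make_study_fixture(3, design=design, n_rows=24, n_cols=24)
        fx2 = make_study_fixture(3, design=design, n_rows=24, n_cols=24)
        d1, d2 = tmp_path / "one", tmp_path / "two"
        fx1.save(d1)
        fx2.save(d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []


def test_default_design_matches_packaged_counts():
    df = default_design()
    assert list(df["records"]) == [10, 5, 1, 14, 1, 7, 25, 18, 2, 13, 5, 11,
                                   2, 10, 7, 1, 3, 3]
    assert df["species"].nunique() == 17
    assert (df.groupby("species")["records"].max() >= 6).sum() == 9
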