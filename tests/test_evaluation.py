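import numpy as np
import pytest
from shapely.geometry import box

from nichecast.evaluation import (auc, compare_covariate_sets, crossval,
                                  draw_pseudo_presences, make_folds,
                                  pseudo_protocol, recovery_spearman,
                                  refine_eoo)
from nichecast.geo_io import Grid, OccurrenceSet, PolygonSet, resolve_occurrences
from nichecast.maxent_core import fit_maxent, predict
from nichecast.synthetic_data import (NicheParams, sample_species,
                                      true_suitability)


def brute_force_auc(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def occ_of_cells(cells, grid, species="sp"):
    coords = [grid.cell_center(r, c) for r, c in cells]
    return resolve_occurrences(species, coords, grid)


class TestFolds:
    def test_partition_is_balanced_disjoint_exhaustive(self, landscape):
        occ = occ_of_cells([(i, i) for i in range(8)], landscape["dem"])
        plan = make_folds(occ, 4, seed=1)
        sizes = np.bincount(plan.assignments, minlength=4)
        assert list(sizes) == [2, 2, 2, 2]
        for fold in range(4):
            train, test = plan.train_test(fold)
            assert len(train) == 6 and len(test) == 2
            assert set(train) | set(test) == set(range(8))

    def test_uneven_counts_differ_by_at_most_one(self, landscape):
        occ = occ_of_cells([(i, 2 * i) for i in range(7)], landscape["dem"])
        plan = make_folds(occ, 4, seed=1)
        assert sorted(np.bincount(plan.assignments, minlength=4)) == [1, 2, 2, 2]

    def test_same_seed_reproduces_assignments(self, landscape):
        occ = occ_of_cells([(i, i) for i in range(9)], landscape["dem"])
        a = make_folds(occ, 4, seed=5)
        b = make_folds(occ, 4, seed=5)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_too_few_presences_rejected(self, landscape):
        occ = occ_of_cells([(1, 1), (2, 2)], landscape["dem"])
        with pytest.raises(ValueError, match="folds"):
            make_folds(occ, 4)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_identical_lists_give_half(self):
        assert auc([0.3, 0.7], [0.3, 0.7]) == 0.5

    def test_hand_counted_example(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_agrees_with_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_p, n_n = rng.integers(1, 51, 2)
            pos = rng.choice([0.1, 0.25, 0.5, 0.8], n_p)  # ties likely
            neg = rng.uniform(0, 1, n_n)
            assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


class TestCrossval:
    def test_niche_signal_yields_high_auc(self, landscape):
        stack = landscape["stack"]
        tm = stack["t_mean"].values
        niche = NicheParams({"t_mean": float(np.quantile(tm, 0.6))},
                            {"t_mean": float(0.07 * tm.std())})
        suit = true_suitability(stack, niche)
        occ = sample_species(suit, 30, seed=5)
        res = crossval(occ, stack, make_folds(occ, 4, 7), seed=7)
        assert res.mean_auc > 0.9

    def test_uniform_random_species_scores_near_half(self, landscape):
        stack = landscape["stack"]
        dem = landscape["dem"]
        rng = np.random.default_rng(9)
        cells = rng.choice(dem.n_rows * dem.n_cols, 100, replace=False)
        occ = occ_of_cells([(i // dem.n_cols, i % dem.n_cols) for i in cells], dem)
        res = crossval(occ, stack, make_folds(occ, 4, 9), seed=9)
        assert 0.4 <= res.mean_auc <= 0.6

    def test_identical_inputs_reproduce_result(self, landscape):
        stack = landscape["stack"]
        occ = occ_of_cells([(i, 3 * i % 60) for i in range(10)], landscape["dem"])
        plan = make_folds(occ, 4, 2)
        a = crossval(occ, stack, plan, seed=2)
        b = crossval(occ, stack, plan, seed=2)
        assert a.fold_aucs == b.fold_aucs

    def test_fold_relabeling_leaves_auc_multiset_unchanged(self, landscape):
        stack = landscape["stack"]
        occ = occ_of_cells([(i, 3 * i % 60) for i in range(10)], landscape["dem"])
        plan = make_folds(occ, 4, 2)
        relabeled = type(plan)(plan.k, (plan.assignments + 1) % plan.k, plan.seed)
        a = crossval(occ, stack, plan, seed=2)
        b = crossval(occ, stack, relabeled, seed=2)
        assert sorted(a.fold_aucs) == pytest.approx(sorted(b.fold_aucs))


class TestCompareCovariateSets:
    def test_identical_stacks_give_zero_t(self, landscape):
        stack = landscape["stack"]
        dem = landscape["dem"]
        occ = {}
        plans = {}
        for j, name in enumerate(["s1", "s2", "s3"]):
            o = occ_of_cells([(5 * j + i, 2 * i + j) for i in range(8)], dem, name)
            occ[name] = o
            plans[name] = make_folds(o, 4, j)
        table, ttest = compare_covariate_sets(occ, stack, stack, plans, seed=1)
        assert ttest.statistic == 0.0
        assert (table["mean_auc_with"] == table["mean_auc_without"]).all()


class TestRefineEoo:
    def test_whole_grid_polygon_keeps_all_cells(self, landscape):
        dem = landscape["dem"]
        poly = PolygonSet("sp", [box(dem.x_origin - 1, dem.y_origin - 1,
                                     dem.x_origin + 10, dem.y_origin + 10)])
        mask = refine_eoo(poly, None, 0.0, (-np.inf, np.inf), dem)
        assert mask.values.sum() == (~dem.mask).sum()

    def test_impossible_forest_requirement_raises(self, landscape):
        dem = landscape["dem"]
        bare = dem.copy_with(np.zeros_like(dem.values))
        poly = PolygonSet("sp", [box(dem.x_origin, dem.y_origin,
                                     dem.x_origin + 10, dem.y_origin + 10)])
        with pytest.raises(ValueError, match="empty"):
            refine_eoo(poly, bare, 100.0, (-np.inf, np.inf), dem)

    def test_mask_matches_exhaustive_cell_check(self):
        rng = np.random.default_rng(1)
        dem = Grid(rng.uniform(0, 1000, (10, 10)), 0.0, 0.0, 1.0)
        poly = PolygonSet("sp", [box(0, 0, 5, 10)])  # left half
        lo, hi = 100.0, 800.0
        mask = refine_eoo(poly, None, 0.0, (lo, hi), dem)
        expected = 0
        for r in range(10):
            for c in range(10):
                lon, lat = dem.cell_center(r, c)
                if lon < 5 and lo <= dem.values[r, c] <= hi:
                    expected += 1
                    assert mask.values[r, c] == 1
        assert int(mask.values.sum()) == expected


class TestPseudoPresences:
    def test_single_cell_mask_returns_that_cell(self):
        dem = Grid(np.zeros((4, 4)), 0, 0, 1.0)
        m = np.zeros((4, 4))
        m[2, 3] = 1
        occ = draw_pseudo_presences(dem.copy_with(m), 1, seed=0)
        assert occ.presence_cells == [(2, 3)]

    def test_same_seed_reproduces_draw(self):
        dem = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        mask = dem.copy_with(np.ones((10, 10)))
        a = draw_pseudo_presences(mask, 20, seed=3)
        b = draw_pseudo_presences(mask, 20, seed=3)
        assert a.presence_cells == b.presence_cells

    def test_selection_frequencies_uniform_within_3_sigma(self):
        dem = Grid(np.zeros((10, 10)), 0, 0, 1.0)
        mask = dem.copy_with(np.ones((10, 10)))
        counts = np.zeros(100)
        n_rep, n_draw = 200, 5
        for rep in range(n_rep):
            occ = draw_pseudo_presences(mask, n_draw, seed=rep)
            for r, c in occ.presence_cells:
                counts[r * 10 + c] += 1
        p = n_draw / 100
        sigma = np.sqrt(n_rep * p * (1 - p))
        assert np.all(np.abs(counts - n_rep * p) <= 3 * sigma + 1)


class TestPseudoProtocol:
    def test_oversized_polygon_training_degrades_auc(self, landscape):
        stack = landscape["stack"]
        dem = landscape["dem"]
        tm = stack["t_mean"].values
        niche = NicheParams({"t_mean": float(np.quantile(tm, 0.5))},
                            {"t_mean": float(0.07 * tm.std())})
        suit = true_suitability(stack, niche)
        occ = sample_species(suit, 24, seed=11)
        real = crossval(occ, stack, make_folds(occ, 4, 11), seed=11)
        whole = PolygonSet("sp", [box(dem.x_origin, dem.y_origin,
                                      dem.x_origin + 10, dem.y_origin + 10)])
        mask = refine_eoo(whole, None, 0.0, (-np.inf, np.inf), dem)
        pseudo = draw_pseudo_presences(mask, occ.n_cells, seed=11)
        res = pseudo_protocol(occ, pseudo, stack, 4, seed=11)
        assert res.mean_auc < real.mean_auc

    def test_true_support_mask_recovers_real_performance(self, landscape):
        stack = landscape["stack"]
        tm = stack["t_mean"].values
        niche = NicheParams({"t_mean": float(np.quantile(tm, 0.5))},
                            {"t_mean": float(0.07 * tm.std())})
        suit = true_suitability(stack, niche)
        occ = sample_species(suit, 24, seed=12)
        real = crossval(occ, stack, make_folds(occ, 4, 12), seed=12)
        core = suit.copy_with((suit.values > 0.5).astype(float))
        pseudo = draw_pseudo_presences(core, occ.n_cells, seed=12)
        res = pseudo_protocol(occ, pseudo, stack, 4, seed=12)
        assert abs(res.mean_auc - real.mean_auc) < 0.1

    def test_uniform_pseudo_training_is_uninformative(self, landscape):
        stack = landscape["stack"]
        dem = landscape["dem"]
        tm = stack["t_mean"].values
        niche = NicheParams({"t_mean": float(np.quantile(tm, 0.5))},
                            {"t_mean": float(0.07 * tm.std())})
        occ = sample_species(true_suitability(stack, niche), 24, seed=13)
        everywhere = dem.copy_with(np.ones_like(dem.values))
        pseudo = draw_pseudo_presences(everywhere, occ.n_cells, seed=13)
        res = pseudo_protocol(occ, pseudo, stack, 4, seed=13)
        assert abs(res.mean_auc - 0.5) <= 0.15
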