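import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from iltcniche.errors import ParameterError, ValidationError
from iltcniche.spatial import (SpatialWeights, build_spatial_weights,
                               imbalance_index, morans_i,
                               morans_permutation, severity_correlation)

from _oracles import morans_i_direct


class TestSpatialWeights:
    def test_unit_square_k2_is_rook_adjacency(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        w = build_spatial_weights(coords, k=2)
        assert w.total == 8.0  # 4 spots x 2 side-neighbours, symmetric
        dense = w.w.toarray()
        assert dense[0, 3] == 0 and dense[1, 2] == 0  # no diagonals
        np.testing.assert_array_equal(dense, dense.T)
        assert np.all(np.diag(dense) == 0)

    def test_k_at_least_n_gives_complete_graph(self):
        coords = np.random.default_rng(0).uniform(0, 1, (5, 2))
        w = build_spatial_weights(coords, k=4)
        assert w.total == 5 * 4

    def test_duplicate_coordinates_tie_break_by_index(self):
        coords = np.zeros((4, 2))  # all identical: pure index ordering
        w = build_spatial_weights(coords, k=1)
        dense = w.w.toarray()
        # each spot picks the lowest-index other spot; union-symmetrised
        assert dense[1, 0] == 1 and dense[2, 0] == 1 and dense[3, 0] == 1
        assert dense[1, 2] == 0

    def test_too_few_spots_raises(self):
        with pytest.raises(ParameterError, match="reduce k"):
            build_spatial_weights(np.zeros((3, 2)), k=3)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        w = build_spatial_weights(coords, k=2)
        res = morans_i(np.array([1.0, -1.0, -1.0, 1.0]), w)
        assert res["I"] == pytest.approx(-1.0, abs=1e-12)

    def test_two_disconnected_blocks_is_plus_one(self):
        wb = sp.csr_matrix(np.kron(np.eye(2), np.ones((3, 3)) - np.eye(3)))
        w = SpatialWeights(np.arange(6), wb, k=2)
        res = morans_i(np.array([5.0, 5, 5, 9, 9, 9]), w)
        assert res["I"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_on_random_fields(self, rng):
        coords = rng.uniform(0, 5, (15, 2))
        w = build_spatial_weights(coords, k=3)
        x = rng.normal(size=15)
        assert morans_i(x, w)["I"] == pytest.approx(
            morans_i_direct(x, w.w.toarray()), abs=1e-10)

    def test_affine_invariance(self, rng):
        coords = rng.uniform(0, 5, (30, 2))
        w = build_spatial_weights(coords, k=4)
        x = rng.normal(size=30)
        assert morans_i(x, w)["I"] == pytest.approx(
            morans_i(-2.5 * x + 7, w)["I"], abs=1e-12)

    def test_constant_field_flagged_not_raised(self):
        coords = np.random.default_rng(0).uniform(0, 1, (10, 2))
        w = build_spatial_weights(coords, k=3)
        res = morans_i(np.ones(10), w)
        assert np.isnan(res["I"]) and res["flag"] == "constant_field"

    def test_permutation_mean_matches_null_expectation(self, rng):
        coords = rng.uniform(0, 10, (40, 2))
        w = build_spatial_weights(coords, k=6)
        x = rng.normal(size=40)
        vals = [morans_i(rng.permutation(x), w)["I"] for _ in range(1000)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (-1 / 39)) < 3 * se


class TestMoransPermutation:
    def test_observed_equal_to_null_gives_p_one(self):
        # a field whose permutations all produce the same I: two spots
        # swapped leaves I unchanged on a symmetric complete graph
        w = SpatialWeights(np.arange(4),
                           sp.csr_matrix(np.ones((4, 4)) - np.eye(4)), k=3)
        res = morans_permutation(np.array([1.0, 2, 3, 4]), w, n_perm=99,
                                 seed=0)
        assert res["p"] == pytest.approx(1.0)

    def test_seed_reproducible(self, rng):
        coords = rng.uniform(0, 5, (25, 2))
        w = build_spatial_weights(coords, k=4)
        x = rng.normal(size=25)
        a = morans_permutation(x, w, n_perm=199, seed=5)
        b = morans_permutation(x, w, n_perm=199, seed=5)
        assert a["p"] == b["p"]

    def test_constant_field_p_one(self):
        coords = np.random.default_rng(0).uniform(0, 1, (10, 2))
        w = build_spatial_weights(coords, k=3)
        res = morans_permutation(np.zeros(10), w, n_perm=99, seed=0)
        assert res["p"] == 1.0 and res["flag"] == "constant_field"

    def test_row_standardised_weights_also_calibrated(self, rng):
        # both weight modes give valid (conservative-at-worst) null p
        coords = rng.uniform(0, 10, (60, 2))
        for std in (False, True):
            w = build_spatial_weights(coords, k=6, row_standardise=std)
            hits = 0
            n_fields = 150
            for i in range(n_fields):
                x = rng.normal(size=60)
                if morans_permutation(x, w, 99, seed=i)["p"] <= 0.05:
                    hits += 1
            assert hits / n_fields < 0.12


class TestImbalanceIndex:
    def _summary(self, gdt, mait):
        rows = []
        for i, (g, m) in enumerate(zip(gdt, mait)):
            for layer, pg, pm in (("dermis", g, 0.0),
                                  ("epidermis", 0.0, m)):
                rows.append({"sample": f"D{i}", "layer": layer,
                             "group": "L", "pasi": 5.0 + i, "n_spots": 100,
                             "low_n": False, "pct_gdT": pg, "pct_MAIT": pm,
                             "pct_iNKT": 0.0})
        return pd.DataFrame(rows)

    def test_components_are_z_scored(self):
        out = imbalance_index(self._summary([1, 4, 7, 2], [3, 6, 9, 1]))
        for col in ("z_epid_MAIT", "z_derm_gdT"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_sample_has_maximal_index(self):
        out = imbalance_index(self._summary([9, 4, 1], [2, 5, 8]))
        # D2: min dermal gdT and max epidermal MAIT
        assert out.loc[out["index"].idxmax(), "sample"] == "D2"

    def test_swapping_components_negates_index(self):
        g, m = [1, 4, 7, 2], [3, 6, 9, 1]
        a = imbalance_index(self._summary(g, m))
        b = imbalance_index(self._summary(m, g))
        np.testing.assert_allclose(a["index"], -b["index"], atol=1e-9)

    def test_mean_sample_has_zero_index(self):
        out = imbalance_index(self._summary([1, 3, 5], [2, 4, 6]))
        assert out["index"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_component_raises(self):
        with pytest.raises(ValidationError, match="variance"):
            imbalance_index(self._summary([3, 3, 3], [1, 2, 3]))


class TestSeverityCorrelation:
    def test_strictly_increasing_gives_rho_one(self):
        out = severity_correlation([1, 2, 3, 4, 5], [2, 8, 9, 15, 30])
        assert out["rho"] == pytest.approx(1.0)

    def test_reversing_pasi_negates_rho(self, rng):
        x = rng.normal(size=10)
        p = rng.uniform(2, 30, 10)
        a = severity_correlation(x, p)
        b = severity_correlation(x, -p)
        assert a["rho"] == pytest.approx(-b["rho"])

    def test_small_n_reports_rho_without_p(self):
        out = severity_correlation([1, 2, 3], [3, 5, 9])
        assert out["rho"] == pytest.approx(1.0)
        assert np.isnan(out["p"]) and out["flag"] == "small_n"

    def test_missing_pasi_pairs_dropped(self):
        out = severity_correlation([1, 2, 3, 4, 5],
                                   [1, np.nan, 3, 4, 5])
        assert out["n"] == 4

    def test_null_p_values_calibrated(self, rng):
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            r = severity_correlation(rng.normal(size=12),
                                     rng.uniform(2, 30, 12))
            if r["p"] < 0.05:
                hits += 1
        assert 0.035 <= hits / n_sim <= 0.065
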