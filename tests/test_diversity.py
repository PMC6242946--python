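"""Diversity and structure statistics: Shannon index, epigenotype matching,
missing-tolerant distances, PCoA geometry, AMOVA variance components and
Mantel correlation, each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest

from epiclonal.diversity import (EARTH_RADIUS_KM, amova, epi_distance,
                                 geo_distance, mantel, match_epigenotypes,
                                 pcoa, shannon_index)


def frame(rows, index=None):
    return pd.DataFrame(np.asarray(rows, dtype=float),
                        index=index or [f"s{i}" for i in range(len(rows))])


class TestShannon:
    def test_half_frequency_is_ln2(self):
        per_locus, mean, sd = shannon_index(frame([[0], [1]]))
        assert per_locus.iloc[0] == pytest.approx(np.log(2))

    def test_monomorphic_is_zero(self):
        per_locus, _, _ = shannon_index(frame([[1], [1], [1]]))
        assert per_locus.iloc[0] == 0.0

    def test_quarter_frequency(self):
        # -(0.25 ln 0.25 + 0.75 ln 0.75) = 0.562335
        per_locus, _, _ = shannon_index(frame([[1], [0], [0], [0]]))
        assert per_locus.iloc[0] == pytest.approx(0.5623351, abs=1e-6)

    def test_missing_excluded_per_locus(self):
        per_locus, _, _ = shannon_index(frame([[1], [0], [np.nan], [np.nan]]))
        assert per_locus.iloc[0] == pytest.approx(np.log(2))

    def test_order_invariance(self, rng):
        X = frame(rng.integers(0, 2, (12, 8)))
        _, mean1, sd1 = shannon_index(X)
        _, mean2, sd2 = shannon_index(
            X.iloc[rng.permutation(12), rng.permutation(8)])
        assert mean1 == pytest.approx(mean2) and sd1 == pytest.approx(sd2)


class TestMatching:
    def test_identical_rows_match(self):
        g = match_epigenotypes(frame([[0, 1, 0], [0, 1, 0], [1, 1, 0]]))
        assert g.iloc[0] == g.iloc[1] != g.iloc[2]

    def test_missing_matches_anything(self):
        g = match_epigenotypes(frame([[0, 1, np.nan], [0, 1, 0]]))
        assert g.iloc[0] == g.iloc[1]

    def test_single_definite_difference_blocks_match(self):
        g = match_epigenotypes(frame([[0, 1, np.nan], [1, 1, 0]]))
        assert g.iloc[0] != g.iloc[1]


class TestEpiDistance:
    def test_identical_rows_zero(self):
        d = epi_distance(frame([[0, 1], [0, 1]]))
        assert d.iloc[0, 1] == 0.0

    def test_binary_squared_distance_is_mismatch_count(self):
        d = epi_distance(frame([[0, 0, 0, 0], [1, 1, 0, 0]]), squared=True)
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_missing_rescaling(self):
        """1 mismatch over 2 complete loci, 3 loci total -> 1 * 3/2 = 1.5."""
        d = epi_distance(frame([[0, 1, np.nan], [1, 1, 0]]), squared=True)
        assert d.iloc[0, 1] == pytest.approx(1.5)

    def test_pair_without_complete_loci_errors(self):
        with pytest.raises(ValueError, match="s1"):
            epi_distance(frame([[0, np.nan], [np.nan, 1]]))

    def test_sqrt_relation(self, rng):
        X = frame(rng.integers(0, 2, (6, 10)))
        np.testing.assert_allclose(epi_distance(X) ** 2,
                                   epi_distance(X, squared=True), atol=1e-12)


class TestGeoDistance:
    def test_zero_on_diagonal_and_symmetry(self):
        t = pd.DataFrame({"latitude": [50.0, 40.0], "longitude": [4.0, 15.0]})
        d = geo_distance(t)
        assert d.iloc[0, 0] == 0.0
        assert d.iloc[0, 1] == d.iloc[1, 0] > 0

    def test_one_degree_longitude_at_equator(self):
        t = pd.DataFrame({"latitude": [0.0, 0.0], "longitude": [0.0, 1.0]})
        expected = np.pi * EARTH_RADIUS_KM / 180  # 111.195 km
        assert geo_distance(t).iloc[0, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(111.19, abs=0.01)

    def test_coordinates_out_of_range(self):
        t = pd.DataFrame({"latitude": [95.0, 0.0], "longitude": [0.0, 0.0]})
        with pytest.raises(ValueError):
            geo_distance(t)


class TestPcoa:
    def test_collinear_points(self):
        D = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(D)
        assert res.coordinates.shape[1] == 1  # a line: one positive axis
        got = np.abs(np.diff(res.coordinates.iloc[:, 0]))
        np.testing.assert_allclose(got, [1.0, 1.0], atol=1e-10)

    def test_round_trip_from_plane_coordinates(self, rng):
        pts = rng.normal(size=(7, 2))
        D = pd.DataFrame(np.linalg.norm(pts[:, None] - pts[None], axis=2))
        res = pcoa(D)
        rec = res.coordinates.to_numpy()
        D2 = np.linalg.norm(rec[:, None] - rec[None], axis=2)
        np.testing.assert_allclose(D2, D.to_numpy(), atol=1e-8)

    def test_equidistant_points_give_equal_eigenvalues(self):
        n = 5
        D = pd.DataFrame(1.0 - np.eye(n))
        res = pcoa(D)
        ev = res.eigenvalues[:n - 1]
        np.testing.assert_allclose(ev, ev[0], atol=1e-10)

    def test_matches_scikit_bio(self, rng):
        import warnings
        from skbio.stats.ordination import pcoa as skbio_pcoa

        X = rng.integers(0, 2, (10, 12)).astype(float)
        D = pd.DataFrame(
            np.linalg.norm(X[:, None] - X[None], axis=2))
        ours = pcoa(D)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio_pcoa(D.to_numpy(), number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, :3]),
            np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-6)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0, 1], [2, 0]], dtype=float))


def brute_force_phi_st(X: np.ndarray, labels: np.ndarray):
    """Oracle: variance components from squared Euclidean distances computed
    longhand from coordinates (sums of squares about centroids)."""
    groups = sorted(set(labels))
    N = len(X)
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_within = 0.0
    for g in groups:
        sub = X[labels == g]
        ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = N - len(groups)
    s2_w = ss_within / df_within
    sizes = np.array([int((labels == g).sum()) for g in groups])
    n0 = (N - (sizes**2).sum() / N) / df_among
    s2_a = (ss_among / df_among - s2_w) / n0
    return s2_a / (s2_a + s2_w)


class TestAmova:
    def test_all_variance_among_groups(self):
        X = frame([[0, 0], [0, 0], [1, 1], [1, 1]])
        d2 = epi_distance(X, squared=True)
        res = amova(d2, pd.Series(["a", "a", "b", "b"], index=X.index),
                    n_perm=99, seed=1)
        assert res.phi_st == pytest.approx(1.0)

    def test_matches_coordinate_oracle_on_toy(self, rng):
        """Distance-based variance components equal the longhand
        coordinate-based computation to 1e-10 (6 samples, 2 groups)."""
        X = rng.integers(0, 2, (6, 8)).astype(float)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d2 = pd.DataFrame(((X[:, None] - X[None]) ** 2).sum(axis=2))
        res = amova(d2, pd.Series(labels), n_perm=9, seed=0)
        assert res.phi_st == pytest.approx(brute_force_phi_st(X, labels),
                                           abs=1e-10)

    def test_singleton_groups_dropped(self, rng):
        X = frame(rng.integers(0, 2, (7, 6)))
        labels = pd.Series(["a", "a", "a", "b", "b", "b", "c"],
                           index=X.index)
        res = amova(epi_distance(X, squared=True), labels, n_perm=9, seed=0)
        assert res.df_among == 1 and res.df_within == 4

    def test_p_value_floor(self, rng):
        X = frame(rng.integers(0, 2, (8, 6)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=X.index)
        res = amova(epi_distance(X, squared=True), labels, n_perm=99, seed=3)
        assert res.p_value >= 1 / 100

    def test_fewer_than_two_groups_rejected(self, rng):
        X = frame(rng.integers(0, 2, (4, 6)))
        with pytest.raises(ValueError):
            amova(epi_distance(X, squared=True),
                  pd.Series(["a"] * 3 + ["b"], index=X.index), n_perm=9)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        X = frame(rng.integers(0, 2, (8, 10)))
        d = epi_distance(X)
        res = mantel(d, d.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(res.r**2)

    def test_toy_matches_direct_formula(self):
        d1 = pd.DataFrame([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6],
                           [3, 5, 6, 0]], dtype=float)
        d2 = pd.DataFrame([[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 7],
                           [5, 4, 7, 0]], dtype=float)
        a = np.array([1, 2, 4, 3, 5, 6], dtype=float)  # lower triangles
        b = np.array([2, 1, 3, 5, 4, 7], dtype=float)
        expected = (np.corrcoef(a, b))[0, 1]
        res = mantel(d1, d2, n_perm=9, seed=0)
        assert res.r == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_bio_r(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        X = rng.integers(0, 2, (9, 10)).astype(float)
        Y = rng.normal(size=(9, 2))
        d1 = pd.DataFrame(np.linalg.norm(X[:, None] - X[None], axis=2))
        d2 = pd.DataFrame(np.linalg.norm(Y[:, None] - Y[None], axis=2))
        ours = mantel(d1, d2, n_perm=9, seed=0)
        ref_r, _, _ = skbio_mantel(DistanceMatrix(d1.to_numpy()),
                                   DistanceMatrix(d2.to_numpy()),
                                   permutations=0)
        assert ours.r == pytest.approx(ref_r, abs=1e-12)

    def test_id_mismatch_rejected(self, rng):
        X = frame(rng.integers(0, 2, (4, 5)))
        d1 = epi_distance(X)
        d2 = d1.copy()
        d2.index = d2.columns = list("abcd")
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestNullBehaviour:
    def test_phi_st_near_zero_for_shuffled_labels(self, rng):
        """Identical group composition: Phi_ST fluctuates around 0."""
        X = frame(rng.integers(0, 2, (30, 20)))
        labels = pd.Series(np.repeat(["a", "b", "c"], 10), index=X.index)
        vals = []
        for s in range(30):
            perm = np.random.default_rng(s).permutation(30)
            res = amova(epi_distance(X, squared=True),
                        pd.Series(labels.to_numpy()[perm], index=X.index),
                        n_perm=9, seed=s)
            vals.append(res.phi_st)
        assert abs(np.mean(vals)) < 0.02
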