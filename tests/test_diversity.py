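import numpy as np
import pandas as pd
import pytest
import skbio
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecoassembly.datasets import CommunityTable
from ecoassembly.diversity import (
    alpha_diversity,
    bray_curtis,
    dispersion_homogeneity,
    distance_decay,
    geographic_distance,
    hellinger,
    pcoa,
    permanova,
    temporal_distance,
)
from ecoassembly.exceptions import DataValidationError, ParameterError

from .conftest import make_meta
from .oracles import brute_force_permanova_ss, normal_equation_ols


def table_of(rows, otus=None):
    rows = np.atleast_2d(rows)
    otus = otus or [f"o{j}" for j in range(rows.shape[1])]
    return CommunityTable(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=otus)
    )


class TestAlpha:
    def test_uniform_four(self):
        out = alpha_diversity(table_of([10, 10, 10, 10]))
        assert out.loc["s0", "richness"] == 4
        assert out.loc["s0", "shannon"] == pytest.approx(np.log(4), abs=1e-12)

    def test_single_otu(self):
        out = alpha_diversity(table_of([42, 0, 0]))
        assert out.loc["s0", "richness"] == 1
        assert out.loc["s0", "shannon"] == 0.0

    def test_mixed_counts(self):
        out = alpha_diversity(table_of([1, 1, 2]))
        assert out.loc["s0", "shannon"] == pytest.approx(1.0397, abs=1e-4)

    def test_zero_sum_named(self):
        with pytest.raises(DataValidationError, match="s1"):
            alpha_diversity(table_of([[1, 2], [0, 0]]))


class TestHellinger:
    def test_examples(self):
        out = hellinger(table_of([[4, 0], [1, 1]]))
        assert out.loc["s0"].tolist() == [1.0, 0.0]
        assert out.loc["s1", "o0"] == pytest.approx(0.70711, abs=1e-5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.int64, (4, 6), elements=st.integers(0, 50)))
    def test_rows_have_unit_sum_of_squares(self, counts):
        counts[counts.sum(axis=1) == 0, 0] = 1
        out = hellinger(table_of(counts))
        assert np.allclose((out**2).sum(axis=1), 1.0, atol=1e-12)


class TestBrayCurtis:
    def test_examples(self):
        dm = bray_curtis(table_of([[5, 0], [5, 0], [0, 5], [6, 2]], otus=["x", "y"]))
        assert dm["s0", "s1"] == 0.0
        assert dm["s0", "s2"] == 1.0
        dm2 = bray_curtis(table_of([[6, 2, 0], [2, 2, 4]]))
        assert dm2["s0", "s1"] == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(arrays(np.int64, (5, 7), elements=st.integers(0, 40)))
    def test_range_symmetry_zero_diagonal(self, counts):
        counts[counts.sum(axis=1) == 0, 0] = 1
        dm = bray_curtis(table_of(counts))
        assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)


class TestPCoA:
    def test_equilateral_triangle(self):
        dm = skbio.DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(dm)
        ev = res.eigvals.to_numpy()
        assert ev[0] == pytest.approx(ev[1], abs=1e-9)
        assert abs(ev[2]) < 1e-9

    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(skbio.DistanceMatrix(d, ids=list("abcd")))
        ev = res.eigvals.to_numpy()
        assert (ev[1:] < 1e-9).all()
        coords = res.samples.iloc[:, 0].to_numpy()
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0, 0], [0, 0], [3, 4], [6, 0]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(skbio.DistanceMatrix(d, ids=list("abcd")))
        assert np.allclose(res.samples.iloc[0], res.samples.iloc[1], atol=1e-9)


class TestPermanova:
    def euclid_dm(self, pts):
        pts = np.asarray(pts, dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(len(pts))])

    def test_perfect_separation(self):
        # near-identical within-group points, groups far apart; tiny jitter
        # keeps the maximum F unique so the permutation p attains its floor
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(scale=1e-6, size=(8, 2)),
                         rng.normal(loc=[100, 0], scale=1e-6, size=(8, 2))])
        res = permanova(self.euclid_dm(pts), ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0)
        assert res.R2 == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1 / 200, abs=1e-12)

    def test_r2_matches_euclidean_ss_decomposition(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        res = permanova(self.euclid_dm(pts), groups, n_perm=99, seed=0)
        ss_t, ss_w = brute_force_permanova_ss(pts, groups)
        assert res.R2 == pytest.approx((ss_t - ss_w) / ss_t, abs=1e-10)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        dm = self.euclid_dm(pts)
        mine = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(dm, grouping=list(groups), permutations=99)
        assert mine.F == pytest.approx(float(ref["test statistic"]), rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ParameterError):
            permanova(self.euclid_dm([[0], [1], [2]]), ["a", "a", "a"])


class TestDispersion:
    def euclid_dm(self, pts):
        pts = np.asarray(pts, dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(len(pts))])

    def test_mirrored_clouds_not_different(self):
        cloud = np.random.default_rng(1).normal(size=(8, 2))
        pts = np.vstack([cloud, cloud + [50, 0]])
        res = dispersion_homogeneity(
            self.euclid_dm(pts), ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0
        )
        assert res.p_value > 0.5
        assert res.group_mean_distance["a"] == pytest.approx(res.group_mean_distance["b"], rel=1e-6)

    def test_tight_vs_spread_detected(self):
        rng = np.random.default_rng(2)
        tight = np.zeros((8, 2))
        spread = rng.normal(scale=10.0, size=(8, 2))
        res = dispersion_homogeneity(
            self.euclid_dm(np.vstack([tight, spread])), ["a"] * 8 + ["b"] * 8,
            n_perm=199, seed=0,
        )
        assert res.p_value < 0.05

    def test_single_sample_group_rejected(self):
        with pytest.raises(ParameterError):
            dispersion_homogeneity(self.euclid_dm([[0], [1], [2]]), ["a", "b", "b"])


class TestGeographicTemporal:
    def test_haversine_values(self):
        meta = make_meta(["L1"], [2017], ["A", "B"])
        meta.data.loc[:, ["latitude", "longitude"]] = [[0.0, 0.0], [1.0, 0.0]]
        dm = geographic_distance(meta)
        assert dm.data[0, 1] == pytest.approx(111.19, abs=0.01)
        assert dm.data[0, 0] == 0.0

    def test_symmetry_random_coordinates(self):
        meta = make_meta(["L1", "L2"], [2017, 2019], ["A", "B"])
        rng = np.random.default_rng(0)
        meta.data["latitude"] = rng.uniform(-80, 80, len(meta.data))
        meta.data["longitude"] = rng.uniform(-170, 170, len(meta.data))
        dm = geographic_distance(meta)
        assert np.allclose(dm.data, dm.data.T)

    def test_temporal_days(self):
        meta = make_meta(["L1"], [2017, 2019], ["A"])
        dm = temporal_distance(meta)
        assert dm.data[0, 1] == pytest.approx(730, abs=1)  # 2 years


class TestDistanceDecay:
    def random_dm(self, values, ids):
        return skbio.DistanceMatrix(values, ids=ids)

    def test_constant_dissimilarity_flat(self):
        ids = list("abcd")
        comm = np.full((4, 4), 0.5)
        np.fill_diagonal(comm, 0)
        pred = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        fit = distance_decay(self.random_dm(comm, ids), self.random_dm(pred, ids), n_perm=99)
        assert fit.slope == 0.0
        assert fit.R2 == 0.0

    def test_exact_linear_relation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.5])
        pred = np.abs(x[:, None] - x[None, :])
        comm = 0.1 + 0.05 * pred
        np.fill_diagonal(comm, 0)
        ids = list("abcde")
        fit = distance_decay(self.random_dm(comm, ids), self.random_dm(pred, ids),
                             n_perm=199, seed=1)
        assert fit.R2 == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(0.05, abs=1e-10)
        # two-sided test: an order-reversing permutation ties |r| = 1, so the
        # attainable floor is (1 + n_reversals) / (n_perm + 1)
        assert fit.p_value <= 2 / 200

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        n = 6
        pred = np.zeros((n, n))
        comm = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        pred[iu] = rng.uniform(0, 10, len(iu[0]))
        comm[iu] = rng.uniform(0, 1, len(iu[0]))
        pred += pred.T
        comm += comm.T
        ids = [f"s{i}" for i in range(n)]
        fit = distance_decay(self.random_dm(comm, ids), self.random_dm(pred, ids), n_perm=99)
        slope, intercept = normal_equation_ols(pred[iu], comm[iu])
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        ids = list("ab")
        one = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ParameterError):
            distance_decay(self.random_dm(one, ids), self.random_dm(one, ids))
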