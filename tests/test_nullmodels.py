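import numpy as np
import pandas as pd
import pytest

from ecoassembly.datasets import CommunityTable, read_newick
from ecoassembly.exceptions import ParameterError
from ecoassembly.nullmodels import (
    beta_mntd,
    beta_nti,
    classify_process,
    cophenetic_matrix,
    raup_crick_bray,
)
from ecoassembly.simulate import radiation_tree, simulate_tree

from .oracles import brute_force_beta_mntd


def table_from(rows, samples, otus):
    return CommunityTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestBetaMNTD:
    def test_identical_communities_zero(self, four_tip_tree):
        tab = table_from([[5, 5, 0, 0], [5, 5, 0, 0]], ["k", "m"], list("ABCD"))
        dm = beta_mntd(tab, four_tip_tree)
        assert dm["k", "m"] == pytest.approx(0.0, abs=1e-12)

    def test_single_tip_pair_equals_cophenetic(self, four_tip_tree):
        tab = table_from([[7, 0, 0, 0], [0, 0, 9, 0]], ["k", "m"], list("ABCD"))
        dm = beta_mntd(tab, four_tip_tree)
        assert dm["k", "m"] == pytest.approx(3.0, abs=1e-12)  # A-C path length

    def test_three_tip_mixed_weights_vs_oracle(self):
        tree = read_newick("((A:1,B:2):0.5,C:3);")
        tab = table_from([[5, 5, 0], [0, 0, 10]], ["k", "m"], list("ABC"))
        dist = cophenetic_matrix(tree, list("ABC"))
        expected = brute_force_beta_mntd([5, 5, 0], [0, 0, 10], dist)
        dm = beta_mntd(tab, tree)
        assert dm["k", "m"] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_instances(self, weighted):
        rng = np.random.default_rng(12)
        for rep in range(10):
            n_tips = int(rng.integers(4, 13))
            n_samples = int(rng.integers(2, 7))
            tree = simulate_tree(n_tips, seed=rep)
            otus = [t.name for t in tree.tips()]
            counts = rng.integers(0, 6, size=(n_samples, n_tips))
            counts[counts.sum(axis=1) == 0, 0] = 1
            tab = table_from(counts, [f"s{i}" for i in range(n_samples)], otus)
            dm = beta_mntd(tab, tree, weighted=weighted)
            dist = cophenetic_matrix(tree, otus)
            for i in range(n_samples):
                for j in range(i + 1, n_samples):
                    expected = brute_force_beta_mntd(counts[i], counts[j], dist, weighted)
                    assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_branch_scaling_linearity_and_nti_invariance(self):
        tree = simulate_tree(10, seed=3)
        otus = [t.name for t in tree.tips()]
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 5, size=(4, 10))
        counts[counts.sum(axis=1) == 0, 0] = 1
        tab = table_from(counts, list("wxyz"), otus)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 3.0
        dm1, dm2 = beta_mntd(tab, tree), beta_mntd(tab, scaled)
        assert np.allclose(dm2.data, 3.0 * dm1.data, atol=1e-10)
        b1 = beta_nti(tab, tree, n_null=99, seed=9)
        b2 = beta_nti(tab, scaled, n_null=99, seed=9)
        ok = ~b1.degenerate
        assert np.allclose(b1.beta_nti[ok], b2.beta_nti[ok], atol=1e-8)


class TestBetaNTI:
    def test_identical_pair_degenerate(self, four_tip_tree):
        tab = table_from(
            [[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 3, 7]], ["k", "m", "z"], list("ABCD")
        )
        df = beta_nti(tab, four_tip_tree, n_null=99, seed=0)
        row = df[(df.sample_i == "k") & (df.sample_j == "m")].iloc[0]
        assert row.degenerate
        assert np.isnan(row.beta_nti)

    def test_clustered_communities_negative_on_average(self):
        # All communities are sparse subsets of the same two tight clades of
        # a radiation tree: taxa exchanged between samples are close
        # relatives, so observed betaMNTD sits far below the tip-shuffle null.
        tree = radiation_tree(60, seed=4, clade_size=5)
        otus = [t.name for t in tree.tips()]
        clades = [[t.name for t in stem.tips()] for stem in tree.children]
        superset = [otus.index(o) for o in clades[0] + clades[1]]
        rng = np.random.default_rng(0)
        rows = np.zeros((9, 60), dtype=int)
        for s in range(6):
            idx = rng.choice(superset, size=6, replace=False)
            rows[s, idx] = rng.integers(1, 20, size=6)
        # background samples scattered across all clades keep the pooled
        # taxon set (the null's relabeling space) spanning the whole tree
        for s in range(6, 9):
            rows[s, rng.choice(60, size=30, replace=False)] = 1
        tab = table_from(rows, [f"s{i}" for i in range(9)], otus)
        df = beta_nti(tab, tree, n_null=199, seed=1)
        focal = df[
            df.sample_i.str[1].astype(int).lt(6) & df.sample_j.str[1].astype(int).lt(6)
        ]
        assert focal.beta_nti.mean() < -0.5

    def test_n_null_validation(self, four_tip_tree, tiny_table):
        with pytest.raises(ParameterError):
            beta_nti(tiny_table, four_tip_tree, n_null=10)


class TestRaupCrick:
    def test_identical_communities_strongly_negative(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 30, size=40)
        base[0] = 5
        rows = np.vstack([base, base] + [rng.integers(0, 30, size=40) for _ in range(4)])
        rows[rows.sum(axis=1) == 0, 0] = 1
        tab = table_from(rows, [f"s{i}" for i in range(6)], [f"o{j}" for j in range(40)])
        df = raup_crick_bray(tab, n_null=999, seed=0)
        row = df[(df.sample_i == "s0") & (df.sample_j == "s1")].iloc[0]
        assert row.rc_bray <= -0.99

    def test_range_and_symmetry_under_reordering(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 12, size=(8, 25))
        rows[rows.sum(axis=1) == 0, 0] = 1
        ids = [f"s{i}" for i in range(8)]
        otus = [f"o{j}" for j in range(25)]
        tab = table_from(rows, ids, otus)
        df = raup_crick_bray(tab, n_null=199, seed=5)
        assert df.rc_bray.between(-1, 1).all()
        # reversing sample order must give identical per-pair values
        rev = table_from(rows[::-1], ids[::-1], otus)
        df2 = raup_crick_bray(rev, n_null=199, seed=5)
        key = lambda d: d.assign(
            pair=[tuple(sorted(p)) for p in zip(d.sample_i, d.sample_j)]
        ).set_index("pair")["rc_bray"].sort_index()
        pd.testing.assert_series_equal(key(df), key(df2), atol=1e-12, rtol=0)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-2.5, 0.0, "homogeneous_selection"),
            (2.5, 0.0, "variable_selection"),
            (0.5, 0.97, "dispersal_limitation"),
            (0.5, -0.99, "homogenizing_dispersal"),
            (0.5, 0.2, "drift"),
            # strict boundaries: exactly +-2 is stochastic, exactly +-0.95 is drift
            (2.0, 0.0, "drift"),
            (-2.0, 0.0, "drift"),
            (0.0, 0.95, "drift"),
            (0.0, -0.95, "drift"),
            (np.nan, 0.5, "undetermined"),
        ],
    )
    def test_thresholds(self, bnti, rc, expected):
        assert classify_process([bnti], [rc])[0] == expected

    def test_degenerate_flag_overrides(self):
        out = classify_process([3.0], [0.0], degenerate=[True])
        assert out[0] == "undetermined"

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            classify_process([1.0, 2.0], [0.0])
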