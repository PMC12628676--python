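import numpy as np
import pandas as pd
import pytest

from ecoassembly.coremicro import core_members, core_overlap, spatial_core, temporal_core
from ecoassembly.datasets import CommunityTable
from ecoassembly.exceptions import DataValidationError, ParameterError

from .conftest import make_meta


def table_of(rows, samples, otus):
    return CommunityTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestCoreMembers:
    def test_ubiquitous_and_patchy(self):
        # 'everywhere' is >0.1% in all 4 samples; 'patchy' only in 2 (50% < 75%)
        rows = [[500, 500, 0], [500, 500, 0], [500, 0, 500], [500, 0, 500]]
        tab = table_of(rows, list("abcd"), ["everywhere", "patchy", "other"])
        core = core_members(tab, prevalence=0.75, detection=0.001)
        assert core.otu_ids == ["everywhere"]
        assert core.core_richness == 1

    def test_detection_is_strict_greater(self):
        # exactly 0.1% must NOT count as present
        rows = [[1, 999]] * 4
        tab = table_of(rows, list("abcd"), ["edge", "bulk"])
        core = core_members(tab, prevalence=0.75, detection=0.001)
        assert "edge" not in core.otu_ids

    def test_matches_exhaustive_evaluation_on_toy(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 200, size=(8, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        otus = [f"o{j}" for j in range(5)]
        tab = table_of(counts, [f"s{i}" for i in range(8)], otus)
        rel = counts / counts.sum(axis=1, keepdims=True)
        expected = [o for j, o in enumerate(otus) if (rel[:, j] > 0.01).mean() >= 0.5]
        core = core_members(tab, prevalence=0.5, detection=0.01)
        assert core.otu_ids == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, size=(10, 12))
        counts[counts.sum(axis=1) == 0, 0] = 1
        tab = table_of(counts, [f"s{i}" for i in range(10)], [f"o{j}" for j in range(12)])
        base = set(core_members(tab, 0.5, 0.005).otu_ids)
        assert set(core_members(tab, 0.8, 0.005).otu_ids) <= base
        assert set(core_members(tab, 0.5, 0.02).otu_ids) <= base

    def test_threshold_validation(self):
        tab = table_of([[1]], ["a"], ["o"])
        with pytest.raises(ParameterError):
            core_members(tab, prevalence=0.0)
        with pytest.raises(ParameterError):
            core_members(tab, prevalence=0.75, detection=1.0)


class TestSpatialTemporalCores:
    def build(self, n_lakes=4, years=(2017, 2019)):
        meta = make_meta([f"L{i+1}" for i in range(n_lakes)], list(years), ["A", "B"])
        ids = list(meta.data.index)
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 100, size=(len(ids), 6))
        otus = [f"o{j}" for j in range(6)]
        return meta, ids, counts, otus

    def test_everywhere_is_member_restricted_is_not(self):
        meta, ids, counts, otus = self.build()
        # o0 abundant everywhere; o5 only in lake L1
        counts[:, 5] = 0
        for i, sid in enumerate(ids):
            if sid.startswith("L1-"):
                counts[i, 5] = 80
        tab = table_of(counts, ids, otus)
        core = spatial_core(tab, meta, 2017)
        assert "o0" in core.otu_ids
        assert "o5" not in core.otu_ids  # 1 of 4 lakes < 75%
        assert core.n_units == 4

    def test_fraction_below_prevalence_excluded(self):
        meta, ids, counts, otus = self.build(n_lakes=11, years=(2017,))
        counts[:, 3] = 0
        for i, sid in enumerate(ids):  # present in 5 of 11 lakes only
            if any(sid.startswith(f"L{k}-") for k in (1, 2, 3, 4, 5)):
                counts[i, 3] = 70
        tab = table_of(counts, ids, otus)
        core = spatial_core(tab, meta, 2017)
        assert "o3" not in core.otu_ids

    def test_single_lake_year_degenerates_to_presence(self):
        meta, ids, counts, otus = self.build(n_lakes=1, years=(2017,))
        tab = table_of(counts, ids, otus)
        core = spatial_core(tab, meta, 2017)
        rel = tab.relative_abundance()
        present = set(rel.columns[(rel > 0.001).any(axis=0)])
        assert set(core.otu_ids) == present

    def test_temporal_two_of_four_years_excluded(self):
        meta, ids, counts, otus = self.build(n_lakes=2, years=(2017, 2019, 2021, 2023))
        counts[:, 2] = 0
        for i, sid in enumerate(ids):  # o2 only in 2017 and 2019 for L1
            if sid.startswith("L1-2017") or sid.startswith("L1-2019"):
                counts[i, 2] = 60
        tab = table_of(counts, ids, otus)
        core = temporal_core(tab, meta, "L1")
        assert "o2" not in core.otu_ids
        assert core.n_units == 4

    def test_summary_fields_contract(self):
        meta, ids, counts, otus = self.build()
        tab = table_of(counts, ids, otus)
        core = temporal_core(tab, meta, "L1")
        assert 0 <= core.cumulative_abundance_mean <= 1
        assert core.cumulative_abundance_sd >= 0
        assert core.scope == "temporal:L1"

    def test_unknown_unit_rejected(self):
        meta, ids, counts, otus = self.build()
        tab = table_of(counts, ids, otus)
        with pytest.raises(ParameterError):
            spatial_core(tab, meta, 1999)
        with pytest.raises(ParameterError):
            temporal_core(tab, meta, "Lx")


class TestOverlap:
    def make_core(self, otus):
        c = core_members(
            table_of([[10] * max(len(otus), 1)], ["s"], otus or ["placeholder"]), 0.5, 0.0
        )
        c.otu_ids = list(otus)
        return c

    def test_jaccard_values(self):
        a = self.make_core(["a", "b", "c"])
        assert core_overlap(a, self.make_core(["a", "b", "c"]))["jaccard"] == 1.0
        assert core_overlap(a, self.make_core(["x", "y"]))["jaccard"] == 0.0
        out = core_overlap(a, self.make_core(["b", "c", "d"]))
        assert out["jaccard"] == 0.5
        assert out["shared_ids"] == ["b", "c"]

    def test_both_empty_rejected(self):
        with pytest.raises(DataValidationError):
            core_overlap(self.make_core([]), self.make_core([]))
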