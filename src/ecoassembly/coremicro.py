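"""Core microbiome extraction: overall, spatial (per year, across lakes) and
temporal (per lake, across years) cores.

An OTU is "present" in a unit when its relative abundance exceeds the
detection threshold (strict ``>``, default 0.1%), and belongs to the core
when present in at least the prevalence fraction of units (``>=``, default
75%).  For the spatial core the units are the ecosystems sampled in a given
year; for the temporal core the years a given ecosystem was sampled.
Replicates are collapsed to unit-level presence with "any replicate above
detection" by default ("mean" averages replicate relative abundances first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import CommunityTable, SampleFrame
from .exceptions import DataValidationError, ParameterError

__all__ = ["CoreSet", "core_members", "spatial_core", "temporal_core", "core_overlap"]


@dataclass
class CoreSet:
    scope: str  # "overall", "spatial:<year>", "temporal:<ecosystem>"
    otu_ids: list
    prevalence_threshold: float
    detection_threshold: float
    n_units: int
    cumulative_abundance_mean: float
    cumulative_abundance_sd: float

    @property
    def core_richness(self) -> int:
        return len(self.otu_ids)


def _check_thresholds(prevalence: float, detection: float) -> None:
    if not 0 < prevalence <= 1:
        raise ParameterError(f"prevalence must be in (0, 1], got {prevalence}")
    if not 0 <= detection < 1:
        raise ParameterError(f"detection must be in [0, 1), got {detection}")


def _core_from_presence(
    presence: pd.DataFrame, rel_units: pd.DataFrame, scope: str, prevalence: float, detection: float
) -> CoreSet:
    """Membership from a units x OTUs presence frame; abundance summarized
    over the same units' relative abundances."""
    frac = presence.mean(axis=0)
    members = list(frac.index[frac >= prevalence])
    cum = rel_units[members].sum(axis=1) if members else pd.Series(0.0, index=rel_units.index)
    sd = float(cum.std(ddof=1)) if len(cum) > 1 else 0.0
    return CoreSet(
        scope=scope,
        otu_ids=members,
        prevalence_threshold=prevalence,
        detection_threshold=detection,
        n_units=presence.shape[0],
        cumulative_abundance_mean=float(cum.mean()),
        cumulative_abundance_sd=sd,
    )


def core_members(
    table: CommunityTable, prevalence: float = 0.75, detection: float = 0.001
) -> CoreSet:
    """Overall core: OTUs above detection in >= ``prevalence`` of samples."""
    _check_thresholds(prevalence, detection)
    if table.data.size == 0:
        raise DataValidationError("empty community table")
    rel = table.relative_abundance()
    return _core_from_presence(rel > detection, rel, "overall", prevalence, detection)


def _unit_presence(
    table: CommunityTable,
    meta: SampleFrame,
    unit_column: str,
    sample_ids: list,
    detection: float,
    replicate_mode: str,
):
    """Collapse samples to unit-level presence and unit-level mean relative
    abundance (units = lakes or years)."""
    rel = table.relative_abundance().loc[sample_ids]
    units = meta.data.loc[sample_ids, unit_column]
    if replicate_mode == "any":
        presence = (rel > detection).groupby(units).any()
    elif replicate_mode == "mean":
        presence = rel.groupby(units).mean() > detection
    else:
        raise ParameterError(f"unknown replicate_mode {replicate_mode!r}")
    rel_units = rel.groupby(units).mean()
    return presence, rel_units


def spatial_core(
    table: CommunityTable,
    meta: SampleFrame,
    year: int,
    prevalence: float = 0.75,
    detection: float = 0.001,
    replicate_mode: str = "any",
) -> CoreSet:
    """Core of a sampling year across lakes: OTUs present (above detection in
    at least one of a lake's samples that year) in >= ``prevalence`` of lakes."""
    _check_thresholds(prevalence, detection)
    samples = [s for s in table.sample_ids if s in meta.data.index and meta.data.loc[s, "year"] == year]
    if not samples:
        raise ParameterError(f"year {year} has no samples")
    presence, rel_units = _unit_presence(table, meta, "ecosystem", samples, detection, replicate_mode)
    return _core_from_presence(presence, rel_units, f"spatial:{year}", prevalence, detection)


def temporal_core(
    table: CommunityTable,
    meta: SampleFrame,
    ecosystem: str,
    prevalence: float = 0.75,
    detection: float = 0.001,
    replicate_mode: str = "any",
) -> CoreSet:
    """Core of a lake across sampling years, symmetric to :func:`spatial_core`."""
    _check_thresholds(prevalence, detection)
    samples = [
        s for s in table.sample_ids
        if s in meta.data.index and meta.data.loc[s, "ecosystem"] == ecosystem
    ]
    if not samples:
        raise ParameterError(f"ecosystem {ecosystem!r} has no samples")
    presence, rel_units = _unit_presence(table, meta, "year", samples, detection, replicate_mode)
    return _core_from_presence(presence, rel_units, f"temporal:{ecosystem}", prevalence, detection)


def core_overlap(core_a: CoreSet, core_b: CoreSet) -> dict:
    """Jaccard similarity and shared membership of two cores."""
    a, b = set(core_a.otu_ids), set(core_b.otu_ids)
    if not a and not b:
        raise DataValidationError("both cores are empty")
    union = a | b
    shared = sorted(a & b)
    return {"jaccard": len(shared) / len(union), "shared_ids": shared}
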