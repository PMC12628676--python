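"""End-to-end pipeline: validate -> rarefy -> diversity -> distance decay ->
cores -> phylogenetic-signal gate -> betaNTI + Raup-Crick -> classification
-> turnover partitioning -> subset permutation tests, run independently per
habitat, from a config that points at input files or at a synthetic
scenario.

Outputs are plain TSV/JSON tables under the configured output directory plus
a run manifest (seeds, stage row counts, per-stage wall time).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coremicro, datasets, diversity, nullmodels, partition, signal, simulate
from .exceptions import ParameterError, SignalGateError

log = logging.getLogger("ecoassembly")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; either ``scenario`` or input paths."""

    output_dir: str = "results/run"
    seed: int = 0
    # synthetic mode
    scenario: dict | None = None
    # file mode
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    environment_path: str | None = None
    table_format: str = "tsv"
    # stage parameters
    habitats: list | None = None
    rarefaction_depth: int | None = None
    low_abundance_filter: float = 0.0
    abundant_threshold: float = 0.01
    detection: float = 0.001
    prevalence: float = 0.75
    n_null: int = 999
    n_perm: int = 999
    n_classes: int = 30
    force: bool = False

    def __post_init__(self):
        if self.scenario is None and self.table_path is None:
            raise ParameterError("config needs either a scenario block or input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load_inputs(config: PipelineConfig):
    if config.scenario is not None:
        cfg = simulate.ScenarioConfig(**{**config.scenario, "seed": config.scenario.get("seed", config.seed)})
        return simulate.assemble_dataset(cfg)
    table = datasets.load_community_table(config.table_path, format=config.table_format)
    meta = datasets.load_sample_frame(config.metadata_path)
    tree = datasets.read_newick(config.tree_path) if config.tree_path else None
    env = (
        datasets.load_environment_table(config.environment_path)
        if config.environment_path
        else None
    )
    return table, meta, tree, env


def _stage(manifest, name, t0, **info):
    manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3), **info})
    log.info("stage %s done in %.2fs %s", name, time.time() - t0, info)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every habitat; return (and write) the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"seed": config.seed, "stages": [], "habitats": {}}

    t0 = time.time()
    table, meta, tree, env = _load_inputs(config)
    _stage(manifest, "load", t0, n_samples=len(table.sample_ids), n_otus=len(table.otu_ids))

    t0 = time.time()
    report = datasets.validate_dataset(table, meta, tree, strict=False)
    drop = set(report.zero_sum_samples) | set(report.samples_missing_metadata)
    if drop:
        table = table.subset_samples([s for s in table.sample_ids if s not in drop])
    if report.zero_sum_otus:
        table = table.drop_empty_otus()
    datasets.validate_dataset(table, meta, tree, strict=True)
    _stage(manifest, "validate", t0, dropped=sorted(drop), empty_otus=len(report.zero_sum_otus))

    if config.low_abundance_filter > 0:
        table = datasets.filter_low_abundance(table, config.low_abundance_filter)
    if config.rarefaction_depth:
        t0 = time.time()
        table, dropped = datasets.rarefy(table, config.rarefaction_depth, seed=config.seed)
        _stage(manifest, "rarefy", t0, depth=config.rarefaction_depth, dropped=dropped)

    habitats = config.habitats or sorted(set(meta.data.loc[table.sample_ids, "habitat"]))
    for habitat in habitats:
        manifest["habitats"][habitat] = _run_habitat(config, out, habitat, table, meta, tree, env, manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_habitat(config, out, habitat, table, meta, tree, env, manifest):
    hdir = out / habitat
    hdir.mkdir(exist_ok=True)
    ids = [s for s in table.sample_ids if meta.data.loc[s, "habitat"] == habitat]
    if len(ids) < 4:
        raise ParameterError(f"habitat {habitat!r} has too few samples ({len(ids)})")
    tab = table.subset_samples(ids).drop_empty_otus()
    sub_meta = meta.subset(ids)
    info = {"n_samples": len(ids)}

    # alpha/beta diversity
    t0 = time.time()
    alpha = diversity.alpha_diversity(tab)
    alpha.to_csv(hdir / "alpha_diversity.tsv", sep="\t")
    hel = diversity.hellinger(tab)
    bc = diversity.bray_curtis(hel)
    pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids).to_csv(hdir / "bray_curtis.tsv", sep="\t")
    ord_res = diversity.pcoa(bc)
    ord_res.samples.iloc[:, :4].to_csv(hdir / "pcoa_coordinates.tsv", sep="\t")
    tests = {}
    for factor in ("ecosystem", "year"):
        res = diversity.permanova(
            bc, sub_meta.data.loc[list(bc.ids), factor], n_perm=config.n_perm,
            seed=config.seed, factor=factor,
        )
        tests[f"permanova_{factor}"] = asdict(res)
        try:
            disp = diversity.dispersion_homogeneity(
                bc, sub_meta.data.loc[list(bc.ids), factor], n_perm=config.n_perm, seed=config.seed
            )
            tests[f"dispersion_{factor}"] = asdict(disp)
        except ParameterError as exc:
            tests[f"dispersion_{factor}"] = {"error": str(exc)}
    _stage(manifest, f"{habitat}:diversity", t0, **info)

    # distance decay
    t0 = time.time()
    geo = diversity.geographic_distance(sub_meta)
    tmp = diversity.temporal_distance(sub_meta)
    eco = sub_meta.data["ecosystem"]
    yr = sub_meta.data["year"]
    ddr = {
        "geographic": asdict(diversity.distance_decay(
            bc, geo, pairs_filter=lambda a, b: eco[a] != eco[b] and yr[a] == yr[b],
            n_perm=config.n_perm, seed=config.seed, predictor_name="geographic_km")),
        "temporal": asdict(diversity.distance_decay(
            bc, tmp, pairs_filter=lambda a, b: eco[a] == eco[b] and yr[a] != yr[b],
            n_perm=config.n_perm, seed=config.seed, predictor_name="temporal_days")),
    }
    with open(hdir / "distance_decay.json", "w") as fh:
        json.dump(ddr, fh, indent=2)
    _stage(manifest, f"{habitat}:distance_decay", t0)

    # cores
    t0 = time.time()
    overall = coremicro.core_members(tab, config.prevalence, config.detection)
    spatial = [
        coremicro.spatial_core(tab, sub_meta, y, config.prevalence, config.detection)
        for y in sorted(set(yr))
    ]
    temporal = [
        coremicro.temporal_core(tab, sub_meta, e, config.prevalence, config.detection)
        for e in sorted(set(eco))
    ]
    core_rows = [
        dict(scope=c.scope, core_richness=c.core_richness,
             cumulative_abundance_mean=c.cumulative_abundance_mean,
             cumulative_abundance_sd=c.cumulative_abundance_sd, n_units=c.n_units)
        for c in [overall, *spatial, *temporal]
    ]
    pd.DataFrame(core_rows).to_csv(hdir / "core_summary.tsv", sep="\t", index=False)
    _stage(manifest, f"{habitat}:cores", t0, n_cores=len(core_rows))

    # phylogenetic signal gate
    t0 = time.time()
    gate = {"checked": tree is not None and env is not None}
    if gate["checked"]:
        abundant = signal.filter_abundant(tab, config.abundant_threshold, "any_sample")
        optima = signal.cca_optima(
            abundant, env.loc[tab.sample_ids], n_perm=min(config.n_perm, 199), seed=config.seed
        )
        if not optima.has_signal_basis:
            optima = signal.abundance_weighted_optima(abundant, env.loc[tab.sample_ids])
        correlogram = signal.mantel_correlogram(
            optima, tree, n_classes=config.n_classes, n_perm=config.n_perm, seed=config.seed
        )
        correlogram.to_csv(hdir / "mantel_correlogram.tsv", sep="\t", index=False)
        gate.update(
            method=optima.method,
            p_axis1=optima.p_axis1,
            passed=signal.has_short_distance_signal(correlogram),
        )
        if not gate["passed"] and not config.force:
            raise SignalGateError(
                f"habitat {habitat!r}: no significant positive short-distance "
                "phylogenetic signal; betaNTI-based inference is not justified "
                "(re-run with force=True to override)"
            )
    _stage(manifest, f"{habitat}:signal_gate", t0, **{k: str(v) for k, v in gate.items()})

    # null models + classification + partitioning
    t0 = time.time()
    pairs = nullmodels.assembly_analysis(tab, tree, n_null=config.n_null, seed=config.seed)
    cats = partition.categorize_pairs(sub_meta)
    pairs = pairs.merge(cats, on=["sample_i", "sample_j"])
    pairs.to_csv(hdir / "pairwise_assembly.tsv", sep="\t", index=False)
    _stage(manifest, f"{habitat}:null_models", t0, n_pairs=len(pairs))

    t0 = time.time()
    summaries = []
    subset_values = {}
    for subset in ("all", "intra_lake", "inter_lake_same_year", "inter_year_same_lake"):
        try:
            summary = partition.contributions(pairs, subset)
        except Exception:
            continue
        summaries.append(summary)
        subset_values[subset] = summary.set_index("process")["per_type_percent"].to_dict()
    summary_df = pd.concat(summaries, ignore_index=True)
    summary_df.drop(columns=["per_type_percent"]).to_csv(
        hdir / "process_contributions.tsv", sep="\t", index=False
    )
    perm_tests = []
    compared = [("inter_lake_same_year", "inter_year_same_lake"),
                ("inter_lake_same_year", "intra_lake"),
                ("inter_year_same_lake", "intra_lake")]
    for sa, sb in compared:
        if sa not in subset_values or sb not in subset_values:
            continue
        for process in partition.CLASSIFIED_PROCESSES:
            p = partition.subset_permutation_test(
                subset_values[sa][process], subset_values[sb][process],
                n_perm=config.n_perm, seed=config.seed,
            )
            perm_tests.append(dict(subset_a=sa, subset_b=sb, process=process, p_value=p))
    with open(hdir / "subset_permutation_tests.json", "w") as fh:
        json.dump(perm_tests, fh, indent=2)
    _stage(manifest, f"{habitat}:partition", t0, n_subsets=len(summaries))

    return {
        "n_samples": len(ids),
        "n_pairs": len(pairs),
        "diversity_tests": tests,
        "distance_decay": ddr,
        "signal_gate": gate,
        "process_contributions": summary_df.drop(columns=["per_type_percent"]).to_dict("records"),
    }
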