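"""Synthetic lake-microbiome datasets assembled under known ecological processes.

The generator emulates the study design of a cluster of Antarctic lakes:
``n_ecosystems`` lakes x ``n_years`` austral-summer campaigns x habitats
(sediment / water) x ``n_replicates`` field replicates, a regional pool of a
few hundred OTUs related by a Yule phylogeny, and Brownian-motion niche
optima on that phylogeny (so niche preference carries phylogenetic signal).

Each scenario assembles every sample from the regional pool under one of the
five classical community-assembly processes, with the scenario designed so
that the betaNTI / Raup-Crick classification should recover it as dominant:

* ``variable_selection``   — Gaussian environmental filtering, environment
  differing among lakes: communities converge within and diverge between
  lakes, onto phylogenetically distinct clades.
* ``homogeneous_selection`` — same filter, identical environment everywhere:
  all communities converge onto the same clade.
* ``dispersal_limitation`` — each lake receives a private random subset of
  the pool (neutral weights within it).
* ``homogenizing_dispersal`` — every sample is a multinomial draw straight
  from the common pool (mass effects swamp local dynamics).
* ``drift``                — serial demographic bottlenecks per sample
  lineage (bottleneck 5% of the library size, 5 cycles), then resampling.

Counts are multinomial at ``reads_per_sample`` reads, so sample sums are
exact.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skbio

from ._seeding import substream
from .datasets import CommunityTable, SampleFrame
from .exceptions import ParameterError

__all__ = [
    "ScenarioConfig",
    "RegionalPool",
    "simulate_tree",
    "radiation_tree",
    "evolve_trait_bm",
    "build_regional_pool",
    "assemble_dataset",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

#: Base sampling years of the emulated design; extended by 2-year steps beyond four.
BASE_YEARS = (2017, 2019, 2021, 2023)

#: Radiation phylogeny of the regional pool: number of tips per terminal
#: clade, stem length from the root to each clade (with +-10% jitter), and
#: mean exponential branch length inside clades.  Long, near-equal stems and
#: short twigs encode strong niche conservatism: Brownian optima are nearly
#: constant within a clade and independent between clades.
RADIATION_CLADE_SIZE = 5
RADIATION_STEM_LENGTH = 1.0
RADIATION_TWIG_LENGTH = 0.02

#: Drift scenario constants: bottleneck fraction of the library and cycle count.
DRIFT_BOTTLENECK_FRACTION = 0.2
DRIFT_CYCLES = 1

#: Dispersal-limitation colonization model: each lake receives a private
#: random subset of the pool, and a lake-specific lognormal "founder effect"
#: perturbs within-lake dominance (restricted exchange lets priority effects
#: and local drift fix different dominants in different lakes).
DISPERSAL_SUBSET_FRACTION = 0.3
DISPERSAL_FOUNDER_SIGMA = 2.0

#: Environment value shared by all lakes under homogeneous selection: one end
#: of the standardized regional niche spectrum, so the common filter selects
#: a clade-restricted set of specialists.
HOMOGENEOUS_ENV = 1.0

#: Immigration floor of the Gaussian filter (relative to its peak): the
#: propagule trickle that keeps maladapted taxa detectable as rare colonists.
SELECTION_BACKGROUND = 5e-5

#: Lognormal sigma of the ecosystem x year dominance turnover inside the fit
#: set under selection.  Selection fixes *which clade* wins, while founder
#: effects and local drift decide *which of its ecologically equivalent
#: members* dominate a given lake-year — the turnover that makes selected
#: communities exchange close relatives rather than identical taxa.
SELECTION_TURNOVER_SIGMA = 0.3

#: Exponent applied to regional pool abundances inside the selection kernel.
#: Values < 1 flatten neutral dominance among the fit taxa: under strong
#: selection, realized abundances reflect fitness under the filter (plus
#: founder turnover) more than regional commonness.
SELECTION_POOL_EXPONENT = 0.3

#: Probability that a pool member is locally present in a given lake-year
#: under selection.  Colonization/extinction dynamics mean each lake-year
#: realizes only a subset of the taxa the environment would admit, so two
#: selected communities exchange close relatives instead of sharing every
#: taxon outright.
SELECTION_OCCUPANCY = 0.5

#: Half-range of the standardized environmental gradient spanned by the lakes.
ENV_GRADIENT_HALF_RANGE = 1.5


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic dataset: design sizes, assembly process and strengths.

    ``selection_strength_sigma`` is the Gaussian niche breadth in units of the
    (standardized) niche-optimum scale — smaller means harsher filtering.
    ``trait_rate`` is the Brownian variance per unit branch length.
    """

    process: str = "variable_selection"
    n_otus_pool: int = 300
    n_ecosystems: int = 11
    n_years: int = 4
    n_replicates: int = 2
    habitats: tuple[str, ...] = ("sediment", "water")
    reads_per_sample: int = 7690
    selection_strength_sigma: float = 0.3
    trait_rate: float = 1.0
    pool_lognormal_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise ParameterError(f"unknown process {self.process!r}; expected one of {PROCESSES}")
        for name in ("n_otus_pool", "n_ecosystems", "n_years", "n_replicates", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.selection_strength_sigma <= 0:
            raise ParameterError("selection_strength_sigma must be > 0")
        if self.trait_rate <= 0:
            raise ParameterError("trait_rate must be > 0")

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class RegionalPool:
    """Regional species pool: phylogeny, niche optima, and relative abundances."""

    tree: skbio.TreeNode
    optima: pd.Series  # per-OTU environmental optimum (standardized units)
    pool_abundance: pd.Series  # simplex over OTUs

    def __post_init__(self):
        if not np.isclose(self.pool_abundance.sum(), 1.0):
            raise ParameterError("pool_abundance must sum to 1")
        tips = {t.name for t in self.tree.tips()}
        if set(self.optima.index) != tips:
            raise ParameterError("optima must be defined for exactly the tree tips")


# ---------------------------------------------------------------------------
# Phylogeny and traits


def simulate_tree(
    n_tips: int,
    seed: int = 0,
    mean_branch_length: float = 0.1,
    conservatism_gamma: float = 0.0,
) -> skbio.TreeNode:
    """Simulate a rooted Yule (pure-birth) topology with Exp branch lengths.

    Tips are labelled ``OTU1`` .. ``OTUn``.  At each step a uniformly chosen
    extant lineage splits; afterwards every edge gets an independent
    exponential length with the given mean.

    ``conservatism_gamma > 0`` additionally scales each edge by (number of
    descendant tips)**gamma, so deep splits are long relative to terminal
    twigs.  Brownian traits evolved on such a tree diverge mostly between
    major clades and little within them — the niche-conservatism structure
    under which closely related taxa share environmental preferences.
    """
    if n_tips < 2:
        raise ParameterError(f"n_tips must be >= 2, got {n_tips}")
    rng = substream(seed, "yule-tree")
    root = skbio.TreeNode()
    leaves = [skbio.TreeNode(), skbio.TreeNode()]
    root.extend(list(leaves))
    while len(leaves) < n_tips:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        kids = [skbio.TreeNode(), skbio.TreeNode()]
        node.extend(kids)
        leaves.extend(kids)
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(mean_branch_length))
        if conservatism_gamma > 0:
            k = node.count(tips=True) if not node.is_tip() else 1
            node.length *= k**conservatism_gamma
    root.length = None
    return root


def evolve_trait_bm(tree: skbio.TreeNode, rate: float, seed: int = 0) -> pd.Series:
    """Evolve a continuous trait by Brownian motion from a root value of 0.

    Each branch adds a Normal(0, rate * branch_length) increment, so a tip's
    marginal variance equals ``rate`` times its root-to-tip path length and
    covariances equal ``rate`` times shared path length.
    """
    if rate <= 0:
        raise ParameterError(f"rate must be > 0, got {rate}")
    rng = substream(seed, "bm-trait")
    values: dict[int, float] = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        bl = node.length or 0.0
        val = values[id(node.parent)] + rng.normal(0.0, np.sqrt(rate * bl))
        values[id(node)] = val
        if node.is_tip():
            out[node.name] = val
    return pd.Series(out, name="optimum")


def radiation_tree(
    n_tips: int,
    seed: int = 0,
    clade_size: int = RADIATION_CLADE_SIZE,
    stem_length: float = RADIATION_STEM_LENGTH,
    twig_length: float = RADIATION_TWIG_LENGTH,
) -> skbio.TreeNode:
    """Two-level radiation phylogeny: many small tight clades on long stems.

    The root carries ``n_tips // clade_size`` clade stems of near-equal
    length; each clade is a little Yule subtree with short exponential
    branches.  Brownian traits on this tree are nearly constant within a
    clade and essentially independent between clades — a simple, explicit
    model of deep niche conservatism.
    """
    if n_tips < 2:
        raise ParameterError(f"n_tips must be >= 2, got {n_tips}")
    rng = substream(seed, "radiation-tree")
    root = skbio.TreeNode()
    n_clades = max(1, round(n_tips / clade_size))
    sizes = np.full(n_clades, n_tips // n_clades)
    sizes[: n_tips - int(sizes.sum())] += 1
    for c in range(n_clades):
        stem = skbio.TreeNode(length=float(stem_length * (0.9 + 0.2 * rng.random())))
        root.append(stem)
        leaves = [stem]
        while len(leaves) < sizes[c]:
            node = leaves.pop(int(rng.integers(len(leaves))))
            kids = [skbio.TreeNode(), skbio.TreeNode()]
            node.extend(kids)
            leaves.extend(kids)
        for nd in stem.traverse(include_self=False):
            nd.length = float(rng.exponential(twig_length))
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1}"
    root.length = None
    return root


def build_regional_pool(config: ScenarioConfig) -> RegionalPool:
    """Radiation tree + BM niche optima + lognormal regional abundances."""
    tree = radiation_tree(config.n_otus_pool, seed=config.seed)
    optima = evolve_trait_bm(tree, config.trait_rate, seed=config.seed)
    # Standardize optima so the environmental gradient and niche breadth are
    # expressed on a fixed scale regardless of tree depth.
    optima = (optima - optima.mean()) / optima.std()
    rng = substream(config.seed, "pool-abundance")
    w = np.exp(rng.normal(0.0, config.pool_lognormal_sigma, size=config.n_otus_pool))
    tips = [t.name for t in tree.tips()]
    pool = pd.Series(w / w.sum(), index=tips, name="pool_abundance")
    return RegionalPool(tree=tree, optima=optima.loc[tips], pool_abundance=pool)


# ---------------------------------------------------------------------------
# Study design and assembly


def _years(n: int) -> list[int]:
    years = list(BASE_YEARS)
    while len(years) < n:
        years.append(years[-1] + 2)
    return years[:n]


def _design_frame(config: ScenarioConfig) -> pd.DataFrame:
    """Enumerate the sample design with ids like ``L03-2019-W-A``."""
    rows = []
    years = _years(config.n_years)
    reps = [chr(ord("A") + i) for i in range(config.n_replicates)]
    # Lakes sit on a sub-kilometre grid in a maritime-Antarctic lake district.
    base_lat, base_lon = -62.20, -58.96
    for e in range(config.n_ecosystems):
        eco = f"L{e + 1:02d}"
        lat = base_lat + 0.004 * (e % 4)
        lon = base_lon + 0.006 * (e // 4)
        for year in years:
            for habitat in config.habitats:
                for rep in reps:
                    sid = f"{eco}-{year}-{habitat[0].upper()}-{rep}"
                    rows.append(
                        dict(
                            sample_id=sid,
                            ecosystem=eco,
                            year=year,
                            habitat=habitat,
                            replicate=rep,
                            latitude=lat,
                            longitude=lon,
                            date=f"{year}-01-15",
                        )
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _environment_values(config: ScenarioConfig, design: pd.DataFrame) -> pd.Series:
    """True environment per (ecosystem, year): a lake gradient plus year jitter.

    Under ``homogeneous_selection`` the gradient collapses to a single value;
    for all other processes lakes are spread over the standardized gradient
    (the environment simply has no effect on assembly there).
    """
    ecos = sorted(design["ecosystem"].unique())
    years = sorted(design["year"].unique())
    rng = substream(config.seed, "environment")
    if config.process == "homogeneous_selection":
        base = {eco: HOMOGENEOUS_ENV for eco in ecos}
    else:
        grid = np.linspace(-ENV_GRADIENT_HALF_RANGE, ENV_GRADIENT_HALF_RANGE, len(ecos))
        base = dict(zip(ecos, grid))
    env = {}
    for eco in ecos:
        for year in years:
            env[(eco, year)] = base[eco] + rng.normal(0.0, 0.05)
    return pd.Series(env)


def _selection_weights(
    pool: RegionalPool, env: float, sigma: float, background: float = None
) -> np.ndarray:
    """Gaussian environmental filter over the pool, with a weak immigration floor.

    The floor (mass effects: a trickle of propagules of every pool member
    reaches every lake) keeps maladapted taxa present as rare scattered
    colonists, so per-sample communities are dominated by the locally fit
    clade while the dataset-wide taxon pool still spans the whole phylogeny.
    """
    if background is None:
        background = SELECTION_BACKGROUND
    opt = pool.optima.to_numpy()
    gauss = np.exp(-((opt - env) ** 2) / (2.0 * sigma**2))
    w = pool.pool_abundance.to_numpy() ** SELECTION_POOL_EXPONENT * (gauss + background)
    return w / w.sum()


def _drift_weights(pool_p: np.ndarray, reads: int, rng: np.random.Generator) -> np.ndarray:
    """Serial bottleneck-and-regrow resampling of the pool frequencies."""
    bottleneck = max(1, int(round(DRIFT_BOTTLENECK_FRACTION * reads)))
    p = pool_p.copy()
    for _ in range(DRIFT_CYCLES):
        counts = rng.multinomial(bottleneck, p)
        p = counts / counts.sum()
    return p


def assemble_dataset(
    config: ScenarioConfig,
) -> tuple[CommunityTable, SampleFrame, skbio.TreeNode, pd.DataFrame]:
    """Generate one complete synthetic dataset under the configured process.

    Returns ``(table, metadata, tree, environment)``.  The environment table
    has one row per sample with the single variable ``env`` — the true
    ecosystem x year environment plus small measurement noise — which is what
    a probe lowered into the lake would report whether or not the environment
    drove assembly.
    """
    pool = build_regional_pool(config)
    design = _design_frame(config)
    true_env = _environment_values(config, design)
    pool_p = pool.pool_abundance.to_numpy()
    otu_ids = list(pool.pool_abundance.index)
    n = len(otu_ids)

    # Per-lake colonization state for dispersal limitation, shared across
    # years, habitats and replicates (the lake's colonization history): a
    # private random subset of the pool plus lake-specific founder dominance.
    lake_weights = {}
    if config.process == "dispersal_limitation":
        k = max(2, int(round(DISPERSAL_SUBSET_FRACTION * n)))
        for eco in sorted(design["ecosystem"].unique()):
            rng_e = substream(config.seed, "dispersal-subset", eco)
            idx = rng_e.choice(n, size=k, replace=False)
            w = np.zeros(n)
            w[idx] = pool_p[idx] * np.exp(
                rng_e.normal(0.0, DISPERSAL_FOUNDER_SIGMA, size=k)
            )
            lake_weights[eco] = w / w.sum()

    rows = np.zeros((len(design), n), dtype=np.int64)
    for i, (sid, meta) in enumerate(design.iterrows()):
        eco, year, habitat = meta["ecosystem"], meta["year"], meta["habitat"]
        env = true_env[(eco, year)]
        if config.process in ("variable_selection", "homogeneous_selection"):
            # Replicates share the ecosystem-year generative state (filter +
            # within-clade dominance turnover); only the multinomial sampling
            # noise differs between them.
            w = _selection_weights(pool, env, config.selection_strength_sigma)
            rng_t = substream(config.seed, "selection-turnover", eco, year)
            w = w * np.exp(rng_t.normal(0.0, SELECTION_TURNOVER_SIGMA, size=n))
            w = w * (rng_t.random(n) < SELECTION_OCCUPANCY)
            if w.sum() <= 0:
                w = _selection_weights(pool, env, config.selection_strength_sigma)
            w = w / w.sum()
        elif config.process == "dispersal_limitation":
            w = lake_weights[eco]
        elif config.process == "homogenizing_dispersal":
            w = pool_p
        else:  # drift: each sample lineage drifts independently
            rng_d = substream(config.seed, "drift", sid)
            w = _drift_weights(pool_p, config.reads_per_sample, rng_d)
        rng_s = substream(config.seed, "sampling", sid)
        rows[i] = rng_s.multinomial(config.reads_per_sample, w)

    table = CommunityTable(pd.DataFrame(rows, index=design.index, columns=otu_ids))
    table = table.drop_empty_otus()  # pool members never sampled anywhere
    meta = SampleFrame(design)
    env_rng = substream(config.seed, "env-noise")
    env_obs = np.array(
        [true_env[(r["ecosystem"], r["year"])] for _, r in design.iterrows()]
    ) + env_rng.normal(0.0, 0.05, size=len(design))
    env_df = pd.DataFrame({"env": env_obs}, index=design.index)
    return table, meta, pool.tree, env_df
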