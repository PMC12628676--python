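# ecoassembly

Null-model quantification of microbial community assembly processes, built
for replicated lake-survey designs (many lakes x several years x duplicate
samples, water and sediment analyzed independently).

Microbial ecologists routinely ask how much of community turnover is driven
by deterministic environmental selection versus stochastic dispersal and
demographic drift. `ecoassembly` implements the standard two-index
null-model framework to answer that question from an OTU table, a rooted
phylogeny and sample metadata, and ships a synthetic-data generator that
assembles communities under each candidate process so the whole inference
chain can be validated end to end without any sequencing data.

## The method

For every pair of communities *k, m* the package computes the
**β-mean-nearest-taxon distance**

> βMNTD(k,m) = ½ [ Σᵢ f_ik · minⱼ d(i,j) + Σⱼ f_jm · minᵢ d(i,j) ]

with *f* the within-sample relative abundances, *i*, *j* running over taxa
present in *k* and *m*, and *d* the cophenetic distance on the phylogeny.
Standardizing the observed value against a null distribution obtained by
shuffling taxon labels across the tree tips gives the **β-nearest taxon
index** (βNTI), in units of null standard deviations.  Pairs with βNTI < −2
are assembled by **homogeneous selection**, βNTI > +2 by **variable
selection**.  Pairs in between are resolved by the **Raup–Crick
Bray–Curtis** index (RC_Bray), which compares observed Bray–Curtis
dissimilarity against communities rebuilt by drawing each sample's richness
from the pool (probability ∝ occupancy) and filling reads ∝ pooled relative
abundance: RC_Bray > +0.95 → **dispersal limitation**, RC_Bray < −0.95 →
**homogenizing dispersal**, otherwise **ecological drift**.  Thresholds are
strict inequalities; degenerate pairs (zero null spread) are reported as
`undetermined` and excluded from percentages.

Before any of this is interpreted, the package checks the framework's
prerequisite — phylogenetic signal in niche preference — by estimating
per-OTU environmental optima (scores on the first significant CCA axis of
abundant taxa against the environment) and testing, with a 30-class Mantel
correlogram under progressive Bonferroni correction, that closely related
taxa have similar optima.

Pairwise labels are then aggregated the way the study design dictates:
intra-lake (same lake, same year), inter-lake within a year (spatial
turnover), inter-year within a lake (temporal turnover) and all pairs,
with percentages computed per replicate-combination "comparison type",
averaged across types (mean ± SD, 95% CI from the SE), and compared between
subsets by exact two-sided permutation tests.  Spatial (per-year, across
lakes) and temporal (per-lake, across years) core microbiomes use a 0.1%
detection and 75% prevalence rule.

## Worked example

```python
from ecoassembly import ScenarioConfig, assemble_dataset, assembly_analysis
from ecoassembly.partition import categorize_pairs, contributions

cfg = ScenarioConfig(process="variable_selection", n_otus_pool=300,
                     n_ecosystems=8, n_years=2, n_replicates=2,
                     habitats=("water",), reads_per_sample=5000, seed=1)
table, meta, tree, env = assemble_dataset(cfg)

pairs = assembly_analysis(table, tree, n_null=199, seed=1)
pairs = pairs.merge(categorize_pairs(meta), on=["sample_i", "sample_j"])
print(contributions(pairs, "inter_lake_same_year")
      .set_index("process")["mean_percent"].round(1))
```

prints the mean contribution (%) of each process to spatial turnover:

```
process
variable_selection        58.3
homogeneous_selection     13.4
dispersal_limitation      19.3
homogenizing_dispersal     0.0
drift                      8.9
```

— the generating process (variable selection: lakes with different
environments filtering different clades) dominates the inter-lake subset,
with the remainder split between dispersal limitation and drift.  The
numbered scripts under `analysis/` run the same chain as a narrative:
`01_simulate_datasets.py` writes one dataset per process,
`02_diversity_turnover.py` shows spatial structure dominating inter-annual
structure (PERMANOVA R² = 0.76 for lake identity vs 0.03 for year),
`03_phylo_signal.py` verifies the correlogram gate, `04_assembly_processes.py`
recovers each generating process as the modal label, and
`05_core_microbiome.py` contrasts spatial and temporal cores (collapsed
spatial core under dispersal limitation, near-identical large cores under
homogenizing dispersal).

A CLI covers the two shell-level entry points:

```bash
ecoassembly simulate --process drift --out results/sim
ecoassembly run --seed 3 --out results/demo   # one-command synthetic demo
```

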