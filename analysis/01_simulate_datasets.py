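#!/usr/bin/env python
"""Generate the five synthetic study datasets, one per assembly process.

Each dataset emulates the field design — lakes x years x duplicate samples,
one habitat — with communities assembled from a shared regional species pool
under a single known process.  Files (OTU table, Newick tree, metadata,
environment) are written under results/data/<process>/ in the same dialects
the loaders read, so every later step can also be run from files.
"""

from pathlib import Path

from ecoassembly.datasets import write_newick
from ecoassembly.simulate import PROCESSES, ScenarioConfig, assemble_dataset

SEED = 1
OUT = Path("results/data")

# Analysis-scale design: 8 lakes x 2 years x 2 replicates, 300-OTU pool,
# 5000 reads per sample (about two thirds of the field study's rarefaction
# depth, which keeps the whole analysis chain fast on one CPU).
BASE = dict(
    n_otus_pool=300, n_ecosystems=8, n_years=2, n_replicates=2,
    habitats=("water",), reads_per_sample=5000,
)


def main() -> None:
    for process in PROCESSES:
        cfg = ScenarioConfig(process=process, seed=SEED, **BASE)
        table, meta, tree, env = assemble_dataset(cfg)
        outdir = OUT / process
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_tsv(outdir / "otu_table.tsv")
        meta.to_csv(outdir / "metadata.csv")
        env.to_csv(outdir / "environment.csv", index_label="sample_id")
        write_newick(tree, outdir / "tree.nwk")
        print(
            f"{process}: {len(table.sample_ids)} samples x {len(table.otu_ids)} OTUs, "
            f"median sample richness {int((table.counts > 0).sum(axis=1).mean())}"
        )


if __name__ == "__main__":
    main()
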