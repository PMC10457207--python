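#!/usr/bin/env python
"""Generate the default synthetic branching CITE-seq dataset.

Draws ~2,000 thymocyte-like cells (three genotypes: CD4-restricted,
CD8-restricted, wild-type) with 600 genes and 20 surface proteins, writes
the counts (MTX + TSV) and the full ground truth under results/simdata/,
and prints a summary of the study conditions.
"""

import numpy as np

from lineagewave import io as lwio
from lineagewave.simdata import SimConfig, simulate_dataset

SEED = 1
OUTDIR = "results/simdata"


def main():
    config = SimConfig(seed=SEED)
    bundle, truth = simulate_dataset(config)
    lwio.write_counts_bundle(bundle, OUTDIR)
    lwio.write_ground_truth(truth, OUTDIR)
    lwio.write_manifest(OUTDIR, SEED, config.to_dict())

    cells = truth.cells
    print(f"cells: {bundle.n_cells}  genes: {len(bundle.gene_names)}  "
          f"proteins: {len(bundle.protein_names)}")
    print(f"median RNA library: {np.median(bundle.rna.sum(1)):.0f} UMIs; "
          f"median protein library: {np.median(bundle.protein.sum(1)):.0f}")
    print("cells per genotype:",
          cells["genotype"].value_counts().to_dict())
    print("cells per true stage:",
          cells["true_stage"].value_counts().to_dict())
    n_de = int((truth.de_direction != 0).to_numpy().sum())
    print(f"planted between-lineage DE (gene, bin) pairs: {n_de}")
    print(f"planted driver TFs: "
          f"{ {tf: len(t) for tf, t in truth.tf_targets.items()} }")
    print(f"written to {OUTDIR}/")


if __name__ == "__main__":
    main()
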