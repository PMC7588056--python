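#!/usr/bin/env python
"""Build trees from the selected-region genotype matrix and compare them
with the true species tree.

Reads results/selection/ (script 02) and results/simulation/ (script 01);
writes results/trees/: NJ tree with 1,000 bootstrap supports, UPGMA
dendrogram, and an RF-comparison JSON.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from plastomarkers.trees import (bootstrap_support, hamming_distance_matrix,
                                 neighbor_joining, read_newick,
                                 robinson_foulds, upgma, write_newick)

SEL = Path("results/selection")
SIM = Path("results/simulation")
OUT = Path("results/trees")
SEED = 42
N_BOOTSTRAP = 1000


class _GM:
    def __init__(self, path: Path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        self.taxa = list(df.index)
        self.alleles = np.array(
            [[ord(str(x)[0]) for x in row] for row in df.values], dtype=np.uint8)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm = _GM(SEL / "genotype_matrix.tsv")
    true_tree = read_newick(SIM / "true_tree.nwk")

    boot = bootstrap_support(gm, "nj", n_reps=N_BOOTSTRAP, seed=SEED)
    write_newick(boot, OUT / "genotype_nj_bootstrap.nwk")
    supports = [float(n.label) for n in boot.preorder_node_iter()
                if n.label is not None]
    print(f"NJ tree with {N_BOOTSTRAP} bootstraps: "
          f"{sum(s >= 95 for s in supports)}/{len(supports)} internal edges "
          f"with support >= 95%")

    cluster = upgma(hamming_distance_matrix(gm))
    write_newick(cluster, OUT / "genotype_upgma.nwk")

    point = neighbor_joining(hamming_distance_matrix(gm))
    rf_nj, norm_nj = robinson_foulds(point, true_tree)
    rf_up, norm_up = robinson_foulds(cluster, true_tree)
    (OUT / "rf_comparison.json").write_text(json.dumps({
        "nj": {"rf": rf_nj, "normalized": norm_nj},
        "upgma": {"rf": rf_up, "normalized": norm_up},
        "n_bootstrap": N_BOOTSTRAP,
    }, indent=2) + "\n")
    print(f"RF(NJ genotype tree, true tree) = {rf_nj} "
          f"({'identical topology' if rf_nj == 0 else 'differs'})")
    print(f"RF(UPGMA dendrogram, true tree) = {rf_up}")


if __name__ == "__main__":
    main()
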