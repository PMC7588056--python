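#!/usr/bin/env python
"""Scan the simulated plastome alignment with sliding-window pi / Tajima's D
and select the marker blocks with D > -0.5.

Reads results/simulation/ (script 01); writes results/selection/: the
window TSV, all-blocks BED, selected-blocks BED, the genotype matrix TSV
and the selection report JSON.
"""

import json
from pathlib import Path

import numpy as np

from plastomarkers.alignment import MultipleAlignment
from plastomarkers.markers import (blocks_to_bed, build_genotype_matrix,
                                   collect_blocks, select_blocks)
from plastomarkers.popgen import window_scan, window_stats_frame

SIM = Path("results/simulation")
OUT = Path("results/selection")
D_THRESHOLD = -0.5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    aln = MultipleAlignment.read_fasta(SIM / "alignment.fasta")

    windows = window_scan(aln, window=500, step=100)
    with open(OUT / "window_stats.tsv", "w") as fh:
        fh.write("# window=500 step=100 max_gap_fraction=0.2 min_usable=100\n")
        window_stats_frame(windows).to_csv(fh, sep="\t", index=False)
    defined = [w.D for w in windows if w.d_defined]
    print(f"{len(windows)} windows; D range "
          f"[{min(defined):.2f}, {max(defined):.2f}], "
          f"median {np.median(defined):.2f} — most of the genome shows the "
          f"strong rare-allele excess expected under constraint + outgroup")

    blocks = collect_blocks(aln, min_length=150, max_gap_fraction=0.1)
    selected = select_blocks(blocks, D_THRESHOLD)
    blocks_to_bed(blocks, OUT / "blocks.bed")
    blocks_to_bed(selected, OUT / "selected_blocks.bed")
    print(f"{len(selected)}/{len(blocks)} well-aligned blocks pass "
          f"Tajima's D > {D_THRESHOLD}")

    gm, report = build_genotype_matrix(aln, selected, D_THRESHOLD)
    gm.write_tsv(OUT / "genotype_matrix.tsv")
    report.write_json(OUT / "selection_report.json")
    print(f"selected regions: {report.total_length} bp total, "
          f"{report.n_segregating} segregating sites")

    truth = json.loads((SIM / "truth.json").read_text())
    labels = np.array(sum(([lab] * n for lab, n in truth["region_labels_rle"]), []))
    purity = float(np.mean([labels[c] == "neutral" for _, c in gm.sites]))
    print(f"{100 * purity:.1f}% of the selected segregating sites fall in "
          f"truth-neutral regions")


if __name__ == "__main__":
    main()
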