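"""Marker-region selection: collect well-aligned blocks from a whole-plastome
alignment, keep those passing a Tajima's D neutrality threshold, and emit the
concatenated segregating-site genotype matrix.

The logic: on a plastome alignment that includes an outgroup, most windows
show a strong rare-allele excess (D well below -1) because conserved
sequence accumulates variation only on terminal branches. The few blocks
with D above the threshold (default -0.5, strictly greater-than) carry
intermediate-frequency, clade-shared variants — exactly the sites that can
reconstruct the species tree from a few hundred base pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import MultipleAlignment
from .popgen import TajimaComponents, segregating_sites, tajimas_d

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedBlock",
    "GenotypeMatrix",
    "SelectionReport",
    "collect_blocks",
    "select_blocks",
    "build_genotype_matrix",
    "proximal_genes",
]


@dataclass
class AlignedBlock:
    """A maximal well-aligned run of columns [start, end) with its
    diversity statistics."""

    block_id: int
    start: int
    end: int
    gap_fraction: float
    usable_sites: int
    stats: TajimaComponents

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeMatrix:
    """Taxa x segregating-site base calls with source coordinates."""

    taxa: list[str]
    sites: list[tuple[int, int]]  # (block_id, alignment column)
    alleles: np.ndarray = field(repr=False)  # uint8, taxa x sites

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = [f"b{b}:{c}" for b, c in self.sites]
        data = [
            [chr(x) for x in self.alleles[i]] for i in range(len(self.taxa))
        ]
        return pd.DataFrame(data, index=self.taxa, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class SelectionReport:
    n_blocks_selected: int
    total_length: int
    n_segregating: int
    d_threshold: float
    proximal_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "n_blocks_selected": self.n_blocks_selected,
            "total_length": self.total_length,
            "n_segregating": self.n_segregating,
            "d_threshold": self.d_threshold,
            "proximal_genes": self.proximal_genes,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def collect_blocks(
    aln: MultipleAlignment,
    min_length: int = 150,
    max_gap_fraction: float = 0.1,
) -> list[AlignedBlock]:
    """Maximal runs of columns whose per-column gap/'N' fraction is at most
    ``max_gap_fraction``; runs shorter than ``min_length`` are dropped.
    Every surviving block carries full Tajima components."""
    if aln.length == 0:
        raise ValueError("empty alignment")
    good = aln.column_gap_fraction() <= max_gap_fraction
    blocks: list[AlignedBlock] = []
    # run-length decomposition of the good-column mask
    boundaries = np.flatnonzero(np.diff(good.astype(np.int8))) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [aln.length]])
    bid = 0
    for s, e in zip(starts, ends):
        if not good[s] or (e - s) < min_length:
            continue
        sub = aln.slice_columns(int(s), int(e))
        comp = tajimas_d(sub)
        blocks.append(
            AlignedBlock(
                block_id=bid, start=int(s), end=int(e),
                gap_fraction=float(sub.column_gap_fraction().mean()),
                usable_sites=comp.usable_sites, stats=comp,
            )
        )
        bid += 1
    if not blocks:
        logger.warning("no well-aligned block passed min_length=%d", min_length)
    return blocks


def select_blocks(
    blocks: list[AlignedBlock],
    d_threshold: float = -0.5,
    d_upper: float | None = None,
) -> list[AlignedBlock]:
    """Blocks with defined Tajima's D strictly greater than ``d_threshold``
    (optionally also below ``d_upper``); input order preserved. Blocks with
    undefined D are never selectable."""
    out = []
    for b in blocks:
        if not b.stats.defined:
            continue
        if b.stats.D > d_threshold and (d_upper is None or b.stats.D < d_upper):
            out.append(b)
    return out


def build_genotype_matrix(
    aln: MultipleAlignment,
    selected: list[AlignedBlock],
    d_threshold: float = -0.5,
) -> tuple[GenotypeMatrix, SelectionReport]:
    """Concatenate selected blocks and keep only gap-free segregating
    columns, each tagged with its (block, alignment-column) source."""
    if not selected:
        raise ValueError("no selected blocks")
    sites: list[tuple[int, int]] = []
    cols: list[np.ndarray] = []
    for b in selected:
        sub = aln.slice_columns(b.start, b.end)
        _, idx = segregating_sites(sub, "exclude_column")
        for c in idx:
            sites.append((b.block_id, b.start + int(c)))
            cols.append(sub.matrix[:, int(c)])
    if not sites:
        raise ValueError("no segregating sites in the selected blocks")
    gm = GenotypeMatrix(
        taxa=list(aln.taxa), sites=sites,
        alleles=np.stack(cols, axis=1),
    )
    report = SelectionReport(
        n_blocks_selected=len(selected),
        total_length=sum(b.length for b in selected),
        n_segregating=gm.n_sites,
        d_threshold=d_threshold,
    )
    return gm, report


def blocks_to_bed(blocks: list[AlignedBlock], path: str | Path,
                  chrom: str = "alignment") -> None:
    lines = [
        f"{chrom}\t{b.start}\t{b.end}\tblock{b.block_id}\t"
        f"{b.stats.D if b.stats.defined else 'NA'}"
        for b in blocks
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def proximal_genes(
    selected: list[AlignedBlock],
    annotations,
    max_distance: int = 1000,
    projection: np.ndarray | None = None,
) -> list[str]:
    """Genes overlapping or within ``max_distance`` bp of any selected block.

    ``annotations`` is a PlastomeRecord or a list of (gene_name, start, end)
    in reference coordinates; ``projection`` maps alignment column ->
    reference bp (required, since alignment and genome coordinates differ
    whenever the alignment contains indel columns).
    """
    if projection is None:
        raise ValueError("a column->reference projection map is required")
    projection = np.asarray(projection)
    if hasattr(annotations, "features"):
        genes = [
            (f.gene_name, f.intervals[0][0], f.intervals[-1][1])
            for f in annotations.features
        ]
    else:
        genes = [(n, int(s), int(e)) for n, s, e in annotations]
    found: dict[str, int] = {}
    for b in selected:
        ref_start = int(projection[b.start])
        ref_end = int(projection[b.end - 1]) + 1
        for name, gs, ge in genes:
            if gs - max_distance < ref_end and ref_start < ge + max_distance:
                if name not in found or gs < found[name]:
                    found[name] = gs
    return [name for name, _ in sorted(found.items(), key=lambda kv: (kv[1], kv[0]))]
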