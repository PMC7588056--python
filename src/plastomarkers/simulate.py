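"""Synthetic plastome-scale data with known ground truth.

The generator produces the three substrates every downstream stage needs:

* a binary species tree with one outgroup and a fixed number of monophyletic
  ingroup clades (the shape of a small plant genus sampled with an
  outgroup);
* a plastome-like whole-genome alignment in which mutations are *placed* on
  tree branches column by column. Constrained regions force most mutations
  onto terminal branches, producing the singleton excess (strongly negative
  Tajima's D) that purifying selection plus an outgroup leaves on conserved
  plastid sequence; neutral regions place mutations proportional to branch
  length, so clades share intermediate-frequency variants and D stays near
  zero;
* orthologous codon-aligned gene sets evolved with separate synonymous and
  nonsynonymous rates, so pairwise Ks grows with path length on the tree.

Mutation placement — not a full substitution-model simulation — is the
mechanism, because the statistics under study are functions of the site
frequency spectrum, not of the substitution process. All randomness flows
from explicit integer seeds; a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import dendropy
import numpy as np

from .alignment import MultipleAlignment

Regime = Literal["neutral", "constrained"]

__all__ = [
    "SpeciesTree",
    "Region",
    "RegionPlan",
    "SimulationTruth",
    "SimulatedGeneSet",
    "SimulatedGeneData",
    "simulate_species_tree",
    "default_region_plan",
    "evolve_alignment",
    "evolve_codon_genes",
]

SPACER = "spacer"


@dataclass
class SpeciesTree:
    """A binary species tree with one outgroup; branch lengths in
    substitutions/site."""

    newick_string: str
    taxa: list[str]
    outgroup_label: str
    is_ultrametric: bool = True

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick_string, schema="newick", preserve_underscores=True
        )


@dataclass
class Region:
    length: int
    regime: Regime
    mutation_rate: float  # expected substitutions/site over the whole tree

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("region length must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.regime not in ("neutral", "constrained"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class RegionPlan:
    regions: list[Region]
    terminal_bias: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.terminal_bias <= 1.0:
            raise ValueError("terminal_bias must lie in [0, 1]")
        if not self.regions:
            raise ValueError("a plan needs at least one region")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.regions)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated alignment."""

    true_tree: SpeciesTree
    region_labels: list[str]  # per-column regime ('neutral'/'constrained'/'spacer')
    seed: int

    def rle(self) -> list[tuple[str, int]]:
        runs: list[tuple[str, int]] = []
        for label in self.region_labels:
            if runs and runs[-1][0] == label:
                runs[-1] = (label, runs[-1][1] + 1)
            else:
                runs.append((label, 1))
        return runs

    def write_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "true_tree_newick": self.true_tree.newick_string,
            "outgroup": self.true_tree.outgroup_label,
            "region_labels_rle": [[lab, n] for lab, n in self.rle()],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def write_bed(self, path: str | Path, chrom: str = "alignment") -> None:
        lines = []
        pos = 0
        for label, n in self.rle():
            lines.append(f"{chrom}\t{pos}\t{pos + n}\t{label}")
            pos += n
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _join_random(rng: np.random.Generator, items: list) -> tuple:
    """Random binary topology over items by iterative pair joining."""
    items = list(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return items[0]


def simulate_species_tree(
    n_ingroup: int,
    n_clades: int,
    depth: float,
    seed: int,
    internal_scale: float = 0.3,
    terminal_scale: float = 0.03,
    outgroup_scale: float = 0.2,
) -> SpeciesTree:
    """Binary tree: ``n_clades`` monophyletic ingroup clades plus one
    outgroup attached at the root; deterministic for a fixed seed.

    Edge lengths (substitutions/site) are drawn i.i.d. as
    ``depth * scale * U(0.5, 1)`` with separate scales for internal and
    ingroup-terminal edges; the outgroup edge is ``depth * outgroup_scale``.
    The defaults make internal edges long relative to terminal ones —
    the shape of a radiation sampled with one representative per species,
    where most coalescent depth lies between clades. Every internal edge
    then carries enough expected mutations to be recoverable, while
    terminal and outgroup edges contribute only a moderate rare-allele
    class. The tree is therefore not ultrametric.
    """
    if n_clades < 1 or n_ingroup < n_clades:
        raise ValueError("require n_ingroup >= n_clades >= 1")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    ingroup = [f"T{i + 1:02d}" for i in range(n_ingroup)]
    outgroup = "OUT"

    # near-equal deterministic clade membership; topology random within
    sizes = [n_ingroup // n_clades + (1 if i < n_ingroup % n_clades else 0)
             for i in range(n_clades)]
    clades, pos = [], 0
    for sz in sizes:
        clades.append(_join_random(rng, ingroup[pos: pos + sz]))
        pos += sz
    ingroup_topo = _join_random(rng, clades)

    def edge_len(node) -> float:
        scale = terminal_scale if isinstance(node, str) else internal_scale
        return depth * scale * rng.uniform(0.5, 1.0)

    def render(node, edge: float) -> str:
        if isinstance(node, str):
            return f"{node}:{edge:.8f}"
        left = render(node[0], edge_len(node[0]))
        right = render(node[1], edge_len(node[1]))
        return f"({left},{right}):{edge:.8f}"

    ing_newick = render(ingroup_topo, edge_len(ingroup_topo))
    newick = f"({ing_newick},{outgroup}:{depth * outgroup_scale:.8f});"
    return SpeciesTree(
        newick_string=newick,
        taxa=ingroup + [outgroup],
        outgroup_label=outgroup,
        is_ultrametric=False,
    )


# ---------------------------------------------------------------------------
# whole-genome alignment
# ---------------------------------------------------------------------------

def default_region_plan(
    total_length: int = 50_000,
    neutral_fraction: float = 0.2,
    n_neutral_regions: int = 4,
    neutral_rate: float = 0.1,
    constrained_rate: float = 0.02,
    terminal_bias: float = 0.95,
) -> RegionPlan:
    """Interleaved constrained/neutral plan: mostly constrained background
    with ``n_neutral_regions`` embedded neutral regions covering
    ``neutral_fraction`` of the alignment."""
    neutral_total = int(round(total_length * neutral_fraction))
    n_constrained = n_neutral_regions + 1
    constrained_total = total_length - neutral_total
    regions: list[Region] = []
    c_len = constrained_total // n_constrained
    n_len = neutral_total // n_neutral_regions
    for i in range(n_neutral_regions):
        regions.append(Region(c_len, "constrained", constrained_rate))
        regions.append(Region(n_len, "neutral", neutral_rate))
    last = total_length - sum(r.length for r in regions)
    regions.append(Region(last, "constrained", constrained_rate))
    return RegionPlan(regions=regions, terminal_bias=terminal_bias)


def _edges(tree: dendropy.Tree, taxa: list[str]):
    """Branches as (leaf-index array below the edge, length, is_terminal)."""
    index = {t: i for i, t in enumerate(taxa)}
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        below = np.array(
            sorted(index[lf.taxon.label] for lf in node.leaf_iter()), dtype=np.int64
        )
        out.append((below, float(length), node.is_leaf()))
    return out


def evolve_alignment(
    tree: SpeciesTree,
    plan: RegionPlan,
    seed: int,
    gap_rate: float = 0.0,
    boundary_gap_run: int = 0,
) -> tuple[MultipleAlignment, SimulationTruth]:
    """Evolve a plastome-like alignment by branch-wise mutation placement.

    Per region, the number of mutations is Poisson with mean
    ``mutation_rate x length``. A constrained-region mutation lands on a
    uniformly chosen *terminal* branch with probability ``terminal_bias``
    (otherwise branch-length-weighted); a neutral-region mutation is always
    branch-length-weighted. Optional ``boundary_gap_run`` all-gap spacer
    columns between regions let gap-density block collection recover the
    region decomposition; ``gap_rate`` sprinkles partial gap columns.
    """
    dtree = tree.tree()
    if len(tree.taxa) < 3:
        raise ValueError("need >= 3 taxa for downstream D computation")
    edges = _edges(dtree, tree.taxa)
    lengths = np.array([e[1] for e in edges])
    if lengths.sum() <= 0:
        raise ValueError("degenerate tree: all branch lengths are zero")
    length_weights = lengths / lengths.sum()
    terminal_idx = [k for k, e in enumerate(edges) if e[2]]

    rng = np.random.default_rng(seed)
    n = len(tree.taxa)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    columns: list[np.ndarray] = []
    labels: list[str] = []
    spacer_col = np.full(n, ord("-"), dtype=np.uint8)

    for ridx, region in enumerate(plan.regions):
        root = rng.choice(bases, size=region.length)
        block = np.tile(root, (n, 1))
        n_mut = rng.poisson(region.mutation_rate * region.length)
        for _ in range(n_mut):
            col = rng.integers(0, region.length)
            if region.regime == "constrained" and rng.random() < plan.terminal_bias:
                k = terminal_idx[rng.integers(0, len(terminal_idx))]
            else:
                k = rng.choice(len(edges), p=length_weights)
            below = edges[k][0]
            current = block[below[0], col]
            alts = bases[bases != current]
            block[below, col] = alts[rng.integers(0, 3)]
        columns.append(block)
        labels.extend([region.regime] * region.length)
        if boundary_gap_run and ridx < len(plan.regions) - 1:
            columns.append(np.tile(spacer_col[:, None], (1, boundary_gap_run)))
            labels.extend([SPACER] * boundary_gap_run)

    matrix = np.concatenate(columns, axis=1)

    if gap_rate > 0:
        L = matrix.shape[1]
        gap_cols = np.flatnonzero(rng.random(L) < gap_rate)
        for col in gap_cols:
            k = 1 + rng.integers(0, max(1, n // 3))
            rows = rng.choice(n, size=k, replace=False)
            matrix[rows, col] = ord("-")

    aln = MultipleAlignment(list(tree.taxa), matrix)
    truth = SimulationTruth(true_tree=tree, region_labels=labels, seed=seed)
    return aln, truth


# ---------------------------------------------------------------------------
# codon genes
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGeneSet:
    """Per-taxon orthologous gene sequences (codon-aligned by construction)."""

    species_id: str
    genes: dict[str, str]


@dataclass
class SimulatedGeneData:
    gene_sets: list[SimulatedGeneSet]
    gene_names: list[str]
    saturation_warnings: list[tuple[str, str]] = field(default_factory=list)

    def write_fasta_dir(self, directory: str | Path) -> None:
        """One codon-alignment FASTA per gene, all taxa."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for gene in self.gene_names:
            lines = []
            for gs in self.gene_sets:
                lines.append(f">{gs.species_id}")
                lines.append(gs.genes[gene])
            (directory / f"{gene}.fasta").write_text("\n".join(lines) + "\n")


def _non_stop_codon_indices():
    from .ks import STOP_CODONS, _CODONS

    return [i for i, c in enumerate(_CODONS) if c not in STOP_CODONS], _CODONS


def evolve_codon_genes(
    tree: SpeciesTree,
    n_genes: int = 57,
    syn_rate: float = 2.0,
    nonsyn_rate: float = 0.4,
    gene_length: int = 300,
    seed: int = 0,
) -> SimulatedGeneData:
    """Evolve orthologous genes by codon substitution with separate
    synonymous and nonsynonymous rates (expected substitutions per
    synonymous / nonsynonymous site per unit branch length).

    No internal stop codons are ever emitted: proposals creating a stop are
    rejected. Pairs whose expected synonymous divergence exceeds the
    Jukes–Cantor correction domain (ps > 0.74) are flagged in
    ``saturation_warnings``.
    """
    if gene_length < 30:
        raise ValueError("gene_length must be >= 30 codons")
    if syn_rate < 0 or nonsyn_rate < 0:
        raise ValueError("rates must be >= 0")
    from .ks import STOP_CODONS, _translate

    rng = np.random.default_rng(seed)
    dtree = tree.tree()
    nt = "ACGT"
    non_stop, codons = _non_stop_codon_indices()
    max_rate = max(syn_rate, nonsyn_rate)

    def mutate(seq: list[str], edge_len: float) -> list[str]:
        seq = list(seq)
        if max_rate == 0 or edge_len <= 0:
            return seq
        n_prop = rng.poisson(edge_len * max_rate * 3 * gene_length)
        for _ in range(n_prop):
            pos = rng.integers(0, 3 * gene_length)
            ci, off = divmod(pos, 3)
            codon = seq[ci]
            alts = [b for b in nt if b != codon[off]]
            mutant = codon[:off] + alts[rng.integers(0, 3)] + codon[off + 1:]
            if mutant in STOP_CODONS:
                continue
            syn = _translate(mutant) == _translate(codon)
            accept_p = (syn_rate if syn else nonsyn_rate) / max_rate
            if rng.random() < accept_p:
                seq[ci] = mutant
        return seq

    gene_names = [f"gene{i + 1:03d}" for i in range(n_genes)]
    per_taxon: dict[str, dict[str, str]] = {t: {} for t in tree.taxa}
    for gene in gene_names:
        root = [codons[non_stop[i]] for i in rng.integers(0, len(non_stop), gene_length)]
        # preorder walk carrying sequences down the tree
        seqs: dict[int, list[str]] = {id(dtree.seed_node): root}
        for node in dtree.preorder_node_iter():
            if node is dtree.seed_node:
                continue
            parent_seq = seqs[id(node.parent_node)]
            child_seq = mutate(parent_seq, node.edge.length or 0.0)
            seqs[id(node)] = child_seq
            if node.is_leaf():
                per_taxon[node.taxon.label][gene] = "".join(child_seq)

    gene_sets = [SimulatedGeneSet(t, per_taxon[t]) for t in tree.taxa]

    warnings: list[tuple[str, str]] = []
    if syn_rate > 0:
        from .trees import tree_distance_matrix

        dm = tree_distance_matrix(dtree)
        for i in range(len(dm.taxa)):
            for j in range(i + 1, len(dm.taxa)):
                if syn_rate * dm.d[i, j] > 0.74:
                    warnings.append((dm.taxa[i], dm.taxa[j]))
    return SimulatedGeneData(
        gene_sets=gene_sets, gene_names=gene_names, saturation_warnings=warnings
    )
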