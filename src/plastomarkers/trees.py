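"""Distance-based phylogenetics: TN93 distances, neighbor joining, UPGMA,
site-resampling bootstrap, and Robinson–Foulds topology comparison.

Trees are DendroPy :class:`~dendropy.Tree` objects throughout, so newick
round-tripping and taxon bookkeeping follow that library's conventions.
The tree *construction* algorithms are implemented here with deterministic
lexicographic tie-breaking, which DendroPy does not guarantee.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import GAP, UNKNOWN

logger = logging.getLogger(__name__)

#: distance reported for saturated (log-domain) TN93 pairs
SATURATION_CAP = 10.0

__all__ = [
    "DistanceMatrix",
    "TN93Components",
    "tn93_distance",
    "tn93_distance_matrix",
    "hamming_distance_matrix",
    "neighbor_joining",
    "upgma",
    "bootstrap_support",
    "robinson_foulds",
    "read_newick",
    "write_newick",
    "bipartitions",
    "tree_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)


@dataclass
class TN93Components:
    """Observed proportions and frequency coefficients of the TN93 distance."""

    P1: float  # purine (A<->G) transition proportion
    P2: float  # pyrimidine (C<->T) transition proportion
    Q: float   # transversion proportion
    gA: float
    gC: float
    gG: float
    gT: float
    usable_sites: int
    saturated: bool = False

    @property
    def gR(self) -> float:
        return self.gA + self.gG

    @property
    def gY(self) -> float:
        return self.gC + self.gT

    @property
    def k1(self) -> float:
        return 2.0 * self.gA * self.gG / self.gR if self.gR > 0 else 0.0

    @property
    def k2(self) -> float:
        return 2.0 * self.gC * self.gT / self.gY if self.gY > 0 else 0.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _as_bytes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8)
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def tn93_distance(seq_a, seq_b) -> tuple[float, TN93Components]:
    """Tamura–Nei (1993) distance between two aligned sequences.

    Gap/'N' positions are removed pairwise; base frequencies are pooled over
    both sequences at the retained sites. A non-positive logarithm argument
    marks the pair saturated and the distance is capped at
    :data:`SATURATION_CAP`.
    """
    a, b = _as_bytes(seq_a), _as_bytes(seq_b)
    if a.size != b.size:
        raise ValueError("sequences must have equal aligned length")
    ok = ~(np.isin(a, (GAP, UNKNOWN)) | np.isin(b, (GAP, UNKNOWN)))
    a, b = a[ok], b[ok]
    m = a.size
    if m == 0:
        raise ValueError("no usable (ungapped) sites in pair")

    A, C, G, T = (ord(x) for x in "ACGT")
    pooled = np.concatenate([a, b])
    freqs = {x: float((pooled == x).sum()) / (2 * m) for x in (A, C, G, T)}
    diff = a != b
    pur = {A, G}
    is_ag = diff & np.isin(a, (A, G)) & np.isin(b, (A, G))
    is_ct = diff & np.isin(a, (C, T)) & np.isin(b, (C, T))
    P1 = float(is_ag.sum()) / m
    P2 = float(is_ct.sum()) / m
    Q = float(diff.sum()) / m - P1 - P2

    comp = TN93Components(
        P1=P1, P2=P2, Q=Q,
        gA=freqs[A], gC=freqs[C], gG=freqs[G], gT=freqs[T],
        usable_sites=m,
    )
    gR, gY, k1, k2 = comp.gR, comp.gY, comp.k1, comp.k2

    d = 0.0
    saturated = False
    # purine-transition term
    if k1 > 0:
        w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
        if w1 <= 0:
            saturated = True
        else:
            d -= k1 * math.log(w1)
    # pyrimidine-transition term
    if k2 > 0:
        w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
        if w2 <= 0:
            saturated = True
        else:
            d -= k2 * math.log(w2)
    # transversion term
    if gR > 0 and gY > 0:
        k3 = 2.0 * (gR * gY - (comp.gA * comp.gG * gY / gR if gR > 0 else 0.0)
                    - (comp.gC * comp.gT * gR / gY if gY > 0 else 0.0))
        w3 = 1.0 - Q / (2.0 * gR * gY)
        if w3 <= 0:
            saturated = True
        elif k3 > 0:
            d -= k3 * math.log(w3)
    elif Q > 0:
        saturated = True

    if saturated:
        comp.saturated = True
        return SATURATION_CAP, comp
    return d, comp


def tn93_distance_matrix(aln) -> DistanceMatrix:
    """All-pairs TN93 distances for a MultipleAlignment."""
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, _ = tn93_distance(aln.matrix[i], aln.matrix[j])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.taxa), d)


def hamming_distance_matrix(gm) -> DistanceMatrix:
    """Pairwise proportion of differing sites over a genotype matrix
    (or any object exposing ``taxa`` plus an ``alleles``/``matrix`` array)."""
    arr = getattr(gm, "alleles", None)
    if arr is None:
        arr = gm.matrix
    arr = np.asarray(arr)
    taxa = list(gm.taxa)
    if len(taxa) < 2:
        raise ValueError("at least 2 taxa required")
    n, L = arr.shape
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1:]).mean(axis=1) if i + 1 < n else []
        for k, val in enumerate(diff, start=i + 1):
            d[i, k] = d[k, i] = float(val)
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def _new_tree(taxa: list[str]) -> tuple[dendropy.Tree, dict[str, dendropy.Node]]:
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    leaves = {}
    for label in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        leaves[label] = node
    return tree, leaves


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining with lexicographic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster label, cluster label) pair, where a cluster is labelled by its
    smallest member taxon. Negative branch lengths are clamped to zero and
    the clamped deficit logged.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")

    tree, leaf_nodes = _new_tree(list(dm.taxa))
    # active clusters: label -> (node, index into working matrix)
    labels = list(dm.taxa)
    nodes = [leaf_nodes[t] for t in labels]
    D = dm.d.astype(float).copy()

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamped negative NJ branch length %.6g to 0", x)
            return 0.0
        return x

    while len(labels) > 3:
        r = len(labels)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if Q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        vi = clamp(D[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2)))
        vj = clamp(D[i, j] - (D[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i]); nodes[i].edge.length = vi
        parent.add_child(nodes[j]); nodes[j].edge.length = vj
        newd = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D = D2
        new_label = min(labels[i], labels[j])
        labels = [labels[k] for k in keep] + [new_label]
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcating join
    root = dendropy.Node()
    if len(labels) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        v0 = clamp((d01 + d02 - d12) / 2.0)
        v1 = clamp((d01 + d12 - d02) / 2.0)
        v2 = clamp((d02 + d12 - d01) / 2.0)
        for node, v in zip(nodes, (v0, v1, v2)):
            root.add_child(node)
            node.edge.length = v
    else:  # pragma: no cover - unreachable for n >= 3
        for node in nodes:
            root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) rooted ultrametric dendrogram."""
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("UPGMA requires >= 2 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")

    tree, leaf_nodes = _new_tree(list(dm.taxa))
    labels = list(dm.taxa)
    nodes = [leaf_nodes[t] for t in labels]
    heights = [0.0] * n
    sizes = [1] * n
    D = dm.d.astype(float).copy()

    while len(labels) > 1:
        r = len(labels)
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        dmin = M.min()
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if M[i, j] <= dmin + 1e-12 * max(1.0, dmin):
                    key = tuple(sorted((labels[i], labels[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        h = D[i, j] / 2.0
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(nodes[k])
            nodes[k].edge.length = max(h - heights[k], 0.0)
        newd = (sizes[i] * D[i, :] + sizes[j] * D[j, :]) / (sizes[i] + sizes[j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        D = D2
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]

    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bipartitions / comparison
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as canonical frozensets of labels.

    Each split is represented by the side *not* containing the
    lexicographically smallest leaf, so representation is orientation-free.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_set = frozenset(leaves)
    ref = leaves[0]
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_set - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Unrooted symmetric-difference (RF) distance and its normalisation by
    the binary-tree maximum 2(n-3)."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    rf = len(b1 ^ b2)
    n = len(l1)
    denom = 2 * (n - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t.label for t in tree.taxon_namespace
                   if any(lf.taxon is t for lf in tree.leaf_node_iter())))
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _build(builder: str, taxa: list[str], arr: np.ndarray) -> dendropy.Tree:
    class _GM:
        pass

    gm = _GM()
    gm.taxa = taxa
    gm.alleles = arr
    dm = hamming_distance_matrix(gm)
    if builder == "nj":
        return neighbor_joining(dm)
    if builder == "upgma":
        return upgma(dm)
    raise ValueError(f"unknown tree builder {builder!r}")


def bootstrap_support(
    gm, builder: str = "nj", n_reps: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """Point-estimate tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of an
    internal bipartition of the point tree is the percentage of replicate
    trees containing it. Replicate ``r`` draws from an independent
    ``default_rng([seed, r])`` substream, so enlarging ``n_reps`` never
    reshuffles earlier replicates. Columns are first put in a canonical
    sort order (by their values over lexicographically sorted taxa) so the
    supports do not depend on input column or taxa order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    arr = np.asarray(getattr(gm, "alleles", None) if hasattr(gm, "alleles") else gm.matrix)
    taxa = list(gm.taxa)
    n, L = arr.shape

    taxa_order = np.argsort(taxa)
    col_keys = [tuple(arr[taxa_order, j]) for j in range(L)]
    canon = sorted(range(L), key=lambda j: col_keys[j])
    arr = arr[:, canon]

    point = _build(builder, taxa, arr)
    point_bips = bipartitions(point) if n > 3 else set()

    counts = {b: 0 for b in point_bips}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, L, size=L)
        rep_tree = _build(builder, taxa, arr[:, idx])
        rep_bips = bipartitions(rep_tree)
        for b in counts:
            if b in rep_bips:
                counts[b] += 1

    all_labels = frozenset(taxa)
    ref = min(taxa)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_reps:g}"
    if L < 2:
        logger.warning("bootstrap on a single-site matrix is low-information")
    return point


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error in {path}: {exc}") from exc


def newick_from_string(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path), schema="newick",
        suppress_rooting=True, unquoted_underscores=True,
    )
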