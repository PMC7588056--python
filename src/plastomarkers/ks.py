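"""Synonymous divergence (Ks) by the Nei–Gojobori (1986) counting method,
per-species-pair Ks distributions, modal-value extraction, and the all-vs-all
modal-Ks divergence matrix.

Conventions (they matter for the numbers):

* Synonymous site counts: for each codon, each of the nine single-nucleotide
  changes contributes 1/3 of a site to the synonymous total if it preserves
  the encoded amino acid. Changes that create a stop codon count as
  nonsynonymous. Per-pair totals average the two sequences.
* Multi-nucleotide codon differences are averaged over all minimal mutational
  pathways; pathways passing through a stop codon are excluded and the
  remaining pathways re-weighted equally. If every pathway passes through a
  stop, all pathways are used.
* Jukes–Cantor correction: Ks = -(3/4)·ln(1 - (4/3)·ps), defined only for
  ps < 3/4 (``valid`` flag otherwise false).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

__all__ = [
    "KsResult",
    "KsDistribution",
    "KsMatrix",
    "pair_codons",
    "ng86_ks",
    "ng86_ks_sequences",
    "pairwise_ks_distribution",
    "modal_ks",
    "ks_distance_matrix",
]

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_CODONS = ["".join(c) for c in itertools.product(_NT, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


def _translate(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return standard_dna_table.forward_table[codon]


@lru_cache(maxsize=1)
def _syn_sites() -> np.ndarray:
    """Per-codon synonymous site counts s_c (64-vector; NaN for stops)."""
    s = np.full(64, np.nan)
    for codon in _CODONS:
        if codon in STOP_CODONS:
            continue
        aa = _translate(codon)
        total = 0.0
        for pos in range(3):
            for alt in _NT:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1:]
                # stop-creating changes are nonsynonymous
                if mutant not in STOP_CODONS and _translate(mutant) == aa:
                    total += 1.0 / 3.0
        s[_CODON_INDEX[codon]] = total
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn diffs, nonsyn diffs) for one codon pair, averaged over minimal
    mutational pathways (stop-free pathways only, when any exist)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    through_stop: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        current = c1
        sd = nd = 0
        hits_stop = False
        for p in order:
            nxt = current[:p] + c2[p] + current[p + 1:]
            if nxt in STOP_CODONS:
                hits_stop = True
            if current in STOP_CODONS or nxt in STOP_CODONS:
                # step to/through a stop cannot be classified synonymous
                nd += 1
            elif _translate(current) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        (through_stop if hits_stop else valid).append((sd, nd))
    chosen = valid if valid else through_stop
    sd = float(np.mean([x[0] for x in chosen]))
    nd = float(np.mean([x[1] for x in chosen]))
    return sd, nd


@lru_cache(maxsize=1)
def _pathway_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 tables of pathway-averaged synonymous/nonsynonymous differences."""
    SD = np.zeros((64, 64))
    ND = np.zeros((64, 64))
    for i, c1 in enumerate(_CODONS):
        if c1 in STOP_CODONS:
            continue
        for j, c2 in enumerate(_CODONS):
            if c2 in STOP_CODONS:
                continue
            SD[i, j], ND[i, j] = _pathway_counts(c1, c2)
    return SD, ND


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class KsResult:
    gene: str
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    n_codons: int
    valid: bool


@dataclass
class KsDistribution:
    """Per-gene Ks values for one species pair."""

    species_pair: tuple[str, str]
    values: list[float]
    n_invalid: int = 0

    def modal(self, method: str = "histogram", bandwidth_or_binwidth: float = 0.005) -> float:
        return modal_ks(self.values, method, bandwidth_or_binwidth)


@dataclass
class KsMatrix:
    """Symmetric modal-Ks divergence matrix (zero diagonal)."""

    taxa: list[str]
    modal: np.ndarray = field(repr=False)
    missing: np.ndarray = field(repr=False)

    def nearest_neighbors(self) -> dict[str, str]:
        """Per taxon, the other taxon at minimal modal Ks (label-lexicographic
        tie-break)."""
        out = {}
        n = len(self.taxa)
        for i, t in enumerate(self.taxa):
            candidates = [
                (self.modal[i, j], self.taxa[j])
                for j in range(n)
                if j != i and not self.missing[i, j]
            ]
            if candidates:
                out[t] = min(candidates)[1]
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.modal, index=self.taxa, columns=self.taxa)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _encode_codons(seq: str) -> np.ndarray:
    """Codon-index array; -1 for codons containing '-', 'N' (or any other
    non-ACGT symbol) and for stop codons."""
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(out.size):
        codon = seq[3 * k: 3 * k + 3]
        if codon in STOP_CODONS or any(c not in _NT_INDEX for c in codon):
            out[k] = -1
        else:
            out[k] = _CODON_INDEX[codon]
    return out


def pair_codons(gene_a: str, gene_b: str) -> list[tuple[str, str]]:
    """Comparable codon pairs from two codon-aligned sequences.

    Pairs containing a gap, 'N', or a stop codon in either member are
    dropped.
    """
    if len(gene_a) != len(gene_b):
        raise ValueError("codon alignments must have equal length")
    a = _encode_codons(gene_a)
    b = _encode_codons(gene_b)
    keep = (a >= 0) & (b >= 0)
    return [(_CODONS[i], _CODONS[j]) for i, j in zip(a[keep], b[keep])]


def _ks_from_indices(a: np.ndarray, b: np.ndarray, gene: str) -> KsResult:
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    if a.size == 0:
        raise ValueError(f"no comparable codon pairs for gene {gene!r}")
    s_c = _syn_sites()
    SD, ND = _pathway_tables()
    syn_sites = float((s_c[a].sum() + s_c[b].sum()) / 2.0)
    nonsyn_sites = 3.0 * a.size - syn_sites
    # canonical orientation: SD/ND are symmetric, and fixing the index order
    # makes ng86_ks(a, b) == ng86_ks(b, a) bitwise exact
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    pair_idx = lo * 64 + hi
    counts = np.bincount(pair_idx, minlength=64 * 64).astype(float)
    syn_diffs = float(counts @ SD.ravel())
    nonsyn_diffs = float(counts @ ND.ravel())
    ps = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else 0.0
    valid = ps < 0.75
    Ks = -0.75 * np.log(1.0 - (4.0 / 3.0) * ps) if valid else float("nan")
    Ka = -0.75 * np.log(1.0 - (4.0 / 3.0) * pn) if pn < 0.75 else float("nan")
    return KsResult(
        gene=gene, syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_diffs, nonsyn_diffs=nonsyn_diffs,
        ps=ps, pn=pn, Ks=float(Ks), Ka=float(Ka),
        n_codons=int(a.size), valid=bool(valid),
    )


def ng86_ks(pairs: list[tuple[str, str]], gene: str = "") -> KsResult:
    """NG86 quantities from an explicit codon-pair list."""
    if not pairs:
        raise ValueError("at least one codon pair is required")
    a = np.array([_CODON_INDEX[p[0].upper()] for p in pairs])
    b = np.array([_CODON_INDEX[p[1].upper()] for p in pairs])
    return _ks_from_indices(a, b, gene)


def ng86_ks_sequences(gene_a: str, gene_b: str, gene: str = "") -> KsResult:
    """NG86 quantities straight from two codon-aligned sequences."""
    if len(gene_a) != len(gene_b):
        raise ValueError("codon alignments must have equal length")
    return _ks_from_indices(_encode_codons(gene_a), _encode_codons(gene_b), gene)


def _gene_map(gene_set) -> dict[str, str]:
    return gene_set.genes if hasattr(gene_set, "genes") else dict(gene_set)


def _species_label(gene_set, fallback: str) -> str:
    return getattr(gene_set, "species_id", fallback)


def pairwise_ks_distribution(genes_a, genes_b, shared: list[str]) -> KsDistribution:
    """One Ks value per shared orthologous gene for a species pair.

    Invalid (saturated) results are excluded with a logged count; zero valid
    genes is an error.
    """
    ga, gb = _gene_map(genes_a), _gene_map(genes_b)
    missing = [g for g in shared if g not in ga or g not in gb]
    if missing:
        raise KeyError(f"shared genes absent from a gene set: {missing}")
    values: list[float] = []
    n_invalid = 0
    for gene in shared:
        res = ng86_ks_sequences(ga[gene], gb[gene], gene)
        if res.valid:
            values.append(res.Ks)
        else:
            n_invalid += 1
    pair = (_species_label(genes_a, "a"), _species_label(genes_b, "b"))
    if n_invalid:
        logger.info("pair %s: %d saturated gene(s) excluded", pair, n_invalid)
    if not values:
        raise ValueError(f"no valid Ks values for pair {pair}")
    return KsDistribution(species_pair=pair, values=values, n_invalid=n_invalid)


def modal_ks(
    values: list[float], method: str = "histogram", bandwidth_or_binwidth: float = 0.005
) -> float:
    """Peak of a Ks distribution.

    histogram: midpoint of the highest-count bin, leftmost on ties, bins of
    the given width anchored at 0. kde: argmax of a Gaussian KDE (absolute
    bandwidth) on a 512-point grid spanning [0, max].
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty Ks value list")
    if np.allclose(vals, vals[0]):
        return float(vals[0])
    if method == "histogram":
        bw = bandwidth_or_binwidth
        edges = np.arange(0.0, vals.max() + bw, bw)
        if edges[-1] <= vals.max():
            edges = np.append(edges, edges[-1] + bw)
        counts, _ = np.histogram(vals, bins=edges)
        best = int(np.argmax(counts))  # argmax returns leftmost maximum
        return float((edges[best] + edges[best + 1]) / 2.0)
    if method == "kde":
        if vals.size < 5:
            raise ValueError("kde modal extraction requires >= 5 values")
        from scipy.stats import gaussian_kde

        std = vals.std(ddof=1)
        factor = bandwidth_or_binwidth / std if std > 0 else 1.0
        kde = gaussian_kde(vals, bw_method=factor)
        grid = np.linspace(0.0, vals.max(), 512)
        return float(grid[int(np.argmax(kde(grid)))])
    raise ValueError(f"unknown modal method {method!r}")


def ks_distance_matrix(
    gene_sets: list,
    shared: list[str],
    method: str = "histogram",
    bandwidth_or_binwidth: float = 0.005,
) -> KsMatrix:
    """All-vs-all modal-Ks matrix over >= 3 taxa.

    Pairs with an empty valid-Ks distribution are flagged missing rather
    than failing the whole matrix.
    """
    if len(gene_sets) < 3:
        raise ValueError("at least 3 taxa are required")
    taxa = [_species_label(gs, f"taxon_{i}") for i, gs in enumerate(gene_sets)]
    n = len(taxa)
    modal = np.zeros((n, n))
    missing = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dist = pairwise_ks_distribution(gene_sets[i], gene_sets[j], shared)
            except ValueError:
                missing[i, j] = missing[j, i] = True
                modal[i, j] = modal[j, i] = float("nan")
                continue
            m = modal_ks(dist.values, method, bandwidth_or_binwidth)
            modal[i, j] = modal[j, i] = m
    return KsMatrix(taxa=taxa, modal=modal, missing=missing)
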