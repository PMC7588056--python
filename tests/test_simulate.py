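"""Synthetic plastome generator: determinism, clade structure, regime
separation and codon-gene contracts."""

import numpy as np
import pytest

from plastomarkers.popgen import segregating_sites, tajimas_d
from plastomarkers.simulate import (Region, RegionPlan, default_region_plan,
                                    evolve_alignment, evolve_codon_genes,
                                    simulate_species_tree)


def _clade_sets(n_ingroup, n_clades):
    sizes = [n_ingroup // n_clades + (1 if i < n_ingroup % n_clades else 0)
             for i in range(n_clades)]
    out, pos = [], 0
    for sz in sizes:
        out.append({f"T{i + 1:02d}" for i in range(pos, pos + sz)})
        pos += sz
    return out


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def test_seventeen_taxon_tree_has_four_monophyletic_clades():
    st = simulate_species_tree(16, 4, 0.05, seed=1)
    assert len(st.taxa) == 17 and st.outgroup_label == "OUT"
    tree = st.tree()
    from plastomarkers.trees import bipartitions

    bips = bipartitions(tree)
    for clade in _clade_sets(16, 4):
        assert frozenset(clade) in bips, f"clade {sorted(clade)} not monophyletic"
    # binary: unrooted n-taxon binary tree has n-3 internal bipartitions
    assert len(bips) == 17 - 3


def test_minimal_two_taxon_tree():
    st = simulate_species_tree(1, 1, 0.05, seed=1)
    assert sorted(st.taxa) == ["OUT", "T01"]
    assert len(list(st.tree().leaf_node_iter())) == 2


def test_tree_parameter_validation():
    with pytest.raises(ValueError):
        simulate_species_tree(3, 4, 0.05, seed=1)
    with pytest.raises(ValueError):
        simulate_species_tree(4, 2, -1.0, seed=1)


def test_tree_deterministic_for_seed():
    a = simulate_species_tree(16, 4, 0.05, seed=7)
    b = simulate_species_tree(16, 4, 0.05, seed=7)
    assert a.newick_string == b.newick_string
    c = simulate_species_tree(16, 4, 0.05, seed=8)
    assert a.newick_string != c.newick_string


def test_branch_lengths_nonnegative():
    tree = simulate_species_tree(16, 4, 0.05, seed=3).tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0


# ---------------------------------------------------------------------------
# alignment evolution
# ---------------------------------------------------------------------------

def test_zero_rate_region_gives_invariant_alignment():
    st = simulate_species_tree(6, 2, 0.05, seed=1)
    plan = RegionPlan([Region(1000, "neutral", 0.0)])
    aln, truth = evolve_alignment(st, plan, seed=1)
    S, _ = segregating_sites(aln)
    assert S == 0 and aln.length == 1000
    assert truth.region_labels == ["neutral"] * 1000


def test_same_seed_identical_fasta_bytes(tmp_path):
    st = simulate_species_tree(8, 2, 0.05, seed=2)
    plan = default_region_plan(5000)
    for run in ("a", "b"):
        aln, _ = evolve_alignment(st, plan, seed=42, boundary_gap_run=5)
        aln.write_fasta(tmp_path / f"{run}.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_degenerate_zero_length_tree_rejected():
    st = simulate_species_tree(4, 2, 0.05, seed=1)
    zeroed = st.newick_string
    import re

    zeroed = re.sub(r":\d+\.\d+", ":0.00000000", zeroed)
    st_zero = type(st)(newick_string=zeroed, taxa=st.taxa,
                       outgroup_label=st.outgroup_label)
    with pytest.raises(ValueError, match="degenerate"):
        evolve_alignment(st_zero, RegionPlan([Region(100, "neutral", 0.1)]), seed=1)


def test_region_plan_validation():
    with pytest.raises(ValueError):
        Region(0, "neutral", 0.1)
    with pytest.raises(ValueError):
        Region(10, "weird", 0.1)
    with pytest.raises(ValueError):
        RegionPlan([Region(10, "neutral", 0.1)], terminal_bias=1.5)


def test_truth_rle_roundtrip(tmp_path):
    st = simulate_species_tree(6, 2, 0.05, seed=1)
    plan = default_region_plan(2000, n_neutral_regions=2)
    _, truth = evolve_alignment(st, plan, seed=9, boundary_gap_run=3)
    assert sum(n for _, n in truth.rle()) == len(truth.region_labels)
    truth.write_json(tmp_path / "truth.json")
    truth.write_bed(tmp_path / "truth.bed")
    import json

    payload = json.loads((tmp_path / "truth.json").read_text())
    assert payload["seed"] == 9
    assert sum(n for _, n in payload["region_labels_rle"]) == len(truth.region_labels)


def test_constrained_regions_have_lower_d_than_neutral():
    """Terminal-biased mutation placement produces a singleton excess:
    constrained-region D is below neutral-region D in >= 95% of 20 seeds."""
    separated = 0
    for seed in range(20):
        st = simulate_species_tree(16, 4, 0.05, seed=seed)
        plan = default_region_plan(10_000)
        aln, truth = evolve_alignment(st, plan, seed=200 + seed)
        labels = np.asarray(truth.region_labels)
        d = {}
        for regime in ("constrained", "neutral"):
            sub = aln.take_columns(np.flatnonzero(labels == regime))
            d[regime] = tajimas_d(sub).D
        if d["constrained"] < d["neutral"]:
            separated += 1
    assert separated >= 19


def test_neutral_columns_alone_recover_topology():
    """10 kb of neutral sequence carries enough clade-shared variation for
    NJ to recover the true topology (RF = 0) in >= 90% of 20 seeds."""
    from plastomarkers.trees import (hamming_distance_matrix,
                                     neighbor_joining, robinson_foulds)

    recovered = 0
    for seed in range(20):
        st = simulate_species_tree(16, 4, 0.02, seed=seed)
        plan = RegionPlan([Region(10_000, "neutral", 0.1)])
        aln, _ = evolve_alignment(st, plan, seed=300 + seed)
        nj = neighbor_joining(hamming_distance_matrix(aln))
        rf, _ = robinson_foulds(nj, st.tree())
        if rf == 0:
            recovered += 1
    assert recovered >= 18


def test_gap_injection_produces_gaps():
    st = simulate_species_tree(6, 2, 0.05, seed=1)
    plan = RegionPlan([Region(2000, "neutral", 0.05)])
    aln, _ = evolve_alignment(st, plan, seed=4, gap_rate=0.05)
    assert (aln.matrix == ord("-")).any()


# ---------------------------------------------------------------------------
# codon genes
# ---------------------------------------------------------------------------

def test_zero_rates_identical_genes_ks_zero():
    from plastomarkers.ks import ng86_ks_sequences

    st = simulate_species_tree(4, 2, 0.05, seed=1)
    gd = evolve_codon_genes(st, n_genes=3, syn_rate=0.0, nonsyn_rate=0.0,
                            gene_length=40, seed=1)
    ref = gd.gene_sets[0]
    for gs in gd.gene_sets[1:]:
        for gene in gd.gene_names:
            assert gs.genes[gene] == ref.genes[gene]
    res = ng86_ks_sequences(ref.genes["gene001"], gd.gene_sets[1].genes["gene001"])
    assert res.Ks == 0.0


def test_no_internal_stop_codons_emitted():
    from Bio.Seq import Seq

    st = simulate_species_tree(8, 2, 0.05, seed=3)
    gd = evolve_codon_genes(st, n_genes=5, syn_rate=3.0, nonsyn_rate=1.0,
                            gene_length=60, seed=3)
    for gs in gd.gene_sets:
        for seq in gs.genes.values():
            protein = str(Seq(seq).translate())
            assert "*" not in protein


def test_gene_simulation_deterministic():
    st = simulate_species_tree(5, 2, 0.05, seed=1)
    g1 = evolve_codon_genes(st, n_genes=4, gene_length=50, seed=11)
    g2 = evolve_codon_genes(st, n_genes=4, gene_length=50, seed=11)
    for a, b in zip(g1.gene_sets, g2.gene_sets):
        assert a.genes == b.genes


def test_gene_length_validation():
    st = simulate_species_tree(4, 2, 0.05, seed=1)
    with pytest.raises(ValueError):
        evolve_codon_genes(st, gene_length=10, seed=1)


def test_saturation_warning_for_extreme_rates():
    st = simulate_species_tree(6, 2, 0.5, seed=1)
    gd = evolve_codon_genes(st, n_genes=2, syn_rate=10.0, nonsyn_rate=1.0,
                            gene_length=40, seed=1)
    assert gd.saturation_warnings


def test_sister_modal_ks_below_distant_over_seeds():
    """Modal Ks orders sister pairs below distant pairs (Monte-Carlo over
    10 seeds)."""
    from plastomarkers.ks import pairwise_ks_distribution
    from plastomarkers.trees import tree_distance_matrix

    wins = 0
    for seed in range(10):
        st = simulate_species_tree(8, 2, 0.05, seed=seed)
        gd = evolve_codon_genes(st, n_genes=57, syn_rate=2.0, nonsyn_rate=0.4,
                                gene_length=200, seed=seed)
        dm = tree_distance_matrix(st.tree())
        idx = {t: i for i, t in enumerate(dm.taxa)}
        sets = {gs.species_id: gs for gs in gd.gene_sets}
        focal = "T01"
        others = [t for t in st.taxa if t != focal]
        sister = min(others, key=lambda t: dm.d[idx[focal], idx[t]])
        distant = max(others, key=lambda t: dm.d[idx[focal], idx[t]])
        m_sis = pairwise_ks_distribution(sets[focal], sets[sister],
                                         gd.gene_names).modal()
        m_far = pairwise_ks_distribution(sets[focal], sets[distant],
                                         gd.gene_names).modal()
        if m_sis < m_far:
            wins += 1
    assert wins >= 9


def test_gene_fasta_dir_roundtrip(tmp_path):
    st = simulate_species_tree(4, 2, 0.05, seed=1)
    gd = evolve_codon_genes(st, n_genes=3, gene_length=40, seed=2)
    gd.write_fasta_dir(tmp_path / "genes")
    from plastomarkers.pipeline import _load_gene_dir

    gene_sets, gene_names = _load_gene_dir(tmp_path / "genes")
    assert gene_names == gd.gene_names
    by_id = {gs.species_id: gs for gs in gene_sets}
    for gs in gd.gene_sets:
        assert by_id[gs.species_id].genes == gs.genes
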