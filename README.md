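# plastomarkers

Tools for finding short plastid genomic regions whose variation is rich
enough — and neutral enough — to recapitulate a whole-plastome species
phylogeny, so that a few hundred base pairs can stand in for an entire
~150 kb chloroplast genome when classifying closely related plant species.

The motivating setting is a small genus (one outgroup, a handful of
clades, one plastome per species) where a full Bayesian species tree from
dozens of single-copy plastid genes exists, and the question is: *which
short sub-genomic regions, selected by a population-genetic neutrality
statistic, reproduce that tree?*

## What it computes

**Window/block diversity statistics.** For an alignment of n sequences,
segregating sites S (gapped columns excluded), nucleotide diversity
π (mean pairwise difference), Watterson's estimator θ_W = S/a₁ with
a₁ = Σ_{i=1}^{n−1} 1/i, and Tajima's statistic

    D = (π − S/a₁) / sqrt(e₁·S + e₂·S·(S−1))

with the standard variance constants. On a plastome alignment that
includes an outgroup, conserved regions accumulate variation mainly on
terminal branches, so D sits well below −1 almost everywhere; the few
well-aligned blocks with **D > −0.5** carry intermediate-frequency,
clade-shared variants and are selected as candidate marker regions. Their
gap-free segregating sites form a taxa × sites genotype matrix, from which
hierarchical clustering (UPGMA) and neighbor-joining trees (TN93 or
Hamming distances, site-resampling bootstrap) are built and compared with
the reference tree by Robinson–Foulds distance.

**Modal-Ks divergence classification.** For every species pair, per-gene
synonymous divergence is estimated over orthologous codon-aligned genes by
the Nei–Gojobori (1986) counting method with Jukes–Cantor correction,
Ks = −(3/4)·ln(1 − (4/3)·p_s); the peak (modal value) of the per-pair Ks
distribution proxies relative divergence time, and the all-vs-all
triangular modal-Ks matrix exposes problematic species complexes as
near-zero off-diagonal entries.

**Plastid GenBank curation.** CDS features are spliced and
strand-resolved; sequences with internal stop codons are masked to 'N',
genes missing a proper start/stop are removed, and the cross-species
intersection keeps genes present in exactly one intact, N-free copy
everywhere. The quadripartite LSC/IRb/SSC/IRa structure is located as the
longest pair of disjoint, exactly reverse-complementary repeats on the
circular genome, and assembly summary tables (with the conventional
two-decimal mean row) are emitted.

**Synthetic plastome simulator.** Because the statistics above are
functions of the site-frequency spectrum, the package ships a generator
that *places* mutations on a known species tree column by column:
constrained regions force mutations onto terminal branches (singleton
excess, strongly negative D), neutral regions place them proportional to
branch length (clade-shared variants, D near 0). Orthologous codon genes
evolve with separate synonymous/nonsynonymous rates. Every downstream
stage is therefore testable against exact ground truth with no external
data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each writes its tables under `results/`:

```sh
python analysis/01_simulate_plastomes.py
python analysis/02_scan_and_select.py
python analysis/03_genotype_trees.py
python analysis/04_ks_classification.py
python analysis/05_assembly_summary.py
```

Output of scripts 02–04 (seed 42):

```
496 windows; D range [-2.37, 0.48], median -2.03 — most of the genome shows
the strong rare-allele excess expected under constraint + outgroup
4/9 well-aligned blocks pass Tajima's D > -0.5
selected regions: 10000 bp total, 961 segregating sites
100.0% of the selected segregating sites fall in truth-neutral regions
NJ tree with 1000 bootstraps: 14/14 internal edges with support >= 95%
RF(NJ genotype tree, true tree) = 0 (identical topology)
modal Ks over 136 pairs: min 0.003, median 0.113, max 0.173
nearest neighbor by modal Ks equals the true sister for 12/12 taxa
```

Reading this: the genome-wide Tajima's D distribution is strongly negative
(median −2.0), exactly the regime in which a −0.5 threshold isolates the
neutral regions; the four selected blocks contain only truth-neutral
segregating sites; the tree built from those sites alone is topologically
identical (RF = 0) to the true 17-taxon tree with full bootstrap support;
and modal Ks correctly pairs every species with its true sister.

The same stages are available as a CLI (`plastomarkers simulate | scan |
select | genotype | tree | ks | compare | run-all`) for use on real data:
a whole-plastome alignment FASTA, per-gene codon alignments, a reference
newick tree and GenBank records.

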