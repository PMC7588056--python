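# Methods

## Statistics

**Tajima's D.** Computed from segregating sites S and the mean pairwise
difference count π with the standard constants (a₁, a₂, b₁, b₂, c₁, c₂,
e₁, e₂); all of them are returned alongside D so any value can be audited.
Two deliberate conventions:

* Under the default `exclude_column` gap policy, a column containing '-'
  or 'N' anywhere is dropped before anything is counted. This matches
  counting segregating sites "excluding gaps" on a whole-genome alignment
  and keeps n constant across columns. A `pairwise` policy (per-pair
  deletion) exists for sensitivity analysis.
* S = 0 makes D **undefined**, not zero. A window of invariant sequence
  carries no frequency-spectrum information; reporting 0 would fake a
  neutral signal, and undefined-D blocks are never selectable.

π is reported per usable site for plots and per-count inside the D
formula; both are exposed.

**Window scan defaults** are 500-column windows stepped by 100, windows
flagged unavailable above 20% gap fraction or below 100 usable columns.
No canonical values exist for these; they are configurable everywhere and
echoed into every output header.

**Block collection.** "Well-aligned blocks" are maximal runs of columns
whose per-column gap/'N' fraction is ≤ 0.1, at least 150 columns long.
This is a deliberate simplification of multi-genome alignment block
decomposition: on a single MSA, gap density is the only available
alignment-quality signal. Selection keeps blocks with defined D strictly
greater than −0.5 (an optional upper bound +0.5 implements the symmetric
|D| < 0.5 variant, off by default). The outgroup is included in the D
computation by default, which shifts the whole D distribution negative —
that shift is what makes the −0.5 threshold discriminating.

**NG86 Ks.** Synonymous site counts: per codon, each of the nine
single-nucleotide changes contributes 1/3 site to the synonymous total if
it preserves the amino acid; changes creating a stop codon count as
nonsynonymous. Multi-nucleotide codon differences are averaged over all
minimal mutational pathways, excluding pathways through stop codons and
re-weighting the rest equally (if every pathway passes through a stop, all
are used). Ks = −(3/4)·ln(1 − (4/3)·p_s), undefined for p_s ≥ 3/4
(`valid=False`, excluded from distributions with a logged count). Codon
pairs are processed in a canonical orientation so Ks(a,b) equals Ks(b,a)
bitwise. The per-codon site vector and the 64×64 pathway tables are
precomputed once, making a 57-gene × 136-pair matrix a few seconds of
work.

**Modal Ks** defaults to a histogram with 0.005-wide bins anchored at 0,
midpoint of the highest bin, leftmost on ties; a Gaussian-KDE mode
(absolute bandwidth, 512-point grid on [0, max]) is available. The
histogram rule is simple, deterministic and adequate at the divergence
scale the simulator produces (modal values 0.003–0.17); at much lower
divergence the peak of a Ks distribution legitimately sits in the zero
bin and modal comparison loses resolution — a property of the estimand,
not of the estimator.

**TN93 distance** uses the closed form with the two transition classes
and pooled empirical base frequencies per pair, pairwise deletion of
gapped sites. Non-positive logarithm arguments flag the pair saturated
and cap the distance at 10 substitutions/site.

**Tree building.** Neighbor joining and UPGMA are implemented here (not
delegated) because reproducibility requires deterministic tie-breaking:
ties in the Q criterion / minimum distance are resolved by the
lexicographically smallest cluster-label pair, a cluster being labelled by
its smallest member taxon. Negative NJ branch lengths are clamped to zero
with the deficit logged. Distance methods stand in for a full
maximum-likelihood search: the quantity under test is topology
recapitulation (Robinson–Foulds distance), which NJ attains on this data
regime, and ML search is out of scope. Bootstrap replicates resample
columns with replacement; replicate r draws from an independent
`default_rng([seed, r])` substream so increasing the replicate count
never reshuffles earlier replicates, and columns are canonically sorted
first so supports are invariant to input column and taxa order. Newick
I/O, the tree container and the RF comparison are DendroPy's; RF is
cross-checked in the tests by an independent bipartition-set oracle.

## The synthetic generator

The generator's purpose is ground truth for the site-frequency-spectrum
statistics, so it **places mutations** rather than simulating a full
substitution process:

* **Species tree.** n_clades monophyletic clades over n_ingroup taxa plus
  one outgroup at the root. Edge lengths are i.i.d. `depth·s·U(0.5,1)`
  with s = 0.3 for internal edges, 0.03 for ingroup terminal edges, and
  an outgroup edge of 0.2·depth (defaults; depth 0.05
  substitutions/site). Long-internal/short-terminal is the shape of a
  radiation sampled with one individual per species; it also guarantees
  every internal edge an expected mutation count high enough to be
  recoverable, and keeps the rare-allele classes (terminal + outgroup
  edges, ≈ 1/3 of total tree length) large enough to be realistic but not
  so large that neutral regions drop below the −0.5 selection threshold.
  The tree is not ultrametric.
* **Alignment.** Per region, Poisson(rate × length) mutations. A
  constrained-region mutation lands on a uniformly chosen terminal branch
  with probability `terminal_bias` (default 0.95) — the singleton excess
  of purifying selection — otherwise, and always for neutral regions,
  branches are chosen proportional to length. Defaults: 50 kb total, 20%
  neutral in 4 regions, neutral rate 0.1 and constrained rate 0.02
  expected substitutions/site over the tree. The neutral rate mirrors the
  segregating-site density of real selected marker regions (on the order
  of 10% of columns); the constrained background is sparser, as conserved
  plastid sequence is. Optional all-gap spacer columns between regions
  let gap-density block collection recover the region decomposition; an
  optional `gap_rate` sprinkles partial gap columns to exercise
  gap-handling paths.
* **Codon genes.** Root codons uniform over the 61 sense codons;
  along each edge, Poisson-many single-nucleotide proposals are accepted
  with probability proportional to the synonymous or nonsynonymous rate
  (2.0 and 0.4 per site per unit branch length by default), and proposals
  creating stops are always rejected — no internal stop is ever emitted.
  Expected pairwise Ks therefore grows with path length (≈ syn_rate ×
  patristic distance).

What the generator does **not** emulate: among-site rate heterogeneity,
indel evolution, recombination, IR-mediated structural change, base
composition bias, and alignment error beyond uniform gap injection.
Passing tests therefore show that the selection logic isolates
frequency-spectrum signal under controlled conditions; they do not certify
performance on alignments whose main pathology is misalignment rather
than selection.

## Curation and structure detection

Start codons accepted: ATG and GTG (GTG starts occur in plastid genes);
the set is configurable. Internal stops are masked codon-wise to 'NNN';
genes with bad frame or missing start/terminal stop are removed but keep a
flag; duplicated (normalized-name) genes are flagged `multi_copy`. Gene
name matching is case-insensitive and strips numeric locus-tag suffixes.
Curation is idempotent: re-curating a curated set changes nothing.

The quadripartite structure is the longest pair of disjoint, exactly
reverse-complementary repeats on the circular sequence, found by binary
search over repeat length with rolling-hash candidate generation and
byte-exact verification; the longer single-copy interval is LSC, and the
repeat copy immediately following it is IRb. Among equal-length maximal
pairs the one minimizing the LSC start is chosen (deterministic).
Intervals are 0-based half-open on the circle and invariant (in length)
under rotation. Coordinates are 0-based half-open throughout the package;
GenBank's 1-based closed convention exists only at the file boundary.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script use 17 taxa × ~50 kb
alignments (20 replicates) and 57 genes × 300 codons (10 replicates) —
large enough that every internal edge of the tree is sampled and modal-Ks
histograms are stable, small enough to run in seconds per replicate.
Floating-point equality in tests is asserted at 1e−12 against enumeration
oracles and 1e−9 against independent formula implementations. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
there is no global random state, and fixed seeds reproduce byte-identical
FASTA/TSV/JSON artifacts (run reports exclude wall-clock timings from the
determinism contract).

## Known limitations

* Real-data mode consumes a precomputed whole-plastome alignment; no
  aligner is bundled, and alignment quality directly drives block
  collection.
* The −0.5 D threshold is a fixed convention, not an estimated quantity;
  on alignments without an outgroup the whole D distribution shifts and
  the threshold's discrimination changes accordingly (an
  exclude-outgroup mode exists for exactly this sensitivity check).
* Using Tajima's D across species violates its single-population sampling
  assumptions; the statistic is used here as a frequency-spectrum
  *filter*, not as a test with calibrated significance.
* The modal-Ks histogram rule returns bin midpoints; uncertainty in the
  peak location is not quantified.
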