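# Methods

`otukit` implements the downstream half of a 16S amplicon community
analysis: everything after OTU picking.  Its inputs are a taxon × sample
count table, a taxonomy table (phylum and genus), and per-sample metadata
(habitat ∈ {water, sediment, intestine}; breeding mode ∈ {MC, RC};
replicate).  This note records the models, conventions, and design choices,
and what the synthetic-data tests do and do not demonstrate.

## Depth normalisation

Sequencing effort is uneven, so counts are subsampled ("rarefied") to a
common depth — by default the smallest per-sample total.  Subsampling is a
single draw *without replacement* from each sample's reads (multivariate
hypergeometric), the dominant convention for "normalising to the least
sequence number".  Consequences the tests rely on: every column sums
exactly to the target depth, no taxon count ever increases, and the
per-taxon expectation and variance follow the hypergeometric law.  The draw
is seeded; the pipeline derives the seed from its master seed.

## Alpha diversity

Per sample, on rarefied counts:

* observed richness S_obs and Good's coverage 1 − F₁/N (F₁ singletons, N
  reads);
* Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)) — the bias-corrected denominator is
  defined even when doubletons are absent;
* ACE with rare/abundant cutoff at 10 reads and the coefficient-of-variation
  correction γ²; when every rare read is a singleton the coverage term
  C_ace is zero and the estimator falls back to Chao1, flagged in the
  output record;
* Shannon H′ = −Σ pᵢ ln pᵢ (natural log; a `base` argument covers log₂
  conventions);
* Simpson reported as **dominance** D = Σ nᵢ(nᵢ−1)/(N(N−1)) — lower is more
  diverse.  This is the variant consistent with diversity being highest
  where D is smallest.

The log base for Shannon and the Simpson variant are package conventions,
documented here rather than inherited facts.  Group comparisons default to
pairwise Student's t-tests with the star scheme * 0.01<P≤0.05,
** 0.001<P≤0.01, *** P≤0.001; one-way ANOVA and Kruskal–Wallis (midranks
with tie correction) are available.  Groups that are entirely constant and
equal return statistic 0, p = 1 by contract.

## Beta diversity

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) on rarefied counts.
PCoA eigendecomposes the Gower-centred −½D² matrix; negative eigenvalues
are reported unaltered (no Lingoes/Cailliez correction) and excluded from
the proportion-explained denominator; axis signs are fixed by making each
axis's largest-magnitude coordinate positive.  UPGMA uses unweighted
average linkage with merge heights equal to *half* the between-cluster mean
distance (ultrametric leaf-to-root depths) and a lexicographic tie-break on
sorted leaf labels, which makes the tree fully deterministic; it is O(n³)
and intended for tens of samples.

ANOSIM uses R = (r̄_between − r̄_within)/(n(n−1)/4) with midranks for tied
distances, so R = 1 under complete separation and R ∈ [−1, 1] always.
One-factor PERMANOVA (Adonis) partitions Σd²/n into within/between parts
and reports pseudo-F and R².  Both tests use seeded label permutations with
the +1-smoothed p = (1 + #{permuted ≥ observed})/(n_perm + 1); at 999
permutations the floor is 0.001.

**Stratified permutations.** Both tests accept a `strata` argument that
restricts shuffling to within-block relabelings.  This matters whenever the
tested factor is balanced within blocks by design: testing breeding mode on
the full three-habitat design with free permutations is badly conservative,
because random relabelings align with the dominant habitat structure more
than the observed (balanced) labeling ever can.  The null-calibration test
therefore stratifies the mode test by habitat; the pipeline's report keeps
the four-row layout (one three-habitat contrast plus the three
within-habitat mode contrasts).

## Composition summaries

Counts aggregate to a taxonomy rank by exact integer summation (per-sample
totals conserved).  "Others" binning merges taxa whose dataset-wide *mean*
relative abundance falls below 1% (per-sample binning would fragment the
legend; the rule is configurable).  Percentages print at 2 decimals,
round-half-even.  Top-N selection orders by total count with lexicographic
tie-break, so the selection is stable across runs.

## Bipartite genus–environment network

Genera with ≥ 5 total reads link to each of the six sample groups
(mode × habitat) where they have at least one read.  Collapsing MC/RC, each
genus's environment set maps to one of seven clusters: 1 intestine-only,
2 intestine+water, 3 all three, 4 intestine+sediment, 5 water+sediment,
6 water-only, 7 sediment-only.  (Which of 6/7 is water-only is an arbitrary
fixed convention; the one/two/three-environment summaries are invariant to
it.)  Membership is presence-based, not abundance-weighted.

## Spearman co-correlation network

Node pre-filter: the 100 most abundant genera present in ≥ 4 samples (the
published 95-node network implies some unstated pre-filter; this one is a
documented reproduction caveat, and both knobs are configurable).  Spearman
ρ is Pearson on midranks; two-sided p from the t-approximation with n−2 df
(p = 0 at ρ = ±1); constant taxa are flagged and excluded.  Edges keep
ρ ≥ 0.75 (inclusive, positive-only by default — an `absolute` mode admits
negative edges) and raw p < 0.05; no multiple-testing correction by default,
with Benjamini–Hochberg available upstream of the filter if desired.  The
node set is exactly the retained edges' endpoints.

Metrics: local clustering C = 2T/(k(k−1)) (0 for degree < 2), average
clustering over all nodes, transitivity 3·triangles/triples, Brandes
betweenness (unnormalised, endpoints excluded), diameter and average path
length over the largest connected component.  Modules come from seeded
Louvain-style multilevel detection at resolution 1.0, with modularity
Q = Σ_c(e_c/m − (d_c/2m)²) of the returned partition.  Each node is
labelled with the habitat of its maximal mean relative abundance (ties fall
to water < sediment < intestine and are flagged); modules take the majority
label.  Hubs rank by betweenness, then degree, then name.

## Synthetic data generator

The generator emulates the 18-sample design: 3 habitats × 2 modes × 3
replicates, depths uniform on 33,000–45,000 reads, 240 taxa by default
(3 × 40 habitat-signature + 120 shared).  Per sample it draws a latent
Gaussian vector with equicorrelated blocks (one block per habitat's
signature set, pairwise latent correlation 0.9), exponentiates with
log-mean offsets, closes to proportions, and draws a multinomial at the
sample's depth.  Because exp() is monotone the latent rank structure
survives, so Spearman-based recovery of the planted blocks is well-posed.

Parameters that matter:

* `habitat_effect_logfold` (default 3.0, natural log): separation of a
  signature taxon's mean between home and away habitats.  Chosen for
  testability — it makes the habitat contrast essentially saturate
  (ANOSIM R ≈ 1, p at the permutation floor) the way a strong real
  habitat effect does.
* `mode_effect_logfold` (default 0.0): the null, matching the study design
  this emulates.  When non-zero it shifts the first half of the shared taxa
  in the second mode's samples — a constant offset on *all* taxa would
  cancel under compositional closure and make the knob a no-op.
* `within_module_latent_correlation` (default 0.9): the planted block
  strength; must be < 1, and block positive-semi-definiteness is validated.
* `lognormal_sigma` (default 1.0): per-taxon log-scale noise.
* `n_taxa_per_habitat_signature` accepts a per-habitat mapping to express
  richness gradients (e.g. sediment > water > intestine).

Ground truth (module membership, full latent correlation matrix, signature
habitats) is returned and written alongside the tables.

**An inherent coupling, and what it implies.**  An equicorrelated block at
ρ = 0.9 necessarily has a dominant common factor, so a habitat's entire
signature mass swings together from sample to sample.  Occasionally one
sample's home-signature block is strongly suppressed and that sample drifts
toward the other habitats' neighbourhood: the UPGMA three-way cut then
recovers the habitat partition exactly in only about half of data sets
(mean adjusted Rand index ≈ 0.9 over ten seeds), and the habitat ANOSIM
success rate (R ≥ 0.9 with p = 0.001) is ≈ 93–94% in long-run sweeps rather
than ~100%.  This is a property of the planted-correlation model itself,
not of the estimators, and the recovery tests assert the measured behaviour
rather than an idealised one.

**What the generator does not emulate:** real 16S features such as
over-dispersion beyond the log-normal, taxa absent from entire habitats
(every taxon has non-zero expected abundance everywhere, so the bipartite
classifier sees mostly cluster-3 genera on synthetic data), phylogenetic
structure, chimeras and OTU-clustering artefacts.  Passing recovery tests
therefore demonstrates correctness of the analysis operations under a
known-truth model, not field realism.

## Problem sizes in the test and acceptance runs

The estimator sweep checks 1,000 random samples against brute-force
formula evaluations; graph metrics are checked exhaustively on every
connected graph with ≤ 6 nodes plus 100 random 20-node graphs; permutation
p-values are checked against exhaustive enumeration on 6-sample toys; null
calibration uses 200 synthetic data sets and signal detection 100; module
recovery uses 20 data sets of 30 samples each.  The full suite runs in
well under a minute of CPU beyond the two ~10 s sweeps.

## Known limitations

* ANOSIM/Adonis are one-factor; no multi-factor formula interface.
* No compositionality-aware correlation (SparCC-style); the Spearman
  threshold network is exactly what it claims to be.
* No phylogenetic diversity or UniFrac (no tree in scope), no NMDS, and no
  publication-grade figure rendering — outputs are plain TSV/Newick/GraphML.
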