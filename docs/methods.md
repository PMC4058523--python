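# Methods

`pomanet` implements a candidate-miRNA-biomarker discovery pipeline for
small two-class cohorts with paired miRNA and mRNA expression profiles
(the motivating design: 6 non-cancerous vs 19 tumor gastric-tissue samples
with both profile types measured on each specimen).  The pipeline chains
five stages; each is re-runnable from the previous stage's TSV output.

## 1. Outlier differential expression (LSOSS)

Tumor cohorts are heterogeneous: an oncogenic feature is often aberrant in
only a *subset* of the case samples, which dilutes classical two-sample
statistics.  The least-sum-of-ordered-subset-squares t-statistic targets
this regime.  For a feature with case values x₁…x_n and control values
y₁…y_m:

1. sort the case values ascending;
2. choose the split index k* ∈ {1,…,n−1} minimizing the summed
   within-subset sum of squares of the two contiguous blocks (ties go to
   the smallest k — a 2-segment 1-D least-squares segmentation);
3. the **outlier subset** O is whichever block's mean lies farther from the
   control mean (ties go to the upper block), so down-regulated outliers
   are found symmetrically;
4. t_L = (mean(O) − mean(y)) / √(s_p² (1/|O| + 1/m)), with s_p² pooled over
   O and the controls on |O| + m − 2 df.

Because k* is optimized, t_L's null distribution is not Student-t;
significance comes from whole-vector class-label permutation, with the same
permutations reused across features (required for a valid
Benjamini–Hochberg pass across the feature family):
p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + n_perm), default n_perm = 999.

Numerical guards: the pooled SD is floored at 0.01 × (median pooled SD over
features); if the floor is still zero and the means differ, a ±10⁶ sentinel
replaces the infinite statistic.  Constant features get t_L = 0, p = 1, and
a `degenerate` flag.  t_L is invariant under adding a constant to all
values and under positive rescaling.

**Selection screen.** Which features proceed to correlation is a screen,
not an inference: specificity is supplied downstream by the correlation
test and the reference-network intersection, while a feature dropped here
is unrecoverable — and, worse, dropping one co-owner of shared targets
silently inflates the apparent exclusivity of the other.  Per-feature
permutation p-values are also intrinsically conservative for subset shifts
in unbalanced designs (much of the subset structure survives relabeling
when cases outnumber controls 19:6) and their 1/(n_perm+1) resolution is
too coarse for FDR control across hundreds of features.  The default
therefore keeps the top 50% of features by |t_L| (recall-oriented);
an absolute top-N and a BH q-value gate are available in the config for
larger or better-balanced designs.

## 2. Inverse-correlation screen

miRNAs repress their targets, so true regulation should appear as negative
monotone association across paired samples.  Every (outlier miRNA, outlier
gene) combination is tested with the tie-corrected Spearman correlation
over all paired samples (a case-only mode is available; using all pairs
maximizes n at 25).  A pair is retained iff ρ ≤ −0.6 (inclusive, with a
10⁻⁹ absolute tolerance on the boundary) and two-sided p < 0.05
(uncorrected — deliberately mirroring a screen, not a discovery test).
p-values use the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df; an exact
permutation p is provided for n ≤ 9 (include-the-boundary-atom convention;
note that for n = 5 the permutation distribution of ρ has atoms of width
0.1, so any continuous approximation can only be compared to atom
midpoints).  Constant vectors make ρ undefined; such pairs are skipped and
counted, preserving the m·g accounting identity.

## 3. Condition-specific subnetwork

Retained pairs are intersected with a reference miRNA→gene interaction
edge list (any merged database export; the package consumes, never
reconstructs, such lists).  Matching is exact-string; a 0% match of pair
miRNAs against the reference triggers a loud id-scheme diagnostic.  The
result is a directed bipartite graph whose node sets are exactly the edge
endpoints; each edge carries its (ρ, p) provenance.  An empty intersection
is a warning, not an error.

## 4. Exclusivity Z-score and candidate nomination

For each miRNA in the subnetwork, β is its out-degree, α the number of its
targets with in-degree exactly 1 (exclusive targets), and Z = α/β ∈ [0,1].
High Z indicates independent regulatory power — deregulated genes that no
other deregulated miRNA explains.

α's significance is assessed against a degree-preserving bipartite
rewiring null: checkerboard swaps (m₁→g₁, m₂→g₂) → (m₁→g₂, m₂→g₁) fix all
out- and in-degrees — hence also the *number* of exclusive genes — while
randomizing which miRNA owns them, which is exactly the quantity α
measures.  The chain records one sample every 10·|E| attempted swaps
(n_perm = 999); p_α = (1 + #{α_perm ≥ α_obs}) / (1 + n_perm).  Degenerate
cases behave sensibly: in an all-exclusive network α_obs is maximal for
everyone and p_α = 1; α = 0 likewise gives p_α = 1.  The test-suite
cross-checks the chain against an independent configuration-model
stub-shuffle sampler.

Candidates: Z ≥ 0.3 (inclusive), α > 1 (strict, i.e. α ≥ 2) and
p_α < 0.05, sorted by Z, then α, then id.  Exclusivity is computed within
the condition-specific subnetwork, not the full reference network: the
question is independence among *deregulated* interactions.

## 5. Evaluation

Each candidate is evaluated as a univariate classifier.  ROC orientation
comes from the candidate's outlier direction (a down-regulated miRNA scores
cases by low expression) — never by auto-flipping to AUC ≥ 0.5, which would
be optimistically biased.  AUC follows the rank/Mann–Whitney formulation
with midrank ties (constant scores give exactly 0.5).  The reported
operating point maximizes Youden's J = sensitivity + specificity − 1 (first
maximizer, i.e. the most stringent threshold, on ties); sensitivity,
specificity and accuracy are quoted there.

Samples are also clustered on candidate expression with the standard
heatmap recipe: per-feature z-scoring (zero-variance rows contribute
zeros), Euclidean distance, complete linkage, cut at two groups; agreement
is the better of the two group-to-class assignments, hence in [0.5, 1].

## Synthetic cohorts and what they do (not) show

The generator plants a fully known truth so that every stage is testable
offline.  Expression is generated directly on the log2 scale (the pipeline
consumes log-transformed processed values): per-feature baselines
~ Normal(8, 2), within-class noise SD 1.0, defaults 6 controls vs 19
cases, 100 miRNAs × 500 genes.

Planted structure (defaults, chosen once as the study conditions):

* **Exclusivity-rich regulators** (4): 6 exclusive targets each, coupling
  `target = baseline − 2.0 · regulator_deviation + noise`, i.e. generative
  |ρ| = 2/√5 ≈ 0.894.  These are the intended biomarkers: expected α = β =
  6, Z = 1.
* **Share-heavy regulators** (6, in 3 pairs): each pair co-owns 10 shared
  targets (`− 1.4 · (dev_a + dev_b)`).  Two *independent* regulators of one
  gene cannot both correlate with it strongly (ρ₁² + ρ₂² ≤ 1), so pair
  members share a latent factor (partner correlation 0.45), giving each
  shared edge a generative |ρ| ≈ 1.4(1+c)/√(2·1.4²(1+c)+1) ≈ 0.785.
  Expected α = 0, Z = 0: they exist so that the subnetwork contains shared
  structure, without which the rewiring null is degenerate and exclusivity
  is meaningless.
* **Subset shifts**: every planted regulator is shifted by 3 within-class
  SDs in a randomly chosen 60% of the case samples; the sign is random.
  Members of a co-ownership group are *co-deregulated* — one subset and one
  direction per group, as a coordinated miRNA program marking one tumor
  subtype.  This is not cosmetic: with independent subsets the partner's
  shift acts as noise in the (regulator, shared gene) correlation and the
  realized all-samples |ρ| falls to ≈ 4.5/√(3.2·15.3) ≈ 0.64 — a coin flip
  against the −0.6 cutoff — whereas co-deregulation reinforces it to
  ≈ 8.2/√(3.2·24.1) ≈ 0.93.  (Var(regulator) ≈ 1 + 9·p(1−p) ≈ 3.2 at
  p = 11/25 shifted samples.)
* **Decoys**: all remaining features are pure noise; the reference network
  adds 500 decoy edges between decoy miRNAs and decoy genes only, so the
  planted exclusivity plan (in-degree 1 vs 2) is realized exactly.

All randomness flows from one master seed through a fixed draw order and a
documented per-stage seed derivation, so runs are byte-reproducible.

What passing on these cohorts does **not** show: real processed expression
is not Gaussian on the log scale, real interaction databases are noisy and
biased, real miRNA programs are not cleanly bipartitioned into exclusive
and shared regulators, and identifier matching across resources is a
substantial practical problem that exact-string matching sidesteps.

A structural property of the subset-outlier regime is worth stating
plainly: with a 3-SD shift in 60% of cases, the remaining 40% of case
samples are control-distributed on every marker *by construction*.  A
single candidate's expected AUC is therefore ≈ (11·Φ(3/√2) + 8·0.5)/19 ≈
0.78, and a two-group cut on candidate expression can agree with the
case/control labels on at most ≈ (6+11)/25 ≈ 0.68 of samples.  Candidate
*identification* (sensitivity/precision of the candidate set) is the
quantity this regime supports; single-marker classification performance is
intrinsically capped until the outlier fraction approaches 1.

## Problem sizes and numerical conventions

* Test-suite and acceptance-script replication: 20 cohorts per condition
  at the default 100 × 500 × 25 size with n_perm = 999 — large enough for
  stable pooled estimates while keeping a full run in tens of seconds.
* Permutation p-values use the add-one convention (never 0), so with
  n_perm = 999 the attainable minimum is 0.001.
* Boundary conventions: ρ cutoff inclusive (tolerance 10⁻⁹), Z cutoff
  inclusive (tolerance 10⁻¹²), α > 1 strict, all p cutoffs strict.
* LSOSS pooled-SD floor ε = 0.01 of the per-scan median; sentinel 10⁶.
* Tie-breaks are deterministic everywhere (smallest split index, upper
  outlier block, first Youden maximizer, mergesort for table sorting), so
  identical configs produce byte-identical TSVs.

## Known limitations

* The rewiring-null p_α loses meaning in (near-)all-exclusive subnetworks
  (p_α → 1 for everyone); the share-heavy archetype exists precisely to
  exercise the informative regime, but real condition-specific subnetworks
  can be exclusivity-saturated, in which case the α test is conservative.
* The correlation screen tests marginal association only; no partial
  correlations, no many-to-one deconvolution.
* Exact-string identifier matching; no miRBase-version or gene-alias
  resolution.
* Univariate evaluation only; no cross-validation or marker panels.
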