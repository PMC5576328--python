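# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Input model and preprocessing

The central object is an OTU × sample matrix of non-negative integer
sequence counts. Two abundance filters operate on the grand total of the
table: the rare-OTU filter (default 0.005% of all sequences, the standard
guideline for open-reference OTU tables) and the dominance filter (default
1%, used to restrict per-pair comparisons to dominating OTUs). Both retain
an OTU whose total is *greater than or equal to* the cut; the boundary
convention matters at exactly the threshold and "≥" is the only defensible
reading of a "≥1%" dominance rule. Filters run before any pairing-specific
analysis; the rare filter runs before rarefaction.

Taxonomic collapsing sums OTUs sharing the lineage prefix through a rank
(default rank 6 = genus, GreenGenes numbering). Lineage labels are
normalized to single-underscore prefixes and an unnamed genus keeps its
family in the taxon key (`...;f_Gemellaceae;g_`), so two unnamed genera in
different families stay distinct. Column sums are conserved exactly.

Rarefaction draws each sample down to a common depth without replacement —
a multivariate hypergeometric draw per sample, seeded, one draw per sample
(no repeated-rarefaction averaging). Samples shallower than the depth are
dropped and logged. The pipeline default depth is "auto": the shallowest
retained sample of the subset being analysed. That is the procedure that
produces depths like 18,250 or 19,743 on real datasets of this design; a
fixed depth can be set per subset in the configuration.

## Pair-level concordance

**Yue–Clayton.** For relative-abundance vectors a, b summing to 1,
θ = Σaᵢbᵢ / (Σaᵢ² + Σbᵢ² − Σaᵢbᵢ), and 1 − θ ∈ [0, 1] is the dissimilarity
(0 identical, 1 disjoint). It is computed per pair on the genus-collapsed
profiles twice: on all taxa, and on the taxa of dominating OTUs only
(dominance filter applied to OTUs first, then collapsed — matching the
"omit rare OTUs before the taxonomic summary" order). The index weights
both shared and unshared components, which is why it is paired with the
LOA view below rather than used alone.

**Bland–Altman.** Per pair, on percent abundances (columns summing to
100), the paired differences d = a − b give limits of agreement
mean(d) ± 1.96·sd(d) with the sample (n−1) standard deviation and the
fixed 1.96 multiplier of the classical method (no t-quantile). The range
statistic (upper − lower)/100 is dimensionless; 0 means perfect agreement.
Because both profiles sum to 100%, mean(d) is identically 0 and the range
is driven entirely by the spread of per-taxon disagreements. At least 3
taxa are required (the sd is degenerate below that).

**Classification.** A pair is discordant when a statistic strictly exceeds
its cut-off; boundary values count as concordant. Defaults: 0.2 for
1 − θ (either OTU set) and 0.1 for the LOA range — the 0.1 limit allows
each taxon's relative abundance to differ by 10 percentage points between
methods. Both cut-offs are conventional rather than derived, and are
exposed as configuration.

**Group comparison.** The mean induced profile and mean spontaneous
profile (over the pairs of a subset) are renormalized and compared with the
same dissimilarity. Crossed perturbations cancel in the means, so a small
group value with large per-pair values is expected behaviour, not a bug —
the package reports both for exactly that reason.

## Per-taxon G-tests

For each taxon the observed per-group sequence totals O_g are tested
against expectations E_g proportional to group sample counts under
homogeneity: G = 2 Σ_g O_g ln(O_g/E_g) (zero totals contribute 0), with a
χ² null on n_groups − 1 degrees of freedom. The table must be rarefied to
a common depth first so that sample count is a fair exposure measure. The
Williams small-sample correction is available behind a flag and off by
default; with per-group totals in the thousands it is immaterial.
Bonferroni multiplies by the number of taxa tested in the run, capped at 1.
The test treats sequences as independent draws; overdispersion across
subjects is not modelled (no zero-inflated or compositional alternatives —
deliberately out of scope), so its p-values are calibrated under
multinomial sampling (verified by simulation in the test suite) but will be
anti-conservative for strongly overdispersed real data.

## Diversity

Alpha metrics per rarefied sample: observed OTUs; Chao1
(S_obs + F1²/(2F2), or the bias-corrected S_obs + F1(F1−1)/2 when there are
no doubletons); Faith's PD as the branch length of the union of
root-to-leaf paths over observed OTUs, including the root's own edge when
it carries a positive length (a fixed, deterministic convention). Group
comparisons use a two-sample pooled-variance t statistic whose null is
generated by label permutation; p = (1 + #{|t*| ≥ |t|})/(1 + n_perm).

Beta diversity uses UniFrac on a precomputed branch-incidence matrix
(branches × leaves), which makes full distance matrices and permutation
tests cheap. Unweighted UniFrac is unique/covered branch length over the
branches below at least one observed leaf. Weighted UniFrac is
Σᵢ bᵢ·|p_Ai − p_Bi| over branches, with p_Xi the fraction of sample X's
sequences descending through branch i; the default is this *raw* form (the
historical default of the era's pipelines), with the normalized form
(divide by Σᵢ bᵢ(p_Ai + p_Bi)) behind a flag. Both metrics are verified
against a brute-force per-branch tally and against scikit-bio.

Pairwise significance keeps both sequencing depths fixed and reassigns
every sequence to one of the two samples uniformly at random — a
multivariate hypergeometric split of the pooled counts — and recomputes the
metric; p = (1 + #{d* ≥ d})/(1 + n_perm). The all-pairs driver runs every
unordered pair (2556 for 72 samples) and multiplies each p by the number of
comparisons actually run. One structural consequence of the add-one
estimator deserves emphasis: the smallest attainable corrected p is
(number of comparisons)/(n_perm + 1), so at desk-scale permutation budgets
(the pipeline default is 100 permutations per pair; even 1000) *no* pair
can reach familywise significance at α = 0.01 across 2556 comparisons.
Historical pipelines reported zero p-values when no permutation reached the
observed distance, which is how such analyses produced "significant pairs";
this package deliberately never reports p = 0, and a user who wants the
corrected pairwise test to have any power must raise `n_perm_pairwise`
toward α⁻¹ × n_comparisons. The uncorrected per-pair p-values remain
calibrated and useful at any budget.

## Ordination

PCoA is classical metric scaling: double-center −½D², eigendecompose,
scale eigenvectors by √λ for positive eigenvalues. Negative eigenvalues
(distances that are not Euclidean-embeddable, common for raw weighted
UniFrac) are reported but contribute no axes; no Lingoes/Cailliez
correction is applied because a correction would change the Procrustes
residual. Proportion explained is relative to the positive eigenvalue sum.

Procrustes superimposes the induced-sample and spontaneous-sample PCoA
configurations (axes 1–3, rows matched by pair): both are centered and
scaled to unit sum of squares, an optimal rotation (reflections allowed)
and dilation are applied, and M² is the residual sum of squares — 0 for
identical shapes, 1 for completely dissimilar ones. The Monte-Carlo test
shuffles the row correspondence of one configuration and counts
permutations with M* ≤ M² (add-one form); shuffling correspondence rather
than raw distances is the natural null for "do the two ordinations match
pair for pair".

ANOSIM ranks all n(n−1)/2 distances (average ranks for ties);
R = (mean between-group rank − mean within-group rank)/(M/2) ∈ [−1, 1],
with label-permutation significance. Sample type (induced vs spontaneous)
is the grouping, per subset.

## Pipeline and reproducibility

Stages run in a fixed order (filter → concordance branch → per-subset
rarefied analyses → UniFrac → ordination → classification), and each
subset analysis (all / exacerbation / stable) uses only the pairs whose
state matches. Every stochastic stage consumes a named child seed derived
from the master seed through `numpy.random.SeedSequence.spawn`, recorded in
the report header, so a fixed configuration reproduces its outputs byte
for byte. Any stage failure aborts with the stage name and offending ids.
Bonferroni is the only multiplicity correction offered, for both the taxon
tests and the pairwise UniFrac driver; ANOSIM and the alpha tests use
α = 0.05, the corrected pairwise UniFrac test α = 0.01, and M² > 0.3 is
annotated as indicative of influential differences (a heuristic, not a
test).

## Synthetic data

The generator emulates a two-method sputum study: default 36 pairs with an
11/25 stable/exacerbation split, 1000 OTUs mapped onto 106 genus-level
lineages (each genus guaranteed at least one OTU, a fraction of genera
unnamed to exercise the `f_X;g_` labelling path), a random bifurcating
tree with exponential branch lengths, and per-sample depths drawn uniformly
in [0.95, 1.05] × 19,500 ≈ 18,525–20,475. The ±5% band around 19,500 keeps
every sample above the depths such designs rarefy to (~18,000–20,000)
while still exercising the unequal-depth code paths; a wider band would
silently drop samples at rarefaction, which would change the paired design
itself.

Compositions follow a hierarchical Dirichlet-multinomial: a global mean
profile m ~ Dirichlet(1) over OTUs, per-pair base composition
π_j ~ Dirichlet(c·m) with c = 200 controlling between-subject variation,
and multinomial sequencing. The spontaneous member's composition is a
logistic-normal perturbation softmax(log π_j + ε), ε ~ N(0, σ²) per OTU —
divergence acts multiplicatively on log-abundance so rare taxa diverge as
realistically as dominant ones — followed by optional per-genus
fold-changes (systematic method effects) and renormalization. σ = 0 with
no effects yields identical compositions (pure sequencing noise);
σ ≈ 0.5 puts the median per-pair 1 − θ near the 0.2 classification cut,
and σ = 2 produces strongly discordant pairs, so a gradient over [0, 2]
spans the full observed range of pair behaviour. A Dirichlet-resampling
perturbation (π′ ~ Dirichlet(c/σ²·π)) is available as an alternative.

What the generator does *not* emulate: taxonomic realism (no skewed
pathogen-dominated profiles — the global mean is symmetric-Dirichlet, so
genus abundances are more even than real sputum, which in turn keeps
Bland–Altman ranges smaller than those of strongly dominated real
communities); overdispersion beyond the between-pair Dirichlet layer;
contamination, chimeras or raw reads. One intrinsic property worth knowing:
because only the spontaneous member is perturbed, large σ slightly lowers
that member's evenness and hence its rarefied richness, so strongly
divergent simulated studies show systematic method differences in alpha
diversity and ANOSIM that a symmetric perturbation would not produce.
Passing tests on this generator therefore demonstrate correctness of the
statistics and recovery of planted structure, not that any real pair of
sampling methods behaves this way.

## Problem sizes used in validation

The acceptance script simulates 36 pairs at 300 OTUs / 106 genera and
~19,500 reads per sample and runs the full pipeline with 100 permutations
per pairwise comparison and 999 elsewhere. The test suite's calibration
studies use 200 replicate datasets (G-test and pairwise-UniFrac type-I
error), 1000 replicate draws (rarefaction moments), 50-pair gradients at
depth 20,000 (dissimilarity recovery, Spearman ρ against true L1
divergence) and 100 replicate 36-pair studies (2-fold effect detection).
These sizes give Monte-Carlo standard errors small enough for 3σ
acceptance bands while keeping the whole suite in the low minutes on one
CPU.

## Known limitations

- The G-test assumes multinomial counts; no subject-level random effect.
- Raw weighted UniFrac is unbounded above (bounded by twice the
  abundance-weighted depth); use the normalized form for cross-tree
  comparability.
- The corrected all-pairs UniFrac test has no power at small permutation
  budgets (see above) — this is a property of never reporting p = 0, not a
  bug.
- BIOM 2.x (HDF5) is not read; convert to BIOM 1.0 JSON or TSV first.
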