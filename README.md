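# microconcord

Paired-sample microbiota concordance analysis.

When the same subjects are sampled with two methods — for instance induced
versus spontaneous sputum in COPD patients — a natural question is whether
the two sample types can be used interchangeably in 16S rRNA microbiota
studies. `microconcord` implements the full statistical workflow for
answering that question from an OTU count table, a taxonomy map, a rooted
phylogeny and a table pairing the two samples of each subject:

- **Per-pair composition agreement.** For each pair the Yue–Clayton
  dissimilarity `1 − θ_YC` with `θ = Σaᵢbᵢ / (Σaᵢ² + Σbᵢ² − Σaᵢbᵢ)` on
  relative-abundance vectors (0 = identical, 1 = disjoint), computed both on
  all genus-level taxa and on the taxa of dominating OTUs (≥1% of all
  sequences); and Bland–Altman 95% limits of agreement on percent
  abundances, `mean(d) ± 1.96·sd(d)` with range statistic
  `(upper − lower)/100`. Pairs are classified discordant when a statistic
  exceeds its cut-off (defaults 0.2 and 0.1).
- **Group comparison.** Yue–Clayton dissimilarity between the *mean* induced
  and mean spontaneous profiles — which can hide discordance that the
  per-pair view reveals.
- **Per-taxon tests.** G-tests (log-likelihood ratio) of per-taxon sequence
  totals between sampling methods on rarefied tables, Bonferroni-corrected.
- **Diversity.** Observed OTUs, Chao1 and Faith's phylogenetic diversity
  with Monte-Carlo permutation t-tests; unweighted and weighted UniFrac with
  depth-preserving sequence-reassignment permutation significance for every
  sample pair (Bonferroni over all `n(n−1)/2` comparisons).
- **Ordination.** PCoA of UniFrac distances, Procrustes superimposition of
  the induced and spontaneous configurations on axes 1–3 (`M² = 0` for
  identical configurations, 1 for completely dissimilar, with a Monte-Carlo
  match test), and ANOSIM by sample type.
- **Synthetic studies.** A seeded generator of paired communities
  (Dirichlet-multinomial base compositions, logistic-normal within-pair
  divergence, optional per-genus fold-change method effects) with a
  ground-truth record, so every stage runs and can be validated without
  external data.

Inputs are plain TSV or BIOM 1.0 JSON count tables, GreenGenes-style
taxonomy TSV (both `g__Name` and `g_Name` prefixes), newick trees and a
pairing TSV (`pair_id`, `induced_id`, `spontaneous_id`,
`state ∈ {stable, exacerbation}`).

## Worked example

```python
import numpy as np
from microconcord import (
    SyntheticConfig, simulate_paired_tables, PipelineConfig, run_pipeline,
)

cfg = SyntheticConfig(
    n_pairs=12, n_otus=200, n_genera=40, depth_mean=10000,
    divergence=np.linspace(0.0, 1.5, 12),  # near-identical -> discordant
    seed=7,
)
dataset = simulate_paired_tables(cfg)[:4]
result = run_pipeline(PipelineConfig(master_seed=1), dataset=dataset)

for r in result.pair_results[:3]:
    print(f"{r.pair_id}  1-theta(all)={r.one_minus_theta_all:.3f}  "
          f"LOA range={r.loa_range:.3f}  discordant={r.discordant}")
print("summary:", result.classification)
print("group 1-theta (all pairs, dominant taxa):",
      round(result.group_theta[('all', 'dominant')], 3))
print(f"Procrustes M^2 = {result.procrustes.m_squared:.3f} "
      f"(p = {result.procrustes.p_monte_carlo:.3f})")
r = result.anosim[('all', 'wuf')]
print(f"ANOSIM (weighted UniFrac, by sample type): R = {r.R:.3f}, p = {r.p:.3f}")
```

prints

```
pair01  1-theta(all)=0.005  LOA range=0.008  discordant=False
pair02  1-theta(all)=0.011  LOA range=0.013  discordant=False
pair03  1-theta(all)=0.025  LOA range=0.020  discordant=False
summary: {'n_pairs': 12, 'theta_discordant_all': 6, 'theta_discordant_dom': 9, 'loa_discordant': 2, 'any_discordant': 9}
group 1-theta (all pairs, dominant taxa): 0.036
Procrustes M^2 = 0.681 (p = 0.088)
ANOSIM (weighted UniFrac, by sample type): R = 0.038, p = 0.144
```

The pairs were simulated along a divergence gradient: the first pairs are
nearly identical (`1 − θ` near 0, tiny LOA ranges, not flagged) while later
pairs diverge and 9 of 12 end up discordant on at least one statistic. The
group-level dissimilarity stays at 0.036 even though individual pairs reach
far larger values — pooling hides pairwise differences. The ANOSIM p shows
that grouping samples *by type* does not separate them, which is exactly the
situation where per-pair statistics matter.

The same analysis runs from the shell:

```sh
microconcord simulate --out-dir data/ --n-pairs 36 --seed 3
microconcord run --config config.yaml --output-dir out/ --seed 11
```

`run` writes `report.tsv` (one row per pair, machine-readable at full
precision), `report.md` (human summary), distance matrices, PCoA
coordinates, per-taxon test tables and a log of every seed used.

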