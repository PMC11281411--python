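# Methods

## The synthetic study generator

`momnet.synthio` emulates a two-group gut multiomics study: a virome
layer quantified as RPKM, a bacterial OTU count layer, a metabolite
intensity layer, and per-sample symptom-scale items. Its purpose is to
provide data with *known* association structure so that every network,
differential and module claim downstream can be scored against ground
truth.

**Latent-factor copula.** Each of `n_modules` blocks has a latent
standard-normal factor Z_b over samples. A feature in block b is
g = a·Z_b + √(1−a²)·ε with a chosen so that the *observed* Spearman
correlation between two block members equals the target `rho_within`:
for bivariate Gaussians ρ_S = (6/π)·asin(ρ_P/2), so the latent Pearson
correlation is set to ρ_P = 2·sin(π·ρ_S/6) and a = √ρ_P. Marginals are
then applied as monotone transforms of g — counts by negative-binomial
quantile coupling (mean exp(log-base), variance μ + αμ², `dispersion`
α), intensities/RPKM as log-normals — so ranks, and hence Spearman
correlations, are preserved exactly. Background features are independent
noise. With `cross_layer=True` (default) blocks draw members from all
layers round-robin, producing cross-kingdom edges; with `False` each
block lives in one layer.

**Zero inflation.** The default `zero_mode="censor"` sets the lowest
`zero_prob` quantile of each feature to zero — detection-limit
censoring, which is monotone per feature, so `rho_within` remains the
Spearman target of the observed data while the zero ties exercise the
tie-corrected Spearman path. `zero_mode="bernoulli"` masks entries
independently instead; this is *not* monotone and attenuates the
observed rank correlation well below the target (measured: target 0.95
→ ≈ 0.62 at 10% masking), because masking changes the estimand rather
than adding noise. It is retained for studying that attenuation, not as
the calibration default.

**Group effects.** `n_diff_features` background features per layer get
their case-group mean shifted by `effect_log2fc` log₂ units (alternating
direction), implemented inside the marginal so ranks within each group
are untouched.

**Symptoms.** GSS items live on a 0–4 ordinal grid (a generator
convention, configurable), Zung depression/anxiety items on 1–4. A
configurable subset of items loads on configurable blocks: the item is a
discretized `loading·Z_b + noise·ε`, plus a severity shift for patients.
The item→block map is the ground truth for symptom–omics edges.

**Presets.** `study_preset()` mirrors the motivating design (12 patients
vs 8 controls); `powered_preset()` keeps the 3:2 proportions at 30 vs 20
samples, enough power for both group-specific networks to pass the
|r| > 0.8, p < 0.001 thresholds on ρ = 0.9 blocks. Tests use larger n
where the property under test needs it.

**Default parameters and why.** 240/160/80 features per layer (a
desk-scale shadow of the study's post-filter feature counts), 6 blocks
of 8, ρ = 0.9, zero_prob = 0.1 (typical zero share of top-abundance
features after retention filtering), dispersion 0.5, effect 2 log₂,
symptom loading 0.8 with noise 0.5. These are fixed conditions, not
tuning knobs.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: compositional coupling between features
(closure effects), phylogenetic correlation among OTUs,
sequencing-depth variation and count noise shared across features,
batch effects, and non-monotone feature dependencies. Conclusions here
concern the estimators and thresholds, not biology.

## Statistical procedures

**Spearman networks.** Correlations are Pearson on mid-ranks
(tie-corrected); p-values use the t approximation on n−2 df. The edge
rule is the conjunction |r| > r_min AND p < p_max AND BH q ≤ q_max with
defaults 0.8 / 0.001 / 0.05; the BH family is all pairs tested in one
`build_network` call (per network). A |r| > 0.6, p < 0.05 preset serves
the cross-omics heatmap and symptom-edge analyses; which of the two
thresholds a symptom network should use is a user decision, both are
provided. Note on calibration: the t approximation is mildly
anticonservative in its extreme tail at small n (measured ≈1.3–1.5×
at the 0.001 level for n = 12–40). At the motivating design's group
sizes (n ≤ 12) the p < 0.001 cut implies |r| > 0.8, and the exact-null
edge rate (full n! enumeration at n = 8: 2.23 × 10⁻³) is what the
calibration tests and the acceptance script check against.

**PERMANOVA.** One-way Anderson pseudo-F on squared distances;
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) (add-one, so p > 0), seeded
label permutations, default n_perm = 999. Permutation p-values are
exactly calibrated by construction; type-I error at α = 0.05 is verified
at 0.05 ± 0.01 over 2000 null datasets.

**PCoA.** Gower-centered −d²/2 followed by symmetric eigendecomposition;
eigenvalues are reported in full (including negative ones, which
Bray–Curtis can produce) but coordinates are taken only on non-negative
axes; requesting more axes than available truncates with a warning. No
Lingoes/Cailliez correction — ordinations here are 2-D displays.

**Shannon.** Natural log by default (nats); any base via the `base`
argument.

**Differential abundance.** Per feature, a two-sided Mann–Whitney U —
exact enumeration when both groups have ≤ 8 samples and no ties,
tie-corrected normal approximation otherwise — with BH adjustment across
the feature set; constant features get p = 1 and a flag. The LDA effect
size is a deliberate two-class *variant* of LEfSe (the design has no
subclasses, so the subclass Wilcoxon stage is omitted): abundances are
scaled to a fixed 10⁶ per-sample total, then over `n_boot = 30` rounds a
shrinkage-regularized LDA is fit on a 2/3 subsample of each class and
each feature is scored as 0.5·(|w̃_f·Δ_f| + |Δ_f|) (unit-norm LDA weight
times raw class-mean difference, averaged with the raw difference),
floored at 1 before log₁₀; the score is the mean over rounds.
Subsampling draws from the sorted sample ids of each class, making
scores invariant to input column order. A feature is "differential" at
p < 0.05 AND score > 2, annotated with the higher-median group.
*Limitation:* the null magnitude of LDA-style scores scales with a
feature's abundance — dominant features can exceed 2 under the null,
which is exactly why the rank-test gate is conjoined; the expected null
pass count stays below α·m.

## Network topology

Betweenness, closeness and the clustering coefficient are computed on
the unweighted thresholded graph (the threshold already binarizes
association strength); closeness uses Wasserman–Faust normalization per
connected component so fragmented networks give finite values;
eigenvector centrality is power iteration on |r| weights (tol 1e-8, max
1000 iterations — non-convergence raises, which can happen on
disconnected graphs whose components tie in spectral radius; the
analysis drivers therefore run centralities on the giant component).
Modules come from seeded Louvain on |r| weights, labeled by descending
size, with modularity Q reported for the returned partition. Zi is the
within-module degree z-score (population SD; 0 where the module SD is
0), Pi = 1 − Σ_s (κ_is/k_i)²; roles use the conventional 2.5 / 0.62
cutoffs: module hub (high Zi), connector (high Pi), network hub (both),
peripheral (neither). "Top 25% of modules" means the ⌈0.25·n_modules⌉
largest by node count. The power-law check is a least-squares fit of
log frequency vs log degree over degrees ≥ 1 and needs ≥ 5 distinct
degrees — satisfied by sequencing-scale networks but usually not by
planted-block networks, whose degree spectra are clique-like; drivers
report NaN in that case rather than forcing a fit.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
package's own benchmark conditions: recovery benchmarks use 60 samples
per group, ρ = 0.95, 3-log₂ effects and within-layer blocks of 8; null
calibrations use 2000 PERMANOVA datasets (20 samples, 30 features,
99 permutations each) and ~2 × 10⁵ independent feature pairs at n = 8
against the exact permutation null; the exhaustive centrality check
covers every graph on ≤ 7 nodes. Ties in the retention filter are broken
toward the lexicographically smaller feature id; retained counts use
ceiling so a positive fraction never empties a table. All stochastic
components take explicit seeds and equal seeds reproduce outputs
bit-for-bit.

## Known limitations

- Spearman t-approximation tail behavior at small n (above); an exact
  permutation p option is a natural extension but full enumeration is
  only feasible for n ≲ 10.
- No compositional treatment (no CLR/SparCC/SPIEC-EASI); correlations on
  relative data can reflect closure, which the generator does not model.
- Eigenvector centrality is ill-defined across disconnected components;
  values are comparable only within a component.
- The LEfSe-style score is a variant, not a clone; published LDA-score
  magnitudes are comparable only qualitatively.
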