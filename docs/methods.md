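# Methods

This note documents the statistical machinery of `ferroscore`, its
defaults, the design choices that were genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## The synthetic cohort generator

The generator is the package's stand-in for transplant-biopsy expression
studies and defines the reference conditions used by the test-suite and
`scripts/acceptance.py`.

Model: gene g has a baseline b_g ~ N(baseline_mean, 1); sample s observes

    x[g, s] = b_g + shift_g · 1[s is case] + ε,   ε ~ N(0, σ²)

with shift_g = +δ_driver for a planted subset of driver genes, −δ_suppressor
for a planted subset of suppressor genes and 0 otherwise. Defaults: 40
cases + 40 controls; a 150-gene panel (60 drivers, 60 suppressors, 30
markers) plus 500 background genes; δ = 1.0 log2 units planted on half of
each affected category; σ = 0.7; baseline_mean = 6.0. Planting the shift
on only half of each category makes signature derivation a real selection
problem rather than a rubber stamp, and the untouched markers plus
background genes supply realistic nuisance dimensions. The effect size of
one log2 unit (a two-fold change) against σ = 0.7 is typical of a clearly
differentially expressed immune-activation gene in bulk biopsy data.

Survival: the latent score z(s) is the standardized difference between a
sample's mean planted-driver and mean planted-suppressor expression —
deliberately the same axis the ferroptosis score estimates, so prognosis
is tied to the quantity the pipeline recovers. Event times are
exponential with hazard h₀ · HR^z, HR = 2 per SD by default, and
h₀ = ln 2 / horizon (median survival at the 1095-day horizon for an
average sample). Censoring is an independent exponential clock with rate
h₀ · c/(1−c), which makes the censoring probability of an average sample
exactly the configured rate c (default 0.5); c = 0 disables censoring.

Not modelled: batch effects, platform differences, library-size or
compositional artefacts, correlated gene modules, non-proportional
hazards. Tests passing on these cohorts therefore establish correctness
of the algorithms under their stated assumptions — not performance on any
particular GEO series, whose headline AUCs depend on real biological and
technical variation the generator does not imitate.

## Consensus clustering

For each k in 2..9 (configurable), 200 resamples (configurable; 1000 for
publication-grade runs) draw ⌈0.8·n⌉ samples without replacement and
cluster them with the base method; co-sampling and co-clustering tallies
yield the consensus matrix. The base clusterer is agglomerative with
average linkage on 1 − Pearson correlation between samples (k-means on
Euclidean distance is the configurable fast alternative). Resample
streams are derived deterministically from the seed (per-k seed = seed + k),
so runs are exactly reproducible, and the stream generator is exposed
(`resample_indices`) so independent tally implementations can verify the
matrix entry by entry.

Gene rows are **median-centered** before the distance computation
(`prepare_values`). Correlation between samples is taken across genes, so
the shared per-gene baseline acts as a common signal: without centering,
all sample pairs correlate strongly and the leading structure in the
distance matrix is outlier separation rather than group separation — at
k = 2 average linkage then splits off stragglers and the consensus matrix
turns ambiguous. Median-centering is the standard preprocessing for
correlation-based consensus clustering of samples, and full per-gene
z-scoring remains available (`z_score=True`); centering can be disabled
for data already centred upstream.

k selection replaces the visual "flattest CDF" judgement with PAC: the
fraction of off-diagonal consensus values strictly inside (0.1, 0.9).
The k minimizing PAC wins; ties at a nonzero minimum break toward smaller
k. Ties at PAC exactly 0 carry no information — a deterministic base
clusterer merges true groups *crisply* when k is too small — so tied
zero-PAC candidates are adjudicated by the Δ-area rule (largest candidate
whose relative increase in area under the consensus CDF exceeds 0.05).
Pairs never co-sampled get consensus 0 with a warning (conservative; no
0/0). Final labels cut an average-linkage tree of 1 − consensus at the
chosen k and are numbered 1..k by decreasing cluster size.

## Moderated differential expression

The two-group moderated t shrinks per-gene pooled variances s²_g (d_g =
n₁+n₂−2 df) toward a prior s₀² with d₀ prior df:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)
    t_g  = logFC_g / √(s̃²_g (1/n₁ + 1/n₂)),  p on d₀ + d_g df.

(d₀, s₀²) are estimated by moment matching on log s²_g: under normality
log s²_g follows a scaled log-F whose mean and variance involve digamma /
trigamma functions of d_g/2 and d₀/2; the excess variance of the observed
log-variances is inverted through the trigamma function by Newton
iteration. When the observed log-variances are *less* dispersed than
chi-square sampling alone predicts, the excess is non-positive and the
prior df is effectively infinite (represented as 10⁶): all genes share
s₀². With fewer than 10 genes the prior is not estimable and the engine
falls back to the ordinary pooled t (d₀ = 0, also available explicitly
via `prior_df=0`, which reproduces the textbook statistic to 1e-10).

Multiple testing uses Benjamini–Hochberg step-up (the conventional
reading of "adjusted p" in transcriptomic screens). Signatures take
strict inequalities: A = {logFC > 0.5, FDR-adjusted p < 0.05}, B =
{logFC < −0.5, same}, with logFC oriented so positive means higher in the
case-enriched cluster (the cluster with the larger fraction of TCMR
diagnoses when the pipeline chooses it). An empty signature is an error
with advice to relax thresholds, since a PCA over zero genes is
undefined. The wider screen at |logFC| > 1 used for exploratory gene
lists is the same operation at a different threshold.

## The ferroptosis score

Per signature, the training submatrix (genes × samples) is centered
gene-wise at its training means (no variance scaling by default; with
`scale=True` the per-gene SDs are folded into the rotation and the
loading vector renormalized, which rescales each signature's coordinate
by one positive constant). The rotation is the leading left-singular
vector over genes — a unit-norm PC1 loading — and a sample's coordinate
is the inner product of the rotation with its centered profile. The raw
score is coord_B − coord_A.

Two sign rules remove the inherent PCA sign ambiguity:

1. each rotation is flipped, if necessary, so that its coordinate
   covaries positively with the mean expression of its own signature
   genes across training samples;
2. a global orientation sign (±1, stored in the model) makes the case
   group's mean training score exceed the control group's when labels
   are supplied at fit time; without labels it defaults to +1 and is
   logged.

The emitted score is orientation · (coord_B − coord_A). Flipping a stored
rotation together with the orientation bookkeeping provably leaves every
emitted score unchanged, and the tests verify this numerically.

Projection onto a new cohort uses only the stored gene means and
rotations. Signature genes absent from the new matrix are imputed at the
training mean — contributing exactly 0 after centering — with a warning;
more than 50% of a signature absent is an error, as the projection
becomes unreliable. NaN cells are imputed the same way per cell, so a
sample with every signature value unmeasured scores exactly 0 (the
training-mean profile). Requiring ≥ 3 usable genes per signature at fit
time guards against degenerate PCAs; `min_genes=1` is available for the
analytically transparent single-gene case, where the score reduces to a
centered expression difference.

## Evaluation

ROC is computed over the full threshold sweep (score ≥ cutoff classifies
positive); the trapezoidal area equals the tie-aware normalized
Mann–Whitney U exactly, which the tests check against an exhaustive
pairwise oracle. The Youden cutoff maximizes sensitivity + specificity −
1, ties resolved toward higher specificity. Constant scores degenerate to
AUC 0.5 with a warning. Group comparisons use the Welch (unequal
variance) t-test — the robust default where only "t-test" is specified.

Kaplan–Meier estimation and the two-group log-rank test are delegated to
`lifelines` behind the module surface and cross-checked in the tests
against a hand product-limit calculation and an independent risk-table
summation oracle. High/low score groups split at the median by default
(configurable quantile or explicit cutoff); the dichotomization rule is a
choice, not an estimate, and is recorded in every survival report.

The fixed-horizon ROC treats graft loss at or before the horizon
(default 1095 days) as positive and follow-up beyond the horizon as
negative; samples censored at or before the horizon are excluded and the
exclusion count reported. This binary-outcome treatment is simple and
auditable; inverse-probability-of-censoring weighting and time-dependent
ROC estimators are deliberate non-goals.

## Pipeline and reproducibility

`run_pipeline` executes ingest/simulate → panel subset → consensus
clustering → case-cluster identification (largest TCMR fraction) →
moderated-t signatures → score fit → projection and evaluation of the
training and any validation cohorts, persisting every intermediate
artifact plus a manifest with package version, parameters, per-stage
seeds (fixed offsets from the global seed) and input checksums. A failed
stage aborts with its name recorded in the manifest, and partial
artifacts remain on disk. Fixed config and seed give byte-identical
tabular outputs.

Problem sizes in the test-suite and acceptance script (e.g. 100–200
resamples, 20 generator seeds for the k-selection rate, 2000-gene null
matrices, 100 survival replicates) are chosen to make Monte-Carlo
assertions stable at desk scale; all are parameters, and larger runs only
tighten the same estimates.

## Known limitations

- Exactly two groups everywhere: no multi-factor designs, covariates, or
  k > 2 scoring contrasts.
- Probe-to-symbol mapping for array platforms is the caller's
  responsibility; the reader only collapses duplicate symbols
  (max-variance rule).
- The fixed-horizon ROC's censoring-by-exclusion can bias AUC when
  censoring is informative.
- Cross-platform projection assumes comparable log2 scales; no quantile
  or batch normalization is applied.
- The generator's independence assumptions (gene-wise independent noise,
  exponential survival, independent censoring) are idealizations; see the
  generator section for what passing tests do and do not show.
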