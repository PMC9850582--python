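# ferroscore

Ferroptosis-signature scoring of kidney-transplant rejection transcriptomes.

T cell–mediated rejection (TCMR) of a kidney allograft is diagnosed by
biopsy, and a transcriptomic surrogate is valuable both for screening and
for prognosis. `ferroscore` implements a complete, tested pipeline that
builds such a surrogate from the expression activity of
ferroptosis-associated genes (FerrDb-style panels of *driver*,
*suppressor* and *marker* genes):

1. **Consensus clustering** of biopsy samples over the ferroptosis-panel
   subspace — repeated subsampling, base clustering, and a consensus
   matrix whose entry (i, j) is the empirical probability that samples i
   and j co-cluster. The number of clusters k is chosen quantitatively by
   PAC (proportion of ambiguous clustering), with the Δ-area-under-CDF
   rule as tie-breaker and alternative.
2. **Moderated differential expression** between the two clusters: an
   empirical-Bayes moderated t with variance prior (d₀, s₀²) estimated by
   digamma/trigamma moment matching, BH-adjusted p-values, and signature
   derivation at |log₂FC| > 0.5, FDR < 0.05. Genes up in the case-enriched
   cluster form **signature A**, genes down form **signature B**.
3. **Ferroptosis score**: per-signature PCA over the training samples; a
   sample's score is the difference of its PC1 coordinates,

       score(s) = orientation · (PC1_B(s) − PC1_A(s)),

   with rotations (unit-norm PC1 loading vectors) and gene-wise training
   means stored in a serializable model. New cohorts are scored by
   *projection* through the stored rotation — never refit — so the score
   transfers across datasets that share gene identifiers.
4. **Evaluation**: ROC/AUC (exactly the tie-aware Mann–Whitney
   statistic), Youden-index operating point, Welch t-tests, Kaplan–Meier
   curves for high/low-score groups, log-rank test, and a fixed-horizon
   (default 3-year) ROC for graft loss.

Because the original study cohorts live in GEO, the package ships a
first-class **synthetic-cohort generator** that reproduces the assumed
statistical structure — planted log2 shifts in a fraction of driver and
suppressor genes, Gaussian noise, nuisance background genes, and
exponential survival whose hazard rises with the latent case axis — so
every stage is testable offline against known ground truth. Real matrices
in TSV/GCT form can be substituted anywhere.

## Worked example

```python
import ferroscore as fs

# a cohort of 40 TCMR-like and 40 non-rejection samples, 150-gene panel
config = fs.CohortConfig(seed=1)
matrix, phenotypes, truth = fs.generate_cohort(config)
panel, _ = fs.generate_gene_universe(config)

sub = fs.subset_to_panel(matrix, panel)
result = fs.consensus_cluster(sub, k_range=range(2, 10), n_resamples=200, seed=17)
print(result.chosen_k, result.pac[2])          # -> 2  0.0
```

Running `python examples/consensus_clustering.py` prints:

```
k   PAC      delta-area
2   0.0000   +0.5063 <- chosen
3   0.0649   +0.0552
...
cluster 1: 40 samples, 100% TCMR
cluster 2: 40 samples, 0% TCMR
```

PAC = 0 at k = 2 means every sample pair either always or never
co-clusters — the two-phenotype structure is rediscovered without labels.
Continuing (`python examples/fit_and_project.py`):

```
model: |A| = 30, |B| = 30, orientation -1
training mean score  TCMR: +5.61   non-rejection: -5.61
held-out cohort AUC = 1.000
```

The signatures recover exactly the planted driver/suppressor genes, the
TCMR group scores higher by construction of the orientation rule, and the
stored rotation separates a fresh cohort perfectly at the default effect
size. `examples/survival_analysis.py` shows the prognostic side (log-rank
p = 4.1e-03 between score halves; 3-year horizon AUC 0.68 on an 80-sample
cohort).

The `examples/` directory holds one short script per capability; each
generates its own input and prints what the numbers mean.

## Command line

The same stages are available as a thin CLI:

```sh
ferroscore simulate --out-dir cohort/ --seed 1
ferroscore cluster  --expression cohort/expression.tsv --panel cohort/panel.tsv \
                    --seed 17 --out clusters.json
ferroscore signatures --expression cohort/expression.tsv --labels clusters.json \
                    --out signatures.json
ferroscore fit      --expression cohort/expression.tsv --signatures signatures.json \
                    --phenotypes cohort/phenotypes.csv --out model.json
ferroscore score    --model model.json --expression new_cohort.tsv --out scores.tsv
ferroscore evaluate --scores scores.tsv --phenotypes new_pheno.csv --out report.json
ferroscore survival --scores scores.tsv --phenotypes new_pheno.csv --out survival.json
ferroscore pipeline --config run.yaml      # all of the above from one YAML
```

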