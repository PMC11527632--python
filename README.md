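# tlscore

Tertiary lymphoid structures (TLS) — ectopic aggregates of T and B cells
inside tumor tissue — are associated with favorable prognosis and response
to immune checkpoint blockade, but they are hard to quantify from bulk
RNA-seq. `tlscore` derives a per-sample **TLS signature score** from a
23-gene TLS-related gene panel (chemokines, chemokine/cytokine receptors,
cytokines, transcription factors, co-stimulatory and inhibitory molecules,
one ECM gene) and carries the score through survival analysis, tumor
mutational burden (TMB) integration, immune-infiltration scoring and
single-cell module scoring. It is written for computational oncologists
who want a reproducible, fully tested implementation of this class of
signature-score pipeline, with a synthetic-cohort generator that provides
ground truth for every stage.

## The method

Starting from a genes × samples expression matrix (FPKM → TPM →
log2(TPM+1), ComBat-style empirical-Bayes batch correction across
cohorts), the derivation chain is:

1. **Consensus clustering** of samples on the 23-gene panel: repeated
   subsampling (80% of samples, 1000 repetitions), clustering at each
   k ∈ 2..9, and accumulation of co-assignment frequencies. The cluster
   number minimizes the **PAC** statistic (proportion of sample pairs with
   consensus in (0.1, 0.9]) — the *TLS clusters*.
2. **Moderated-t differential expression** between the clusters
   (empirical-Bayes variance shrinkage, BH-adjusted p < 0.01), then a
   second consensus clustering on those DEGs — the *gene clusters* — and a
   second DEG screen.
3. **Univariate Cox screening** (Efron ties, Wald p < 0.05) of the
   resulting DEGs against overall survival yields the prognostic genes.
4. **PCA score**: genes are z-scored, the standardized matrix is
   decomposed by SVD, and each sample is scored as

   TLSscore(s) = PC1(s) − PC2(s) = Σᵢ u1ᵢ zᵢₛ − Σᵢ u2ᵢ zᵢₛ

   with the PC1 sign anchored on the favorable-prognosis (HR < 1) genes so
   that a high score tracks good prognosis.
5. **Dichotomization** at the maximally selected log-rank cutpoint
   (candidates inside the (0.1, 0.9) score-quantile window), Kaplan–Meier
   curves and a log-rank test between the high/low groups, and optional
   crossing with a TMB split into four survival strata.

For single-cell data the same 23-gene panel is scored per cell with a
binned-control module score (mean module expression minus the mean of
expression-bin-matched control genes) after QC filtering at the published
thresholds (UMI in [1000, 50000], detected genes in [300, 5000],
hemoglobin fraction ≤ 5%, mitochondrial fraction ≤ 15%).

## Worked example

```python
import tlscore as t
from sklearn.metrics import adjusted_rand_score

spec = t.CohortSpec(n_samples=300, n_genes=1000, effect_size=2.0,
                    beta_surv=0.7, censor_rate=0.3, seed=1)
expr, clinical, truth = t.generate_bulk_cohort(spec)
config = t.PipelineConfig(n_reps=100, seed=1)
art = t.run_derivation(expr, clinical, config,
                       signature_genes=truth.signature_gene_ids)

print("chosen k:", art.tls_clusters.chosen_k)
print("cluster ARI vs latent state:",
      round(adjusted_rand_score(truth.latent_state, art.tls_clusters.labels), 3))
print("prognostic genes:", len(art.prognostic_genes))
rep = art.survival_report
print(f"cutpoint: {rep['cutpoint'].cutpoint:.3f}  "
      f"high/low log-rank p: {rep['logrank_p']:.3g}")
print(art.score_table.head(3).round(3))
```

prints

```
chosen k: 2
cluster ARI vs latent state: 1.0
prognostic genes: 21
cutpoint: -0.660  high/low log-rank p: 5.35e-06
       tlsscore    pc1    pc2 group  cutpoint
S0001    -3.411 -4.623 -1.212   low     -0.66
S0002    -2.430 -2.033  0.397   low     -0.66
S0003     4.271  3.861 -0.409  high     -0.66
```

The generated cohort has two latent TLS states separated by a 2-unit
log-expression shift on the signature block; the consensus step selects
k = 2 (PAC = 0 at k = 2 vs ≥ 0.4 elsewhere) and recovers the states
exactly, and the derived score splits survival with log-rank p ≈ 5×10⁻⁶ —
samples above the cutpoint form the good-prognosis high-score group.

A thin CLI wraps the same library calls:

```bash
tlscore simulate --n-samples 300 --outdir sim/
tlscore run-all --expression sim/expression.tsv --clinical sim/clinical.tsv --outdir run/
tlscore score-bulk --model run/score_model.json --expression sim/expression.tsv --out scores.tsv
tlscore sc-score --mtx-prefix counts --module-gmt module.gmt --out cell_scores.tsv
```

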