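# Methods

This note documents the statistical machinery in `tlscore`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real cohorts.

## Preprocessing

Expression enters as FPKM (or microarray intensities treated as such), is
rescaled per sample to transcripts-per-million (TPM_gs = FPKM_gs / Σ_g
FPKM_gs × 10⁶, so every column sums to 10⁶) and log-transformed as
log2(TPM + 1). Cross-cohort batch effects are removed with the parametric
empirical-Bayes location/scale recipe (ComBat): genes are standardized by
the grand mean and pooled variance, per-batch gene effects (γ, δ²) are
estimated, shrunk toward a normal / inverse-gamma prior whose
hyperparameters are moment-matched across genes, and the data are
back-transformed. Batch correction runs on the log scale (standard
practice; recorded in the provenance output). Only the parametric variant
is implemented. Genes with zero pooled variance cannot be standardized and
pass through unchanged with a warning. Note that EB shrinkage does **not**
exactly re-align batch means when the batch effect is near-constant across
genes (the across-gene effect variance τ² is then small, so individual
gene effects are strongly shrunk toward their common mean); the reference
implementation behaves identically, and our output matches `scanpy.pp.combat`
to ~10⁻³ on shared fixtures.

Duplicate gene symbols keep the max-variance row (logged). A
transposed-input detector flips matrices whose row labels match the
clinical table's sample ids.

## Consensus clustering and PAC

For each of `n_reps` repetitions (default 1000; pipeline checks at 100 for
tractability) a fraction `subsample_frac` = 0.8 of samples is drawn
without replacement and clustered at every k ∈ 2..9. The consensus value
of a sample pair is its co-assignment count divided by its co-sampling
count (pairs never co-sampled score 0 with a warning — vanishingly rare at
the default settings). The cluster number minimizes

PAC = F(0.9) − F(0.1),

the fraction of strictly-upper-triangle consensus entries in (0.1, 0.9]
(entries counted when lower < x ≤ upper; ties in PAC favor smaller k). The
(0.1, 0.9) window is the standard published choice.

**Inner clusterer.** Samples are compared after z-scoring each panel gene.
The default within-subsample clusterer is hierarchical with Euclidean
distance and Ward linkage. A correlation-based variant
(1 − Pearson, average linkage) and k-means are available behind
`inner=`, but correlation distance is *blind by construction* to any
shift component that is uniform across the panel genes — the Pearson
correlation between two samples subtracts each sample's mean profile — so
it cannot detect the coherent up-regulation of a signature block
(measured: ARI ≈ 0.02 on cohorts whose states are separated by 2–4 sd per
gene, vs ARI = 1.0 for the Euclidean/Ward default). Final labels cut a
Ward tree over (1 − consensus); Ward is used here because average linkage
tends to chain individually ambiguous samples into singleton clusters,
which would break the downstream two-group contrasts.

## Differential expression

The two-group screens use a moderated t-statistic: per-gene pooled
variance s²_g with d = n₁+n₂−2 residual df; a scaled inverse-chi-square
prior (d₀, s₀²) fitted by moment-matching on log s²_g (digamma/trigamma
identities, with the trigamma inverse solved by Newton); moderated
variance s̃² = (d₀s₀² + d s²_g)/(d₀+d); t̃ referenced to d₀+d df;
Benjamini–Hochberg step-up adjustment; genes selected at adjusted
p < 0.01. No log-fold-change cutoff is applied (none is part of the
selection rule). Setting the prior df to 0 recovers the ordinary pooled
t exactly — the oracle used in tests. Zero-variance genes are rescued by
the prior and flagged. log-FC is group2 − group1 with groups ordered
lexicographically (recorded in the output header). When a clustering
returns more than two groups, the DEG contrast uses the two largest.

Descriptive group comparisons use Student's t, the Wilcoxon rank-sum
(exact for small tie-free samples, normal approximation with tie
correction otherwise) or one-way ANOVA.

## Survival machinery

* **Kaplan–Meier**: S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) over distinct event
  times; subjects censored at an event time remain at risk through it.
* **Log-rank**: observed-minus-expected with the hypergeometric variance
  at each distinct event time; k-group statistic via the pseudo-inverse of
  the (k−1)-dimensional covariance; the standardized two-group statistic
  z = (O−E)/√V squares to the two-group chi-square (asserted in tests).
* **Cox regression**: Newton–Raphson on the Efron-tie partial likelihood
  (Efron chosen over Breslow for accuracy under ties), convergence at
  |Δℓ| < 10⁻⁹ or 50 iterations with step-halving; Wald SEs from the
  observed information; monotone likelihoods are flagged unconverged with
  |β| capped at 20. Covariates are centered internally for conditioning
  (β is unaffected). The univariate screen keeps genes at Wald p < 0.05.
* **Maximally selected cutpoint**: candidates are the distinct score
  values strictly inside the (0.1, 0.9) quantile window with at least one
  event on each side; each is scored by |z| of the two-group log-rank
  statistic; ties break toward the median score. The selected statistic is
  *not* multiplicity-corrected — the cutpoint only defines groups, and a
  permutation reference is available in the tests.

Time units pass through untouched; the package never converts days/months.

## The signature score

Prognostic genes are z-scored across the training samples (population, n,
denominator — recorded in the model file) and the standardized matrix
decomposed by SVD. The per-sample score is the difference of the first two
principal-component scores, TLSscore = PC1 − PC2. Because SVD signs are
arbitrary, PC1 is anchored so the mean loading over the favorable
(HR < 1) prognostic genes is positive, making high score ↔ good prognosis;
when the favorable set is empty (as on synthetic cohorts where the latent
score raises the hazard, so every prognostic gene has HR > 1) the
largest-|loading| entry of PC1 is made positive instead. PC2's sign is
fixed the same way. A sign rule tied to the score–PC1 correlation would
not work: PC1 and PC2 scores are orthogonal on the training cohort, so
that correlation is unaffected by PC2's sign. New cohorts are scored with
the stored means/sds and loadings, never re-fit; missing model genes are
an error by default (mean-imputation behind a flag).

TMB integration splits TMB at its median (default; maxstat optional),
crosses it with the score group into four strata, tests the four-group
log-rank and reports Pearson/Spearman correlations between score and TMB.
TMB itself is the count of non-silent mutations (Silent/Intron/UTR/Flank
excluded; unknown classes counted or not per config, with a warning)
divided by a 38 Mb exome — a common convention, with a raw-count mode.

## Immune scoring

ssGSEA: per sample, genes are ranked by expression (average ranks for
ties); walking genes in descending order, the enrichment score is
Σᵢ [P_in(i) − P_out(i)] where P_in weights in-set genes by rank^α
(α = 0.25, the original choice) normalized to 1 at the last gene, and
P_out is the unweighted out-of-set ECDF. α = 0 reduces P_in to an
unweighted ECDF. Scores depend only on within-sample ranks. Optional
normalization divides the whole table by its global max−min.

ESTIMATE-style scores: stromal and immune enrichment (unnormalized),
their sum, and purity = cos(0.6049872018 + 0.0001467884 × estimate)
clamped to [0, 1]. The cosine constants were calibrated on a different
platform (TCGA Affymetrix); applied elsewhere they are an approximation,
and the genuine stromal/immune gene lists are not redistributed — the
package ships a clearly-labelled synthetic demo collection and accepts
any GMT.

## Single-cell stages

QC removes cells with UMI above 50,000 or below 1,000, detected genes
above 5,000 or below 300, hemoglobin fraction > 5% or mitochondrial
fraction > 15% — strict inequalities, so boundary values are retained.
Fractions are of counts. Mito/hemoglobin genes are identified by
configurable prefixes (`MT-`; `HBA`/`HBB`). Normalization is
ln(1 + 10⁴·x/total). HVGs are ranked by running-median-detrended log
variance (ties by gene id). The module score bins genes into 24
equal-size average-expression bins and, per module gene, samples 100
control genes from its bin excluding module genes (with replacement if the
bin is small); score = mean(module) − mean(controls), deterministic per
seed, invariant to gene/cell order, and matching `scanpy.tl.score_genes`
to r > 0.95 on shared data. Doublet detection, integration, embedding and
clustering are out of scope; cell-type labels are inputs.

## Synthetic cohorts

The generator emulates the assumed data structure, not HNSCC biology; its
effect sizes are calibration choices, not estimates. Bulk cohorts: two
latent states (B with probability `prop_state_B`), per-sample latent score
= centered state indicator + N(0, 0.15²) jitter; background genes
N(μ_g, σ_g²) on the log-TPM scale (μ_g ~ U(1,6), σ_g ~ U(0.8,1.2)); the
23 signature genes (ids `SIG001…`, deliberately namespaced to avoid
implying real gene biology) gain `effect_size` in state B; batch j adds
`batch_shift·j` and scales noise by `batch_scale^j`. Survival is
exponential with hazard h₀·exp(β_surv·score) — exponential rather than
Weibull so censoring horizons have closed form — censored by an
independent Uniform(0, τ) with τ solved by root-finding for the target
censor rate. Mutation counts are negative binomial with log-mean
α + tmb_β·score (tmb_β < 0 by default, mimicking the observed score–TMB
anti-correlation), written as a MAF-like table with extra silent rows.
Single-cell counts are negative binomial with lognormal depth (~6,000
UMI), a module-enriched cell type (default 4-fold), and an exactly
controlled fraction of cells forced to violate one QC threshold each.

Defaults (n = 300, G = 1000, δ = 2, β_surv = 0.7, censor 0.3,
tmb_β = −0.6) define the standing study conditions; the acceptance
checks run at these sizes with consensus repetitions reduced to 100, the
null-calibration checks at G = 2000 and 200 Cox replicates of n = 500 —
sizes chosen so the whole acceptance run completes in well under a minute
on one core.

What passing these tests shows: the pipeline recovers planted two-state
structure, an injected hazard gradient and an injected TMB slope, with
calibrated error rates, under Gaussian log-expression with independent
background genes. What it does not show: robustness to correlated
background structure, non-Gaussian noise, platform mixtures beyond
location/scale batch effects, or informative censoring — none of which
the generator emulates.

## Numerical details and edge cases

* All RNG flows through `numpy.random.default_rng` with explicit seeds;
  fixed seed ⇒ bit-identical outputs.
* Consensus matrices are symmetrized with unit diagonal; degenerate
  (zero-variance) features are dropped with a warning.
* Cox: constant covariates are an error naming the covariate; ≥1 event
  required.
* maxstat requires ≥10 samples and at least one valid candidate, else
  errors; adding a constant to all scores shifts the cutpoint by exactly
  that constant.
* The derivation aborts with the failing stage's name and retains partial
  artifacts; a null (no-signal) cohort aborts at the DEG stage because no
  gene passes adjusted p < 0.01 — by design, as the selection rule then
  has nothing to carry forward.
* Provenance sidecars record config, seeds, package version and input
  SHA-256 hashes; re-running a config is bit-identical.

## Known limitations

* The moderated-t prior fit assumes a common variance prior across all
  genes; heavy-tailed variance distributions will be under-shrunk.
* The PAC criterion compares a fixed k range and cannot flag "no
  structure" as such (k = 2 is still returned for null data, just with
  high PAC).
* ESTIMATE purity constants are platform-specific (see above).
* Multivariate Cox supports generic numeric/one-hot covariates only; no
  time-dependent covariates, stratification or proportionality
  diagnostics.
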