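"""Synthetic cohorts with known ground truth.

The generator emulates the data structure the bulk pipeline assumes: two
latent TLS states separated by a mean shift on a block of signature genes,
survival hazards tied to the latent score, cross-cohort batch
location/scale effects, mutation burden anti-correlated with the latent
score, and negative-binomial single-cell counts with one module-enriched
cell type. Every output is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .preprocess import ClinicalTable, ExpressionMatrix
from .singlecell import CellMatrix

#: sd of the within-state jitter on the latent score (the state indicator
#: itself has sd 0.5 at balanced proportions)
LATENT_NOISE_SD = 0.15

NONSYNONYMOUS_CLASSES = (
    ("Missense_Mutation", 0.70),
    ("Nonsense_Mutation", 0.10),
    ("Frame_Shift_Del", 0.07),
    ("Frame_Shift_Ins", 0.07),
    ("Splice_Site", 0.06),
)
SILENT_FRACTION = 0.18  # extra silent rows relative to the nonsynonymous count


@dataclass
class CohortSpec:
    """Parameters of one synthetic bulk cohort.

    effect_size is the mean log-expression shift (delta) added to the
    signature-gene block in latent state B; beta_surv is the log-hazard per
    unit latent score; tmb_beta the log-mean mutation-count slope against
    the latent score (negative mimics the observed score-TMB
    anti-correlation); batch j (0-based) adds ``batch_shift * j`` and
    scales residual noise by ``batch_scale ** j``.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_signature_genes: int = 23
    effect_size: float = 2.0
    prop_state_B: float = 0.5
    n_batches: int = 1
    batch_shift: float = 0.0
    batch_scale: float = 1.0
    baseline_hazard: float = 0.02
    beta_surv: float = 0.7
    censor_rate: float = 0.3
    tmb_beta: float = -0.6
    tmb_alpha: float = math.log(60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.n_signature_genes < 1:
            raise ValueError("sizes must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes exceeds n_genes")
        if not (0 < self.prop_state_B < 1):
            raise ValueError("prop_state_B must lie in (0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_scale <= 0 or self.baseline_hazard <= 0:
            raise ValueError("batch_scale and baseline_hazard must be positive")
        finite_fields = ["effect_size", "prop_state_B", "batch_shift", "batch_scale",
                         "baseline_hazard", "beta_surv", "censor_rate", "tmb_beta"]
        for name in finite_fields:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite spec value for {name}")
        # tmb_alpha = -inf is the degenerate all-zero-counts limit and is allowed
        if np.isnan(self.tmb_alpha) or self.tmb_alpha == np.inf:
            raise ValueError("tmb_alpha must be finite or -inf")


@dataclass
class GroundTruth:
    """Latent structure behind one generated cohort."""

    latent_state: np.ndarray  # 'A' / 'B' per sample
    latent_score: np.ndarray
    batch: np.ndarray
    signature_gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"latent_state": self.latent_state,
                             "latent_score": self.latent_score,
                             "batch": self.batch},
                            index=self.sample_ids)


def _censor_tau(rates: np.ndarray, target: float) -> float:
    """Solve for the Uniform(0, tau) horizon giving the target censor rate.

    With T ~ Exp(rate) and C ~ Uniform(0, tau) independent,
    P(C < T) = E[min(T, tau)] / tau = mean_i (1 - exp(-rate_i tau)) / (rate_i tau).
    """
    def censored_prob(tau):
        x = rates * tau
        return float(np.mean(-np.expm1(-x) / x)) - target

    lo, hi = 1e-9, 1.0
    while censored_prob(hi) > 0 and hi < 1e12:
        hi *= 10.0
    return brentq(censored_prob, lo, hi)


def generate_bulk_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Generate one bulk cohort on the log-TPM scale.

    Background genes are Normal(mu_g, sigma_g^2); the signature block gains
    ``effect_size`` in state B. Survival is exponential with hazard
    baseline_hazard * exp(beta_surv * latent_score), censored by an
    independent Uniform(0, tau) with tau solved for the target censor rate.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    sig = spec.n_signature_genes

    gene_ids = [f"SIG{i + 1:03d}" for i in range(sig)] + \
               [f"G{i + 1:05d}" for i in range(g - sig)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    state_b = rng.random(n) < spec.prop_state_B
    latent_state = np.where(state_b, "B", "A")
    latent_score = (state_b.astype(float) - spec.prop_state_B) \
        + rng.normal(0.0, LATENT_NOISE_SD, size=n)

    batch_idx = rng.integers(0, spec.n_batches, size=n)
    batch = np.array([f"batch{j + 1}" for j in batch_idx])

    mu = rng.uniform(1.0, 6.0, size=g)
    sigma = np.concatenate([np.ones(sig), rng.uniform(0.8, 1.2, size=g - sig)])

    X = mu[:, None] + rng.normal(0.0, 1.0, size=(g, n)) \
        * (sigma[:, None] * (spec.batch_scale ** batch_idx)[None, :])
    X[:sig, :] += spec.effect_size * state_b[None, :]
    X += spec.batch_shift * batch_idx[None, :]

    expr = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=sample_ids),
                            unit="logTPM",
                            batch=pd.Series(batch, index=sample_ids, name="batch"))

    rates = spec.baseline_hazard * np.exp(spec.beta_surv * latent_score)
    t_event = rng.exponential(1.0 / rates)
    if spec.censor_rate > 0:
        tau = _censor_tau(rates, spec.censor_rate)
        c = rng.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    clinical = ClinicalTable(pd.DataFrame({
        "time": time, "event": event,
        "age": rng.integers(35, 85, size=n),
        "gender": rng.choice(["F", "M"], size=n),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n),
    }, index=sample_ids))

    truth = GroundTruth(latent_state=latent_state, latent_score=latent_score,
                        batch=batch, signature_gene_ids=gene_ids[:sig],
                        sample_ids=sample_ids)
    return expr, clinical, truth


def as_fpkm_like(m: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Turn a log-TPM matrix into FPKM-like input (exercises fpkm_to_tpm).

    Inverts the log transform and multiplies each sample by a lognormal
    library-size factor, which fpkm_to_tpm must cancel.
    """
    rng = np.random.default_rng(seed)
    tpm = np.exp2(m.values.to_numpy()) - 1.0
    tpm = np.clip(tpm, 0.0, None)
    factors = rng.lognormal(0.0, 0.5, size=tpm.shape[1])
    fpkm = tpm * factors[None, :]
    return ExpressionMatrix(pd.DataFrame(fpkm, index=m.values.index,
                                         columns=m.values.columns),
                            unit="FPKM",
                            batch=None if m.batch is None else m.batch.copy())


def generate_mutation_table(spec: CohortSpec, truth: GroundTruth,
                            dispersion: float = 5.0) -> pd.DataFrame:
    """MAF-like mutation table tied to the latent score.

    Per-sample nonsynonymous counts are negative binomial with
    log-mean ``tmb_alpha + tmb_beta * latent_score`` and fixed dispersion;
    extra silent rows are added at a constant relative rate. Returns a
    DataFrame with Tumor_Sample_Barcode, Hugo_Symbol and
    Variant_Classification columns (samples with zero mutations have no
    rows).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    mu = np.exp(spec.tmb_alpha + spec.tmb_beta * truth.latent_score)
    counts = np.zeros(len(mu), dtype=int)
    positive = mu > 0
    if positive.any():
        p = dispersion / (dispersion + mu[positive])
        counts[positive] = rng.negative_binomial(dispersion, p)

    classes, weights = zip(*NONSYNONYMOUS_CLASSES)
    weights = np.array(weights) / sum(weights)
    rows = []
    for sample, n_mut in zip(truth.sample_ids, counts):
        if n_mut == 0:
            continue
        genes = rng.integers(0, 20000, size=n_mut)
        cls = rng.choice(classes, size=n_mut, p=weights)
        for gi, ci in zip(genes, cls):
            rows.append((sample, f"GENE{gi:05d}", ci))
        n_silent = rng.poisson(SILENT_FRACTION * n_mut)
        for gi in rng.choice(20000, size=n_silent):
            rows.append((sample, f"GENE{gi:05d}", "Silent"))
    table = pd.DataFrame(rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol",
                                        "Variant_Classification"])
    table.attrs["nonsynonymous_counts"] = pd.Series(counts, index=truth.sample_ids)
    return table


def generate_single_cell(n_cells: int, n_genes: int, cell_type_props: dict[str, float],
                         module_genes: list[str], enriched_type: str, seed: int = 0,
                         enrichment: float = 4.0, qc_violation_frac: float = 0.0,
                         target_depth: float = 6000.0,
                         dispersion: float = 2.0) -> CellMatrix:
    """Negative-binomial single-cell counts with one module-enriched type.

    ``cell_type_props`` maps type label -> proportion (must sum to 1);
    module genes get ``enrichment``-fold mean expression in
    ``enriched_type``. A ``qc_violation_frac`` fraction of cells is forced
    to violate exactly one QC threshold each (deep/shallow depth, high
    mitochondrial or hemoglobin fraction); the remainder are drawn well
    inside the bounds.
    """
    if not module_genes:
        raise ValueError("empty module gene set")
    props = dict(cell_type_props)
    if abs(sum(props.values()) - 1.0) > 1e-8:
        raise ValueError("cell type proportions must sum to 1")
    if enriched_type not in props:
        raise ValueError(f"enriched_type {enriched_type!r} not among cell types")

    rng = np.random.default_rng(seed)
    types = sorted(props)
    cell_type = rng.choice(types, size=n_cells, p=[props[t] for t in types])

    gene_ids = list(module_genes) + [f"BG{i + 1:05d}" for i in range(n_genes - len(module_genes))]
    if len(gene_ids) != n_genes:
        raise ValueError("module_genes longer than n_genes")
    module_idx = np.arange(len(module_genes))

    base = rng.lognormal(0.0, 1.0, size=n_genes)
    base = base / base.sum()  # relative expression profile

    depth = rng.lognormal(np.log(target_depth), 0.25, size=n_cells)
    mean = depth[:, None] * base[None, :]
    enriched = cell_type == enriched_type
    mean[np.ix_(enriched, module_idx)] *= enrichment
    # renormalize so enrichment changes composition, not depth
    mean *= (depth / mean.sum(axis=1))[:, None]

    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p)

    frac_mito = rng.beta(2.0, 38.0, size=n_cells) * 0.5  # mean ~2.5%, < 15%
    frac_hgb = rng.beta(1.0, 99.0, size=n_cells) * 0.5   # mean ~0.25%, < 5%
    frac_mito = np.clip(frac_mito, 0.0, 0.12)
    frac_hgb = np.clip(frac_hgb, 0.0, 0.04)

    n_viol = int(round(qc_violation_frac * n_cells))
    if n_viol:
        viol_cells = rng.choice(n_cells, size=n_viol, replace=False)
        kinds = rng.integers(0, 4, size=n_viol)
        for ci, kind in zip(viol_cells, kinds):
            if kind == 0:      # UMI too high
                factor = int(np.ceil(60_000 / max(counts[ci].sum(), 1)))
                counts[ci] *= factor + 1
            elif kind == 1:    # UMI too low
                keep = rng.random(n_genes) < (500.0 / max(counts[ci].sum(), 1))
                counts[ci] = np.where(keep, counts[ci], 0)
            elif kind == 2:
                frac_mito[ci] = rng.uniform(0.16, 0.5)
            else:
                frac_hgb[ci] = rng.uniform(0.06, 0.2)

    cell_ids = [f"C{i + 1:05d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=gene_ids)
    qc = pd.DataFrame({
        "total_umi": counts.sum(axis=1),
        "n_genes_detected": (counts > 0).sum(axis=1),
        "frac_mito": frac_mito,
        "frac_hemoglobin": frac_hgb,
    }, index=cell_ids)
    return CellMatrix(counts=counts_df, qc=qc,
                      cell_type=pd.Series(cell_type, index=cell_ids, name="cell_type"))
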