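import numpy as np
import pytest

import tlscore as t


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort with clear two-state structure."""
    spec = t.CohortSpec(n_samples=120, n_genes=300, effect_size=2.0,
                        censor_rate=0.3, seed=3)
    expr, clinical, truth = t.generate_bulk_cohort(spec)
    return spec, expr, clinical, truth


@pytest.fixture(scope="session")
def derivation(small_cohort):
    """Full derivation on the small cohort (reduced consensus repetitions)."""
    spec, expr, clinical, truth = small_cohort
    config = t.PipelineConfig(n_reps=30)
    art = t.run_derivation(expr.copy(), clinical, config,
                           signature_genes=truth.signature_gene_ids)
    return spec, art, clinical, truth


@pytest.fixture(scope="session")
def sc_matrix():
    """Single-cell matrix with a 4-fold module-enriched T/NK population."""
    module = [f"MOD{i:02d}" for i in range(1, 24)]
    cm = t.generate_single_cell(
        n_cells=500, n_genes=800,
        cell_type_props={"T_NK": 0.3, "B": 0.2, "myeloid": 0.25, "epithelial": 0.25},
        module_genes=module, enriched_type="T_NK", seed=11,
        enrichment=4.0, qc_violation_frac=0.0)
    return cm, module


@pytest.fixture(scope="session")
def sc_normed(sc_matrix):
    cm, module = sc_matrix
    return t.normalize_log1p(t.qc_filter(cm)), module
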