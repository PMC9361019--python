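import numpy as np
import pandas as pd
import pytest

from hccstem import (
    SimulationConfig,
    center_by_compendium,
    generate_gene_sets,
    generate_reference_compendium,
    generate_tumor_cohort,
    score_mrnasi,
    train_oclr,
)


@pytest.fixture(scope="session")
def sim_small():
    """Reduced simulated study shared across tests: reference + cohort +
    gene sets at the recovery-check condition (stem_effect=2, seed=7)."""
    cfg = SimulationConfig(seed=7, stem_effect=2.0)
    X_ref, labels, truth = generate_reference_compendium(cfg)
    X_cohort, clinical, truth = generate_tumor_cohort(cfg, truth)
    gene_sets = generate_gene_sets(cfg, truth)
    return {
        "config": cfg,
        "X_ref": X_ref,
        "labels": labels,
        "X_cohort": X_cohort,
        "clinical": clinical,
        "gene_sets": gene_sets,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def trained_model(sim_small):
    X_centered, means = center_by_compendium(sim_small["X_ref"])
    stem = sim_small["labels"].index[sim_small["labels"] == "stem"]
    return train_oclr(X_centered[stem], centering_means=means)


@pytest.fixture(scope="session")
def cohort_scores(trained_model, sim_small):
    return score_mrnasi(trained_model, sim_small["X_cohort"])


def make_blob_matrix(n_per_blob=20, n_genes=100, separation=5.0, seed=0):
    """Two blobs separated by a +/- patterned mean shift of `separation`
    noise-sd units (half the genes up in blob A, half down), so the
    structure is visible to correlation-based distances."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_blob
    X = rng.normal(0.0, 1.0, size=(n_genes, n))
    pattern = np.concatenate([np.ones(n_genes // 2), -np.ones(n_genes - n_genes // 2)])
    X[:, :n_per_blob] += (pattern * separation / 2)[:, None]
    X[:, n_per_blob:] -= (pattern * separation / 2)[:, None]
    return pd.DataFrame(
        X,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def blob_matrix():
    return make_blob_matrix()
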