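"""Synthetic data generation for the stemness-index pipeline.

Every downstream stage of the analysis (OCLR training, mRNAsi scoring,
subgroup discovery, enrichment, network inference, signature fitting,
survival) can be exercised on data produced here.  The generator emulates
three ingredients of the real study design:

* a reference compendium of stem vs differentiated samples carrying a
  planted "stemness program" — a subset of genes whose mean log2
  expression is shifted in stem samples, half upward and half downward
  (stemness markers rise while differentiation markers fall, and a
  signed program is what makes the correlation-geometry of the
  downstream clustering non-degenerate);
* a tumor cohort in which a latent per-sample stemness level drives both
  a binary drug-response label (logistic link) and survival hazard
  (log-linear proportional hazards on an exponential baseline);
* a four-gene linear-Gaussian regulatory chain (RXRB -> NR1H3 -> CYP8B1
  -> SCD analogs) embedded in one pathway-like gene set, with a mean
  shift of the chain root in non-responders.

All randomness is drawn from per-operation RNG streams derived from
``(seed, operation name)`` so adding operations never perturbs the draws
of earlier ones, and identical configs are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import GeneSetDB

PANEL_GENES = ("RXRB", "NR1H3", "CYP8B1", "SCD")

__all__ = [
    "PANEL_GENES",
    "SimulationConfig",
    "GroundTruth",
    "generate_reference_compendium",
    "generate_tumor_cohort",
    "generate_gene_sets",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are a reduced-scale emulation of the study conditions: a
    stem-cell reference compendium, a sorafenib-treated cohort with a
    roughly two-thirds non-response rate, and a planted four-gene chain.
    """

    n_genes: int = 1000
    n_stem: int = 60
    n_diff: int = 60
    n_stemness_genes: int = 80
    stem_effect: float = 4.0
    n_cohort: int = 150
    response_slope: float = 16.0
    response_intercept: float = -5.0
    hazard_coef: float = 1.5
    censor_rate: float = 0.3
    chain_coefs: tuple[float, float, float] = (0.9, 0.9, 0.9)
    panel_shift: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_stem", "n_diff", "n_stemness_genes", "n_cohort"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if self.n_stemness_genes >= self.n_genes:
            raise ValueError("n_stemness_genes must be < n_genes")
        if self.n_genes < len(PANEL_GENES) + self.n_stemness_genes:
            raise ValueError("n_genes too small to hold program and panel genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if len(self.chain_coefs) != 3:
            raise ValueError("chain_coefs must have exactly 3 entries")
        self.chain_coefs = tuple(float(c) for c in self.chain_coefs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent quantities the generators planted, for recovery checks."""

    stemness_gene_ids: list[str]
    gene_means: pd.Series
    program_signs: pd.Series | None = None
    panel_genes: list[str] = field(default_factory=lambda: list(PANEL_GENES))
    latent_stemness: pd.Series | None = None
    true_response: pd.Series | None = None
    true_chain_edges: list[tuple[str, str]] = field(default_factory=list)
    true_cluster: pd.Series | None = None

    def to_json_dict(self) -> dict:
        return {
            "stemness_gene_ids": list(self.stemness_gene_ids),
            "panel_genes": list(self.panel_genes),
            "gene_means": {k: float(v) for k, v in self.gene_means.items()},
            "program_signs": None
            if self.program_signs is None
            else {k: int(v) for k, v in self.program_signs.items()},
            "latent_stemness": None
            if self.latent_stemness is None
            else {k: float(v) for k, v in self.latent_stemness.items()},
            "true_response": None
            if self.true_response is None
            else dict(self.true_response),
            "true_chain_edges": [list(e) for e in self.true_chain_edges],
            "true_cluster": None
            if self.true_cluster is None
            else {k: int(v) for k, v in self.true_cluster.items()},
        }


def _stream(config: SimulationConfig, op_name: str) -> np.random.Generator:
    """One RNG stream per generator operation, keyed by (seed, op name)."""
    op_key = zlib.crc32(op_name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, op_key]))


def _gene_ids(config: SimulationConfig) -> list[str]:
    n_generic = config.n_genes - len(PANEL_GENES)
    width = len(str(n_generic))
    ids = [f"G{i + 1:0{width}d}" for i in range(n_generic)]
    return ids + list(PANEL_GENES)


def generate_reference_compendium(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate the stem/differentiated reference compendium.

    Returns ``(expression, sample_labels, truth)`` where expression is a
    genes x samples log2-scale matrix, labels take values ``stem`` /
    ``differentiated`` and the truth records the planted program genes
    and the per-gene baseline means shared with the tumor cohort.
    """
    rng = _stream(config, "reference_compendium")
    genes = _gene_ids(config)
    samples = [f"SC{i + 1:03d}" for i in range(config.n_stem)] + [
        f"DF{i + 1:03d}" for i in range(config.n_diff)
    ]
    labels = pd.Series(
        ["stem"] * config.n_stem + ["differentiated"] * config.n_diff,
        index=samples,
        name="label",
    )

    means = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes),
        index=genes,
        name="gene_mean",
    )
    # program genes drawn from the generic pool; panel genes stay out of it
    program = list(rng.choice(genes[: -len(PANEL_GENES)], size=config.n_stemness_genes, replace=False))
    # signed program: first half up in stem samples, second half down
    n_up = (config.n_stemness_genes + 1) // 2
    signs = pd.Series(
        [1] * n_up + [-1] * (config.n_stemness_genes - n_up), index=program, name="sign"
    )

    values = means.to_numpy()[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(samples))
    )
    X = pd.DataFrame(values, index=genes, columns=samples)
    stem_cols = labels.index[labels == "stem"]
    X.loc[program, stem_cols] += signs.to_numpy()[:, None] * config.stem_effect

    truth = GroundTruth(stemness_gene_ids=program, gene_means=means, program_signs=signs)
    return X, labels, truth


def generate_tumor_cohort(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a treated tumor cohort sharing the reference gene universe.

    Latent stemness ``s_i ~ Uniform(0, 1)`` shifts the program genes by
    ``s_i * stem_effect``, drives the probability of non-response through
    a logistic link, and multiplies the exponential event hazard by
    ``exp(hazard_coef * s_i)``.  Four panel genes follow the planted
    linear-Gaussian chain with a mean shift of the root in
    non-responders.

    Returns ``(expression, clinical, truth)``; clinical has columns
    ``sample_id, time_months, event, response``.
    """
    if truth is None or truth.gene_means is None:
        raise ValueError("reference compendium must be generated first")
    rng = _stream(config, "tumor_cohort")
    genes = list(truth.gene_means.index)
    samples = [f"HCC{i + 1:03d}" for i in range(config.n_cohort)]

    s = rng.uniform(0.0, 1.0, size=config.n_cohort)
    values = truth.gene_means.to_numpy()[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(genes), config.n_cohort)
    )
    X = pd.DataFrame(values, index=genes, columns=samples)
    signs = (
        truth.program_signs.reindex(truth.stemness_gene_ids).to_numpy()
        if truth.program_signs is not None
        else np.ones(len(truth.stemness_gene_ids))
    )
    X.loc[truth.stemness_gene_ids] += signs[:, None] * s[None, :] * config.stem_effect

    # binary response: higher stemness -> higher non-response probability
    logit = config.response_intercept + config.response_slope * s
    p_nonresp = 1.0 / (1.0 + np.exp(-logit))
    nonresp = rng.uniform(size=config.n_cohort) < p_nonresp
    response = pd.Series(
        np.where(nonresp, "non_responder", "responder"), index=samples, name="response"
    )

    # four-gene linear-Gaussian chain, root shifted in non-responders
    g1, g2, g3, g4 = truth.panel_genes
    c1, c2, c3 = config.chain_coefs
    e = rng.normal(0.0, config.noise_sd, size=(4, config.n_cohort))
    z1 = config.panel_shift * nonresp.astype(float) + e[0]
    z2 = c1 * z1 + e[1]
    z3 = c2 * z2 + e[2]
    z4 = c3 * z3 + e[3]
    for gene, z in zip((g1, g2, g3, g4), (z1, z2, z3, z4)):
        X.loc[gene] = truth.gene_means[gene] + z

    # exponential survival under proportional hazards; baseline median 30 mo
    h0 = np.log(2.0) / 30.0
    hazard = h0 * np.exp(config.hazard_coef * s)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=config.n_cohort) < config.censor_rate
    t_obs = np.where(censored, t_event * rng.uniform(size=config.n_cohort), t_event)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time_months": t_obs,
            "event": (~censored).astype(int),
            "response": response.to_numpy(),
        }
    )

    truth.latent_stemness = pd.Series(s, index=samples, name="latent_stemness")
    truth.true_response = response
    truth.true_chain_edges = [(g1, g2), (g2, g3), (g3, g4)]
    truth.true_cluster = pd.Series(
        np.where(s > np.median(s), 1, 0), index=samples, name="true_cluster"
    )
    return X, clinical, truth


def generate_gene_sets(
    config: SimulationConfig,
    truth: GroundTruth,
    n_random_sets: int = 8,
    random_set_size: int = 20,
) -> GeneSetDB:
    """Build a GMT-writable gene-set collection over the simulated universe.

    Contains one pathway-like set holding the four panel genes plus the
    stemness program, one set of pure noise genes, and ``n_random_sets``
    random sets.
    """
    if random_set_size > config.n_genes:
        raise ValueError("random_set_size exceeds the gene universe")
    if n_random_sets < 0:
        raise ValueError("n_random_sets must be >= 0")
    rng = _stream(config, "gene_sets")
    genes = list(truth.gene_means.index)
    signal_genes = set(truth.stemness_gene_ids) | set(truth.panel_genes)
    noise_pool = [g for g in genes if g not in signal_genes]

    names, members, descs = [], [], []
    names.append("PPAR_SIGNALING_LIKE")
    members.append(list(truth.panel_genes) + list(truth.stemness_gene_ids))
    descs.append("planted pathway: panel chain plus stemness program")

    noise_size = min(max(random_set_size, 5), len(noise_pool))
    names.append("NOISE_ONLY")
    members.append(list(rng.choice(noise_pool, size=noise_size, replace=False)))
    descs.append("pure noise genes, no planted signal")

    size = max(5, random_set_size)
    for i in range(n_random_sets):
        names.append(f"RANDOM_{i + 1:02d}")
        members.append(list(rng.choice(genes, size=size, replace=False)))
        descs.append("random draw from the gene universe")

    return GeneSetDB(dict(zip(names, members)), dict(zip(names, descs)))
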