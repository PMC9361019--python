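"""PCA-based drug-response signature over a small gene panel.

The four-gene panel (RXRB, NR1H3, CYP8B1, SCD analogs) is standardized
per gene and reduced to its first two principal components; a sample's
signature score is the sum of its coordinates on PC1 and PC2
(score = dim1 + dim2).  An ROC curve against observed response picks
the cutoff closest to the (0, 1) corner; samples scoring strictly above
the cutoff are predicted non-responders (resistant).

Component signs are pinned (largest-|loading| entry positive) so the
score — and hence any published cutoff — has a well-defined sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_PANEL = ("RXRB", "NR1H3", "CYP8B1", "SCD")
DEFAULT_CUTOFF = -0.56

__all__ = [
    "DEFAULT_PANEL",
    "DEFAULT_CUTOFF",
    "SignaturePanel",
    "SignatureScores",
    "ROCResult",
    "fit_signature",
    "score_signature",
    "roc_curve",
    "classify_response",
]


@dataclass
class SignaturePanel:
    gene_ids: list[str]
    standardization_means: np.ndarray
    standardization_sds: np.ndarray
    loadings: np.ndarray  # 2 x n_genes, unit rows
    explained_variance: np.ndarray

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "gene_ids": self.gene_ids,
                    "standardization_means": self.standardization_means.tolist(),
                    "standardization_sds": self.standardization_sds.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SignaturePanel":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=d["gene_ids"],
            standardization_means=np.array(d["standardization_means"]),
            standardization_sds=np.array(d["standardization_sds"]),
            loadings=np.array(d["loadings"]),
            explained_variance=np.array(d["explained_variance"]),
        )


@dataclass
class SignatureScores:
    sample_ids: list[str]
    dim1: np.ndarray
    dim2: np.ndarray
    predicted: list[str] | None = None

    @property
    def pparscore(self) -> np.ndarray:
        return self.dim1 + self.dim2

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"dim1": self.dim1, "dim2": self.dim2, "pparscore": self.pparscore},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        if self.predicted is not None:
            out["predicted"] = self.predicted
        return out

    def score_series(self) -> pd.Series:
        return pd.Series(self.pparscore, index=self.sample_ids, name="pparscore")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def fit_signature(X_panel: pd.DataFrame) -> SignaturePanel:
    """Fit the 2-component PCA on standardized panel expression.

    ``X_panel`` is genes x samples restricted to the panel.  Genes are
    centered and scaled to unit variance on this fitting cohort;
    loadings are the top-2 right singular vectors of the standardized
    samples x genes matrix, sign-fixed so each component's
    largest-|loading| entry is positive.
    """
    if X_panel.shape[1] < 3:
        raise ValueError("need at least 3 samples to fit the signature")
    means = X_panel.mean(axis=1).to_numpy()
    sds = X_panel.std(axis=1, ddof=1).to_numpy()
    if (sds <= 0).any():
        bad = [g for g, s in zip(X_panel.index, sds) if s <= 0]
        raise ValueError(f"zero-variance panel gene(s): {bad}")
    Z = ((X_panel.to_numpy(dtype=float) - means[:, None]) / sds[:, None]).T  # samples x genes
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:2].copy()
    for a in range(2):
        j = int(np.argmax(np.abs(loadings[a])))
        if loadings[a, j] < 0:
            loadings[a] = -loadings[a]
    n = Z.shape[0]
    explained = (S[:2] ** 2) / (n - 1)
    return SignaturePanel(
        gene_ids=list(X_panel.index),
        standardization_means=means,
        standardization_sds=sds,
        loadings=loadings,
        explained_variance=explained,
    )


def score_signature(panel: SignaturePanel, X_new: pd.DataFrame) -> SignatureScores:
    """Project new samples onto the stored loadings.

    New samples are standardized with the panel's stored means/sds so a
    small validation cohort never needs its own (unstable) refit.
    """
    missing = [g for g in panel.gene_ids if g not in X_new.index]
    if missing:
        raise KeyError(f"panel gene(s) missing from cohort: {missing}")
    Xp = X_new.loc[panel.gene_ids].to_numpy(dtype=float)
    Z = ((Xp - panel.standardization_means[:, None]) / panel.standardization_sds[:, None]).T
    coords = Z @ panel.loadings.T
    return SignatureScores(list(X_new.columns), coords[:, 0], coords[:, 1])


def roc_curve(scores: pd.Series | np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC of score vs binary label (1 = positive class).

    AUC uses the Mann-Whitney identity with ties counted 1/2.  The
    operating cutoff minimises the squared distance to the top-left
    corner, (1 - sens)^2 + (1 - spec)^2, with ties broken by higher
    sensitivity then lower threshold; a sample is called positive when
    its score is strictly greater than the cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    pos, neg = s[y == 1], s[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (n_pos * n_neg)

    # candidate thresholds: below the minimum, every unique score
    uniq = np.unique(s)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    tpr = np.array([(pos > t).mean() for t in thresholds])
    fpr = np.array([(neg > t).mean() for t in thresholds])

    d2 = (1.0 - tpr) ** 2 + fpr**2
    best = np.flatnonzero(d2 == d2.min())
    # prefer higher sensitivity, then the lower threshold
    best = best[tpr[best] == tpr[best].max()]
    i = int(best[np.argmin(thresholds[best])])
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=float(auc),
        optimal_cutoff=float(thresholds[i]),
        sensitivity_at_cutoff=float(tpr[i]),
        specificity_at_cutoff=float(1.0 - fpr[i]),
    )


def classify_response(
    scores: pd.Series, cutoff: float = DEFAULT_CUTOFF
) -> pd.Series:
    """Predict non_responder when score > cutoff (strict), else responder."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(
        np.where(np.asarray(scores, float) > cutoff, "non_responder", "responder"),
        index=scores.index if isinstance(scores, pd.Series) else None,
        name="predicted",
    )
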