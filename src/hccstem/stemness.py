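"""One-class logistic regression (OCLR) stemness model and mRNAsi scoring.

The stemness index works in two phases.  Training fits a per-gene weight
vector ``w`` on stem-cell reference samples only, by minimising the
penalised one-class logistic objective

    J(w) = -(1/n) sum_i log sigma(w^T x_i) + l1*||w||_1 + (l2/2)*||w||_2^2

with no intercept, where ``x_i`` is a reference sample centered by the
per-gene mean of the FULL compendium (stem + differentiated).  Centering
by the full compendium is essential: if the training subset centered
itself, the smooth gradient would vanish at the origin and ``w = 0``
would be the exact penalised optimum.

Scoring computes, for each cohort sample, Spearman's correlation between
``w`` and the sample's expression profile over the shared genes, then
min-max rescales the correlations to [0, 1] within the cohort — the
mRNAsi.  Higher mRNAsi means a less differentiated, more stem-like
sample.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StemnessModel",
    "StemnessScores",
    "ConvergenceError",
    "center_by_compendium",
    "train_oclr",
    "score_mrnasi",
    "correlate_genes_with_stemness",
    "oclr_objective",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class StemnessModel:
    gene_ids: list[str]
    weights: np.ndarray
    l1: float
    l2: float
    n_train: int
    centering_means: np.ndarray
    n_iter: int
    final_objective: float
    final_subgrad_norm: float
    converged: bool = True

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids, name="weight")

    def save(self, table_path: str | Path, meta_path: str | Path | None = None) -> None:
        pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "weight": self.weights,
                "centering_mean": self.centering_means,
            }
        ).to_csv(table_path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "l1": self.l1,
                "l2": self.l2,
                "n_train": self.n_train,
                "n_iter": self.n_iter,
                "final_objective": self.final_objective,
                "final_subgrad_norm": self.final_subgrad_norm,
                "converged": self.converged,
            }
            Path(meta_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, table_path: str | Path, meta_path: str | Path | None = None) -> "StemnessModel":
        tab = pd.read_csv(table_path, sep="\t")
        meta = {}
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
        return cls(
            gene_ids=tab["gene_id"].astype(str).tolist(),
            weights=tab["weight"].to_numpy(float),
            centering_means=tab["centering_mean"].to_numpy(float),
            l1=float(meta.get("l1", 0.0)),
            l2=float(meta.get("l2", 1.0)),
            n_train=int(meta.get("n_train", 0)),
            n_iter=int(meta.get("n_iter", 0)),
            final_objective=float(meta.get("final_objective", np.nan)),
            final_subgrad_norm=float(meta.get("final_subgrad_norm", np.nan)),
            converged=bool(meta.get("converged", True)),
        )


@dataclass
class StemnessScores:
    sample_ids: list[str]
    rho: np.ndarray
    mrnasi: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho": self.rho, "mrnasi": self.mrnasi},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def mrnasi_series(self) -> pd.Series:
        return pd.Series(self.mrnasi, index=self.sample_ids, name="mrnasi")

    def save(self, path: str | Path) -> None:
        self.frame().to_csv(path, sep="\t", float_format="%.10g")


def center_by_compendium(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Center each gene by its mean across all reference samples."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 reference samples to center")
    means = X.mean(axis=1)
    return X.sub(means, axis=0), means


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable log sigma(z) = -log(1 + exp(-z))
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = -np.log1p(np.exp(-z[pos]))
    out[~pos] = z[~pos] - np.log1p(np.exp(z[~pos]))
    return out


def oclr_objective(w: np.ndarray, X: np.ndarray, l1: float, l2: float) -> float:
    """Penalised one-class objective; X is genes x samples."""
    z = X.T @ w
    n = X.shape[1]
    return float(
        -np.mean(_log_sigmoid(z)) + l1 * np.abs(w).sum() + 0.5 * l2 * (w @ w)
    )


def _smooth_grad(w: np.ndarray, X: np.ndarray, l2: float) -> np.ndarray:
    z = X.T @ w
    # d/dw of -(1/n) sum log sigma(z_i) is -(1/n) X sigma(-z)
    sig_neg = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    return -(X @ sig_neg) / X.shape[1] + l2 * w


def _subgradient_norm(w: np.ndarray, grad: np.ndarray, l1: float) -> float:
    """Inf-norm of the minimal-norm subgradient of the full objective."""
    g = np.where(
        w != 0,
        grad + l1 * np.sign(w),
        np.maximum(np.abs(grad) - l1, 0.0),
    )
    return float(np.max(np.abs(g))) if len(g) else 0.0


def train_oclr(
    X_centered: pd.DataFrame,
    l1: float = 0.0,
    l2: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10000,
    centering_means: pd.Series | None = None,
) -> StemnessModel:
    """Fit OCLR weights on centered stem-sample expression.

    Proximal gradient descent with a fixed step of 1/L, L the Lipschitz
    bound ``smax(X)^2/(4n) + l2``; the soft-threshold prox handles the
    L1 term.  The objective is monotonically non-increasing and the
    solution is certified by the inf-norm of the minimal subgradient.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    X = X_centered.to_numpy(dtype=float)
    p, n = X.shape
    if n < 1:
        raise ValueError("no training samples")
    smax = np.linalg.norm(X, 2) if min(p, n) > 0 else 0.0
    L = smax**2 / (4.0 * n) + l2
    step = 1.0 / L if L > 0 else 1.0

    w = np.zeros(p)
    obj = oclr_objective(w, X, l1, l2)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = _smooth_grad(w, X, l2)
        if _subgradient_norm(w, grad, l1) <= tol:
            n_iter -= 1
            break
        w_new = w - step * grad
        if l1 > 0:
            w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * l1, 0.0)
        obj_new = oclr_objective(w_new, X, l1, l2)
        w, obj = w_new, obj_new
    grad = _smooth_grad(w, X, l2)
    gnorm = _subgradient_norm(w, grad, l1)
    if gnorm > tol:
        raise ConvergenceError(
            f"OCLR did not converge in {max_iter} iterations: "
            f"objective={obj:.6g}, subgradient inf-norm={gnorm:.3g}"
        )
    if centering_means is None:
        centering_means = pd.Series(0.0, index=X_centered.index)
    return StemnessModel(
        gene_ids=list(X_centered.index),
        weights=w,
        l1=l1,
        l2=l2,
        n_train=n,
        centering_means=centering_means.reindex(X_centered.index).to_numpy(float),
        n_iter=n_iter,
        final_objective=obj,
        final_subgrad_norm=gnorm,
    )


def score_mrnasi(
    model: StemnessModel,
    X_cohort: pd.DataFrame,
    min_overlap_frac: float = 0.5,
    rescale_bounds: tuple[float, float] | None = None,
) -> StemnessScores:
    """Score a cohort: per-sample Spearman of weights vs expression.

    ``rho_i`` is Spearman's correlation (average ranks on ties) between
    the model weights and sample i's expression over the shared genes;
    mRNAsi min-max rescales rho to [0, 1] within the cohort.  Passing
    ``rescale_bounds`` anchors the rescaling to fixed (lo, hi) rho
    bounds instead, making scores comparable across cohorts.
    """
    w = model.weight_series()
    overlap = [g for g in model.gene_ids if g in X_cohort.index]
    if len(overlap) < min_overlap_frac * len(model.gene_ids):
        raise ValueError(
            f"gene overlap {len(overlap)}/{len(model.gene_ids)} below "
            f"{min_overlap_frac:.0%} of model genes"
        )
    wv = w.loc[overlap].to_numpy()
    wr = stats.rankdata(wv)
    E = X_cohort.loc[overlap].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, E)
    # Pearson on ranks == Spearman with average-rank ties
    wr_c = wr - wr.mean()
    rc = ranks - ranks.mean(axis=0)
    denom = np.sqrt((wr_c @ wr_c) * (rc * rc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc.T @ wr_c) / denom
    if rescale_bounds is not None:
        lo, hi = rescale_bounds
    else:
        lo, hi = float(np.min(rho)), float(np.max(rho))
    if hi - lo <= 0:
        raise ValueError("degenerate cohort: all Spearman correlations identical")
    mrnasi = (rho - lo) / (hi - lo)
    return StemnessScores(list(X_cohort.columns), rho, mrnasi)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for small n (< 10)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_genes_with_stemness(
    X: pd.DataFrame,
    scores: StemnessScores,
    genes: list[str],
    exact_below_n: int = 10,
) -> pd.DataFrame:
    """Spearman rho and p of each queried gene's expression vs mRNAsi.

    p-values use the t-approximation of Spearman's statistic, or exact
    permutation for cohorts smaller than ``exact_below_n``.  Constant
    genes get NaN with a warning.
    """
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")
    s = scores.mrnasi_series().reindex(X.columns).to_numpy()
    rows = []
    for g in genes:
        x = X.loc[g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(s) == 0:
            warnings.warn(f"gene {g}: constant values, correlation undefined")
            rows.append({"gene": g, "rho": np.nan, "p": np.nan})
            continue
        if len(x) < exact_below_n:
            rho = stats.spearmanr(x, s).statistic
            p = _spearman_exact_p(x, s, rho)
        else:
            res = stats.spearmanr(x, s)
            rho, p = res.statistic, res.pvalue
        rows.append({"gene": g, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("gene")
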