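"""Stemness subgroup discovery and drug-response association.

The cohort is first split at the median mRNAsi; differential expression
between the halves yields DEGs; resampling-based consensus clustering
(Monti-style) of DEG expression defines the final subgroups; and
chi-square tests relate subgroup membership to the drug-response label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "split_by_median",
    "differential_expression",
    "ConsensusResult",
    "consensus_cluster",
    "AssociationResult",
    "association_test",
    "compare_expression_wilcoxon",
]


def split_by_median(scores: pd.Series) -> pd.Series:
    """Label samples 'high' when strictly above the cohort median, else 'low'."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(scores.median())
    if scores.nunique() == 1:
        raise ValueError("all scores identical; median split is degenerate")
    return pd.Series(
        np.where(scores.to_numpy() > med, "high", "low"),
        index=scores.index,
        name="subgroup",
    )


def differential_expression(
    X: pd.DataFrame,
    labels: pd.Series,
    lfc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    group_a: str = "high",
    group_b: str = "low",
) -> pd.DataFrame:
    """Per-gene Welch t-test between two label groups on log2 expression.

    log2fc is mean(group_a) - mean(group_b); p-values are BH-adjusted
    across all genes; a gene is a DEG when |log2fc| > lfc_threshold and
    adj_p < p_threshold.
    """
    a_cols = labels.index[labels == group_a]
    b_cols = labels.index[labels == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples for Welch's t-test")
    A = X[a_cols].to_numpy(dtype=float)
    B = X[b_cols].to_numpy(dtype=float)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: p=1 when means agree, ~0 otherwise
    degenerate = np.isnan(p)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    adj_p = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "adj_p": adj_p}, index=X.index.copy()
    )
    out["is_deg"] = (np.abs(out["log2fc"]) > lfc_threshold) & (out["adj_p"] < p_threshold)
    return out


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    labels: pd.Series


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = np.sort(consensus[iu])
    if len(vals) == 0:
        return 0.0
    grid = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def consensus_cluster(
    X_degs: pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    reps: int = 1000,
    subsample: float = 0.8,
    rng_seed: int = 0,
    z_score: bool = True,
    delta_threshold: float = 0.1,
    linkage_method: str = "average",
) -> ConsensusResult:
    """Monti-style consensus clustering of samples on DEG expression.

    Each repetition subsamples ``ceil(subsample * n)`` samples, clusters
    them hierarchically (1 - Pearson correlation distance, average
    linkage) and cuts at each k; consensus(i, j) is the co-clustering
    count over the co-sampling count.  The cluster number is the
    smallest k whose next relative increase in consensus-CDF area falls
    below ``delta_threshold``; final labels come from hierarchical
    clustering of 1 - consensus at that k.
    """
    ks = sorted(k_range)
    n = X_degs.shape[1]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    E = X_degs.to_numpy(dtype=float)
    if z_score:
        sd = E.std(axis=1, ddof=0)
        keep = sd > 0
        E = (E[keep] - E[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # pairwise sample distance: 1 - Pearson r over genes (subsampling
    # samples only selects a submatrix, so compute once)
    D_full = 1.0 - np.corrcoef(E.T)
    np.fill_diagonal(D_full, 0.0)
    D_full = np.clip((D_full + D_full.T) / 2.0, 0.0, None)

    rng = np.random.default_rng(rng_seed)
    m = int(np.ceil(subsample * n))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1.0
        Z = linkage(squareform(D_full[np.ix_(idx, idx)], checks=False), method=linkage_method)
        for k in ks:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    consensus = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in ks:
            M = np.where(co_sampled > 0, co_cluster[k] / co_sampled, 0.0)
            np.fill_diagonal(M, 1.0)
            consensus[k] = (M + M.T) / 2.0

    areas = {k: _cdf_area(consensus[k]) for k in ks}
    deltas: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0

    chosen_k = ks[-1]
    for k in ks[:-1]:
        nxt = ks[ks.index(k) + 1]
        if deltas[nxt] < delta_threshold:
            chosen_k = k
            break

    Zc = linkage(
        squareform(np.clip(1.0 - consensus[chosen_k], 0.0, None), checks=False),
        method=linkage_method,
    )
    labels = pd.Series(
        fcluster(Zc, t=chosen_k, criterion="maxclust"),
        index=X_degs.columns,
        name="cluster",
    )
    return ConsensusResult(ks, consensus, areas, deltas, chosen_k, labels)


@dataclass
class AssociationResult:
    contingency: pd.DataFrame
    per_subgroup_p: pd.Series
    per_subgroup_chi2: pd.Series
    overall_p: float
    overall_chi2: float


def association_test(labels: pd.Series, response: pd.Series) -> AssociationResult:
    """Chi-square association of subgroup membership with drug response.

    Per subgroup: goodness-of-fit of (responders, non-responders)
    against equal proportions, df=1, no continuity correction.  Overall:
    Pearson chi-square on the full subgroup x response table.
    """
    response = response.reindex(labels.index)
    levels = sorted(response.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two response levels, got {levels}")
    table = pd.crosstab(labels, response)
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty subgroup in contingency table")
    chi2s, ps = {}, {}
    for grp, row in table.iterrows():
        a, b = float(row.iloc[0]), float(row.iloc[1])
        stat = (a - b) ** 2 / (a + b)
        chi2s[grp] = stat
        ps[grp] = float(stats.chi2.sf(stat, df=1))
    overall_chi2, overall_p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(
        contingency=table,
        per_subgroup_p=pd.Series(ps, name="p"),
        per_subgroup_chi2=pd.Series(chi2s, name="chi2"),
        overall_p=float(overall_p),
        overall_chi2=float(overall_chi2),
    )


def compare_expression_wilcoxon(
    X: pd.DataFrame, genes: list[str], response: pd.Series
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene between response groups,
    with Hommel adjustment across the queried genes."""
    response = response.reindex(X.columns)
    levels = sorted(response.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two response levels, got {levels}")
    a_cols = response.index[response == levels[0]]
    b_cols = response.index[response == levels[1]]
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError("both response groups must be non-empty")
    rows = []
    for g in genes:
        if g not in X.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
        a = X.loc[g, a_cols].to_numpy(float)
        b = X.loc[g, b_cols].to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"gene {g}: constant expression, p set to 1")
            rows.append({"gene": g, "statistic": np.nan, "p": 1.0})
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"gene": g, "statistic": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows).set_index("gene")
    out["adj_p"] = multipletests(out["p"].to_numpy(), method="hommel")[1]
    return out
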