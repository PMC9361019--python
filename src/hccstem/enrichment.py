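"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

ORA tests whether a selected gene list (e.g. DEGs between stemness
subgroups) overlaps a gene set more than expected under hypergeometric
sampling from the universe.  Preranked GSEA walks a log2-fold-change
ranking and scores each set by the extremum of a weighted running sum,
with significance from size-matched gene-set permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetDB", "ora_hypergeometric", "gsea_preranked", "gsea_collection"]


@dataclass
class GeneSetDB:
    """Ordered mapping of gene-set name -> unique member genes."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))  # dedupe, keep order
            if not uniq:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")


def ora_hypergeometric(
    selected: list[str], universe: list[str], db: GeneSetDB
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation test per gene set.

    For each set, p = P(X >= k) with X ~ Hypergeom(N, K, n) where N is
    the universe size, K the set size after intersecting with the
    universe, n the selected-list size and k the observed overlap.
    Benjamini-Hochberg adjustment across tested sets.
    """
    if len(selected) == 0:
        raise ValueError("selected gene list is empty")
    uni = set(universe)
    sel = set(selected)
    if not sel <= uni:
        missing = sorted(sel - uni)[:5]
        raise ValueError(f"selected genes not in universe, e.g. {missing}")
    N, n = len(uni), len(sel)

    rows = []
    for name, members in db.items():
        in_uni = [g for g in members if g in uni]
        K = len(in_uni)
        if K == 0:
            continue
        k = len(sel.intersection(in_uni))
        # upper tail including k itself: sf(k-1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    result = pd.DataFrame(rows).set_index("set")
    result["adj_p"] = multipletests(result["p"].to_numpy(), method="fdr_bh")[1]
    return result


def _es_walk(stats_sorted: np.ndarray, hit: np.ndarray, weight_exponent: float) -> tuple[float, np.ndarray]:
    """Running-sum enrichment score over a descending-sorted ranking."""
    n = len(stats_sorted)
    n_hit = int(hit.sum())
    n_miss = n - n_hit
    w = np.abs(stats_sorted) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit stats are zero: fall back to equal hit increments
        hit_w = hit.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit).astype(float) / n_miss
    walk = np.cumsum(steps)
    es = float(walk[np.argmax(np.abs(walk))])
    return es, walk


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    p_se: float
    leading_edge: list[str]
    n_overlap: int
    n_perm: int


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_set: list[str],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    rng_seed: int = 0,
    min_overlap: int = 3,
    max_overlap: int = 500,
) -> GSEAResult | None:
    """Preranked GSEA of one gene set against a gene -> statistic ranking.

    Genes are sorted by decreasing statistic; the running sum gains
    ``|stat|^exponent / sum(|stat|^exponent over hits)`` at set members
    and loses ``1/(N-K)`` elsewhere; ES is the extremum by absolute
    value.  The null is built from ``n_perm`` random size-matched gene
    sets; NES divides ES by the mean |null ES| of matching sign and the
    permutation p-value is the matching-sign exceedance fraction.

    Returns None (with a warning) when the overlap with the ranking is
    below ``min_overlap``.
    """
    ranked = ranked_stats.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    vals = ranked.to_numpy(dtype=float)
    members = set(gene_set)
    hit = np.isin(genes, list(members))
    k = int(hit.sum())
    if k < min_overlap:
        warnings.warn(f"gene set overlap {k} below minimum {min_overlap}; skipped")
        return None
    if k > max_overlap:
        warnings.warn(f"gene set overlap {k} above maximum {max_overlap}; skipped")
        return None
    if k == len(genes):
        raise ValueError("gene set equals the ranked universe; ES undefined")

    es, walk = _es_walk(vals, hit, weight_exponent)

    rng = np.random.default_rng(rng_seed)
    null_es = np.empty(n_perm)
    idx = np.arange(len(genes))
    for b in range(n_perm):
        perm_hit = np.zeros(len(genes), dtype=bool)
        perm_hit[rng.choice(idx, size=k, replace=False)] = True
        null_es[b], _ = _es_walk(vals, perm_hit, weight_exponent)

    same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
    if len(same_sign) == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same_sign))
        p = float(np.mean(np.abs(same_sign) >= abs(es)))
        p = max(p, 1.0 / (n_perm + 1))  # never report exactly zero
    p_se = float(np.sqrt(p * (1 - p) / n_perm))

    peak = int(np.argmax(np.abs(walk)))
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]

    return GSEAResult(
        set_name="",
        es=es,
        nes=float(nes),
        p=p,
        p_se=p_se,
        leading_edge=leading,
        n_overlap=k,
        n_perm=n_perm,
    )


def gsea_collection(
    ranked_stats: pd.Series,
    db: GeneSetDB,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    rng_seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run preranked GSEA over every set in a collection."""
    rows = []
    for i, (name, members) in enumerate(db.items()):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = gsea_preranked(
                ranked_stats,
                members,
                n_perm=n_perm,
                weight_exponent=weight_exponent,
                rng_seed=rng_seed + i,
                **kwargs,
            )
        if res is None:
            continue
        rows.append(
            {
                "set": name,
                "es": res.es,
                "nes": res.nes,
                "p": res.p,
                "p_se": res.p_se,
                "n_overlap": res.n_overlap,
                "leading_edge": ",".join(res.leading_edge),
            }
        )
    return pd.DataFrame(rows).set_index("set")
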