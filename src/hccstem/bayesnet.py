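"""Score-based Bayesian-network inference with bootstrap edge confidence.

Used on two levels, mirroring the pathway network and the
within-pathway gene network of the analysis: nodes are either pathway
activities (mean member-gene z-scores) or individual gene expression
values.  Structures are learned by greedy hill-climbing over
add/delete/reverse moves maximising the Gaussian (linear-regression)
BIC, with random restarts; edge confidence comes from relearning on
bootstrap resamples of the samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "BNConfig",
    "BNetwork",
    "pathway_activity",
    "bic_score",
    "learn_structure",
    "bootstrap_network",
    "exhaustive_search",
]


@dataclass
class BNConfig:
    """Bootstrap settings; the study-scale default for R is 10000, the
    desk-scale default 200."""

    n_bootstrap: int = 200
    strength_threshold: float = 0.5
    max_parents: int = 3
    restarts: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.strength_threshold <= 1:
            raise ValueError("strength_threshold must be in (0, 1]")


@dataclass
class BNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: from, to, strength, direction_confidence

    def consensus_edges(self, threshold: float = 0.5) -> pd.DataFrame:
        return self.edges[self.edges["strength"] >= threshold].reset_index(drop=True)

    def to_networkx(self, threshold: float = 0.5):
        """Consensus network as a networkx DiGraph with strength attributes."""
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for _, row in self.consensus_edges(threshold).iterrows():
            G.add_edge(
                row["from"],
                row["to"],
                strength=float(row["strength"]),
                direction_confidence=float(row["direction_confidence"]),
            )
        return G


def pathway_activity(
    X: pd.DataFrame, db, min_members: int = 3
) -> pd.DataFrame:
    """Pathway x sample activity: mean of member-gene z-scores.

    Pathways with fewer than ``min_members`` measured, non-constant
    members are skipped with a warning.
    """
    sd = X.std(axis=1, ddof=0)
    usable = X.index[sd > 0]
    if len(usable) == 0:
        raise ValueError("all genes constant; z-scores undefined")
    Z = X.loc[usable].sub(X.loc[usable].mean(axis=1), axis=0).div(sd[usable], axis=0)
    rows, names = [], []
    for name, members in db.items():
        present = [g for g in members if g in Z.index]
        if len(present) < min_members:
            warnings.warn(
                f"pathway {name}: only {len(present)} measured members (<{min_members}); skipped"
            )
            continue
        rows.append(Z.loc[present].mean(axis=0).to_numpy())
        names.append(name)
    return pd.DataFrame(rows, index=names, columns=X.columns)


def _node_bic(y: np.ndarray, P: np.ndarray | None, n: int) -> float:
    """BIC contribution of one node given its parent design matrix."""
    if P is None or P.shape[1] == 0:
        resid = y - y.mean()
        k = 2  # intercept + variance
    else:
        A = np.column_stack([np.ones(len(y)), P])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        k = P.shape[1] + 2
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return ll - 0.5 * k * np.log(n)


class _ScoreCache:
    def __init__(self, data: np.ndarray, cols: list[str]):
        self.data = data
        self.cols = cols
        self.n = data.shape[0]
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def node_score(self, node: int, parents: frozenset[int]) -> float:
        key = (node, parents)
        if key not in self._cache:
            y = self.data[:, node]
            P = self.data[:, sorted(parents)] if parents else None
            self._cache[key] = _node_bic(y, P, self.n)
        return self._cache[key]


def _has_path(adj: dict[int, set[int]], src: int, dst: int) -> bool:
    stack, seen = [src], set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(adj[u])
    return False


def bic_score(data: pd.DataFrame, edges: list[tuple[str, str]]) -> float:
    """Total Gaussian BIC of a DAG over samples x variables data."""
    cols = list(data.columns)
    idx = {c: i for i, c in enumerate(cols)}
    cache = _ScoreCache(data.to_numpy(dtype=float), cols)
    parents: dict[int, set[int]] = {i: set() for i in range(len(cols))}
    for u, v in edges:
        parents[idx[v]].add(idx[u])
    return sum(cache.node_score(i, frozenset(parents[i])) for i in range(len(cols)))


def _random_dag(
    p: int, rng: np.random.Generator, max_parents: int
) -> dict[int, set[int]]:
    order = rng.permutation(p)
    parents: dict[int, set[int]] = {i: set() for i in range(p)}
    for pos, v in enumerate(order):
        preceding = order[:pos]
        for u in preceding:
            if len(parents[v]) >= max_parents:
                break
            if rng.uniform() < 0.3:
                parents[int(v)].add(int(u))
    return parents


def _hill_climb_once(
    cache: _ScoreCache,
    parents: dict[int, set[int]],
    max_parents: int,
    eps: float = 1e-9,
) -> tuple[dict[int, set[int]], float]:
    p = len(cache.cols)
    node_scores = {i: cache.node_score(i, frozenset(parents[i])) for i in range(p)}
    while True:
        children = {i: {j for j in range(p) if i in parents[j]} for i in range(p)}
        best_delta, best_move = eps, None
        for u in range(p):
            for v in range(p):
                if u == v:
                    continue
                if u in parents[v]:
                    # delete u -> v
                    delta = cache.node_score(v, frozenset(parents[v] - {u})) - node_scores[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", u, v)
                    # reverse u -> v (becomes v -> u)
                    if len(parents[u]) < max_parents:
                        without = {j: parents[j] - ({u} if j == v else set()) for j in range(p)}
                        adj = {i: {j for j in range(p) if i in without[j]} for i in range(p)}
                        if not _has_path(adj, u, v):
                            delta = (
                                cache.node_score(v, frozenset(parents[v] - {u}))
                                - node_scores[v]
                                + cache.node_score(u, frozenset(parents[u] | {v}))
                                - node_scores[u]
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
                else:
                    # add u -> v
                    if len(parents[v]) >= max_parents:
                        continue
                    adj = {i: set(children[i]) for i in range(p)}
                    if _has_path(adj, v, u):
                        continue
                    delta = cache.node_score(v, frozenset(parents[v] | {u})) - node_scores[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            parents[v].add(u)
        elif kind == "del":
            parents[v].remove(u)
        else:
            parents[v].remove(u)
            parents[u].add(v)
        node_scores[u] = cache.node_score(u, frozenset(parents[u]))
        node_scores[v] = cache.node_score(v, frozenset(parents[v]))
    return parents, sum(node_scores.values())


def learn_structure(
    data: pd.DataFrame,
    max_parents: int = 3,
    restarts: int = 5,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Greedy hill-climbing DAG search maximising Gaussian BIC.

    ``data`` is samples x variables.  Restart 0 starts from the empty
    graph; further restarts start from random DAGs.  Returns the edge
    list of the best-scoring structure (deterministic given the seed).
    """
    cols = list(data.columns)
    arr = data.to_numpy(dtype=float)
    const = [c for c, s in zip(cols, arr.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant variable(s): {const}")
    cache = _ScoreCache(arr, cols)
    rng = np.random.default_rng(rng_seed)
    p = len(cols)
    best_parents, best_score = None, -np.inf
    for r in range(max(1, restarts)):
        start = {i: set() for i in range(p)} if r == 0 else _random_dag(p, rng, max_parents)
        parents, score = _hill_climb_once(cache, start, max_parents)
        if score > best_score + 1e-12:
            best_parents, best_score = parents, score
    return sorted(
        (cols[u], cols[v]) for v, us in best_parents.items() for u in us
    )


def exhaustive_search(
    data: pd.DataFrame, max_parents: int = 3
) -> tuple[list[tuple[str, str]], float]:
    """Exact best-BIC DAG by dynamic programming over variable orderings.

    Feasible for <= ~6 nodes; serves as the global-optimum oracle for
    the hill climber.
    """
    cols = list(data.columns)
    p = len(cols)
    if p > 6:
        raise ValueError("exhaustive search limited to 6 nodes")
    cache = _ScoreCache(data.to_numpy(dtype=float), cols)

    from itertools import combinations

    def best_parents_for(node: int, candidates: tuple[int, ...]) -> tuple[float, frozenset[int]]:
        best = (cache.node_score(node, frozenset()), frozenset())
        for size in range(1, min(max_parents, len(candidates)) + 1):
            for combo in combinations(candidates, size):
                s = cache.node_score(node, frozenset(combo))
                if s > best[0]:
                    best = (s, frozenset(combo))
        return best

    best_total, best_edges = -np.inf, []
    for order in permutations(range(p)):
        total, edges = 0.0, []
        for pos, node in enumerate(order):
            s, pa = best_parents_for(node, order[:pos])
            total += s
            edges.extend((cols[u], cols[node]) for u in pa)
        if total > best_total + 1e-12:
            best_total, best_edges = total, sorted(edges)
    return best_edges, best_total


def bootstrap_network(data: pd.DataFrame, config: BNConfig) -> BNetwork:
    """Bootstrap edge strengths: resample samples with replacement,
    relearn the structure, and summarise per edge.

    strength = fraction of bootstraps containing the edge in either
    direction; direction_confidence = fraction oriented from -> to among
    those.  Each (from, to) row is the majority orientation.
    """
    cols = list(data.columns)
    n = data.shape[0]
    rng = np.random.default_rng(config.rng_seed)
    pair_counts: dict[tuple[str, str], int] = {}
    dir_counts: dict[tuple[str, str], int] = {}
    R = config.n_bootstrap
    for b in range(R):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        if (sample.std(axis=0) == 0).any():  # pathological resample; redraw
            continue
        edges = learn_structure(
            sample,
            max_parents=config.max_parents,
            restarts=config.restarts,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for u, v in edges:
            key = (u, v) if u < v else (v, u)
            pair_counts[key] = pair_counts.get(key, 0) + 1
            dir_counts[(u, v)] = dir_counts.get((u, v), 0) + 1
    rows = []
    for (a, b), cnt in sorted(pair_counts.items()):
        fwd = dir_counts.get((a, b), 0)
        rev = dir_counts.get((b, a), 0)
        u, v = (a, b) if fwd >= rev else (b, a)
        rows.append(
            {
                "from": u,
                "to": v,
                "strength": cnt / R,
                "direction_confidence": max(fwd, rev) / cnt,
            }
        )
    edges = pd.DataFrame(rows, columns=["from", "to", "strength", "direction_confidence"])
    return BNetwork(nodes=cols, edges=edges)
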