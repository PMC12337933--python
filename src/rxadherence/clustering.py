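"""Risk-profile clustering: Gower distance, PAM, silhouette-based K selection.

All risk factors are unordered categoricals, so the Gower dissimilarity
reduces to the fraction of variables on which two patients differ (simple
matching distance); it is a metric in [0, 1].  Clustering is partition around
medoids (PAM): greedy BUILD initialization followed by SWAP steps, accepting
the single best cost-reducing medoid swap until none remains.  Ties are
broken by lowest row index throughout, so the algorithm is deterministic; the
seed only governs subsampling when the CLARA-style large-n strategy engages.
K is chosen by maximizing the average silhouette width over a candidate
range, with the s(i) = 0 convention for singleton clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CLARA_THRESHOLD = 10_000
CLARA_SAMPLE = 2_000
CLARA_DRAWS = 5
EXACT_SEARCH_LIMIT = 5_000  # max C(n, k) for exact medoid enumeration


def gower_matrix(features: pd.DataFrame) -> np.ndarray:
    """Pairwise categorical Gower distances (fraction of differing variables)."""
    if len(features) < 2:
        raise ValueError("need at least two rows")
    if features.isna().any().any():
        raise ValueError("feature table must have no missing values")
    codes = np.column_stack(
        [pd.factorize(features[c].to_numpy())[0] for c in features.columns]
    )
    n, p = codes.shape
    D = np.zeros((n, n))
    for j in range(p):
        col = codes[:, j]
        D += col[:, None] != col[None, :]
    D /= p
    if not D.any():
        warnings.warn("constant feature table: all Gower distances are zero")
    return D


@dataclass
class ClusterSolution:
    k: int
    medoid_ids: list[int]
    assignment: np.ndarray
    total_cost: float
    avg_silhouette: float | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.assignment


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]
    nearest = sub.argmin(axis=1)
    return nearest, float(sub.min(axis=1).sum())


def _pam_exact(D: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact medoid search by enumeration (small C(n, k) only).

    BUILD+SWAP is a heuristic and can stall in a swap-optimal but globally
    suboptimal medoid set even at n <= 10; for tiny search spaces the exact
    minimum is affordable and is what the small-n contract of this module
    promises."""
    from itertools import combinations

    best_cost, best = np.inf, None
    for pair in combinations(range(D.shape[0]), k):
        cost = D[:, pair].min(axis=1).sum()
        if cost < best_cost - 1e-15:
            best_cost, best = cost, list(pair)
    return best, float(best_cost)


def _pam_core(D: np.ndarray, k: int) -> tuple[list[int], float]:
    n = D.shape[0]
    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # with the largest total-distance reduction (ties -> lowest index).
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.clip(dmin[:, None] - D, 0.0, None).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids = sorted(medoids)
    _, cost = _assign(D, medoids)

    # SWAP: best-improvement steps until no swap lowers the cost.
    while True:
        best = None
        in_set = np.zeros(n, dtype=bool)
        in_set[medoids] = True
        candidates = np.flatnonzero(~in_set)
        for mi, m in enumerate(medoids):
            rest = medoids[:mi] + medoids[mi + 1:]
            dmin_rest = D[:, rest].min(axis=1) if rest else np.full(n, np.inf)
            costs = np.minimum(dmin_rest[:, None], D[:, candidates]).sum(axis=0)
            j = int(costs.argmin())
            if costs[j] < cost - 1e-12 and (best is None or costs[j] < best[0] - 1e-12):
                best = (float(costs[j]), mi, int(candidates[j]))
        if best is None:
            break
        cost, mi, h = best
        medoids = sorted(medoids[:mi] + medoids[mi + 1:] + [h])
        _, cost = _assign(D, medoids)
    return medoids, cost


def pam(
    D: np.ndarray,
    k: int,
    seed: int | None = None,
    clara_threshold: int = CLARA_THRESHOLD,
) -> ClusterSolution:
    """Partition around medoids on a precomputed distance matrix.

    For n above ``clara_threshold`` a CLARA-style strategy is used: PAM on
    several random subsamples, keeping the medoid set with the lowest
    full-data cost (the seed governs the subsampling only).
    """
    n = D.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if k == n:
        medoids = list(range(n))
    elif n <= clara_threshold:
        from math import comb

        if comb(n, k) <= EXACT_SEARCH_LIMIT:
            medoids, _ = _pam_exact(D, k)
        else:
            medoids, _ = _pam_core(D, k)
    else:
        rng = np.random.default_rng(seed)
        best_cost, medoids = np.inf, None
        for _ in range(CLARA_DRAWS):
            sample = np.sort(rng.choice(n, size=min(CLARA_SAMPLE, n), replace=False))
            sub_medoids, _ = _pam_core(D[np.ix_(sample, sample)], k)
            cand = [int(sample[m]) for m in sub_medoids]
            _, cost = _assign(D, cand)
            if cost < best_cost - 1e-12:
                best_cost, medoids = cost, cand
    assignment, cost = _assign(D, medoids)
    return ClusterSolution(k=k, medoid_ids=list(medoids), assignment=assignment, total_cost=cost)


def silhouette_samples(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths s(i) = (b-a)/max(a,b) from a precomputed matrix.

    Points in singleton clusters get s(i) = 0 by convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    n = D.shape[0]
    s = np.zeros(n)
    sizes = {c: int((labels == c).sum()) for c in uniq}
    mean_to = np.column_stack([D[:, labels == c].mean(axis=1) for c in uniq])
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        if sizes[labels[i]] == 1:
            continue  # singleton convention: s = 0
        a = mean_to[i, ci] * sizes[labels[i]] / (sizes[labels[i]] - 1)
        b = np.min(np.delete(mean_to[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def avg_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    return float(silhouette_samples(D, labels).mean())


def select_k(
    D: np.ndarray,
    k_range: range = range(2, 11),
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick K maximizing the average silhouette width (ties -> smaller K).

    Returns the chosen K and the full silhouette-by-K profile.
    """
    n = D.shape[0]
    rows = []
    solutions: dict[int, ClusterSolution] = {}
    for k in k_range:
        if k >= n:
            continue
        sol = pam(D, k, seed=seed)
        sil = avg_silhouette(D, sol.assignment)
        sol.avg_silhouette = sil
        solutions[k] = sol
        rows.append({"k": k, "avg_silhouette": sil, "total_cost": sol.total_cost})
    if not rows:
        raise ValueError("k_range produced no feasible k")
    profile = pd.DataFrame(rows)
    best_k = int(profile.loc[profile["avg_silhouette"].idxmax(), "k"])
    return best_k, profile
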