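"""Phenotype clustering and multivariate concordance.

Projected trait values are z-scored, accessions carrying any trait more
than ``sd_limit`` standard deviations from the mean are removed, and the
remainder is partitioned around medoids (PAM, BUILD + SWAP) on Euclidean
distances.  Enrichment of variety labels within clusters uses two-sided
Fisher exact tests with a Holm familywise adjustment, and concordance
between predicted and observed trait matrices uses Procrustes
superimposition with an optional permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .errors import ConfigError, DataError, SchemaError
from .quantgen import holm_adjust


# ---------------------------------------------------------------------------
# Standardization and outlier removal
# ---------------------------------------------------------------------------

def standardize_and_filter(traits: pd.DataFrame, sd_limit: float = 3.0,
                           id_column: str = "accession"
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Per-trait z-scores; remove accessions with any |z| > ``sd_limit``.

    The z-scores are computed once on the full (pre-removal) distribution;
    removal is a single pass.  Returns the filtered z-table (accession
    index) and the removed ids.
    """
    if id_column in traits.columns:
        df = traits.set_index(traits[id_column].astype(str)).drop(columns=[id_column])
    else:
        df = traits.copy()
        df.index = df.index.astype(str)
    df = df.select_dtypes(include=[np.number])
    if len(df) < 2:
        raise DataError("need at least 2 accessions")
    sd = df.std(ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise DataError(f"zero-variance trait: {zero[0]!r}")
    z = (df - df.mean()) / sd
    bad = z.abs().gt(sd_limit).any(axis=1)
    removed = sorted(z.index[bad])
    return z.loc[~bad], removed


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    k: int
    medoids: list[str]
    labels: pd.Series             # accession -> 1..k (renumbered by size)
    silhouette: float
    total_cost: float             # sum of distances to assigned medoids
    wss: float                    # sum of squared distances to cluster means
    removed_outliers: list[str] = field(default_factory=list)


def _pam_build_swap(D: np.ndarray, k: int) -> tuple[list[int], float]:
    """PAM on a distance matrix; deterministic, lowest-index ties.

    Tiny instances are solved exactly by enumerating medoid sets (SWAP can
    stall in a local optimum there); larger ones use BUILD + SWAP."""
    n = D.shape[0]
    from math import comb
    if comb(n, k) <= 20000:
        from itertools import combinations
        best_cost, best_set = np.inf, None
        for med in combinations(range(n), k):
            cost = D[:, med].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_set = cost, med
        return sorted(best_set), float(best_cost)
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        gains = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP: accept the best strictly improving swap until none remains
    while True:
        med = np.array(medoids)
        dist_to_med = D[:, med]
        order = np.argsort(dist_to_med, axis=1)
        nearest = dist_to_med[np.arange(n), order[:, 0]]
        second = dist_to_med[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        nearest_idx = order[:, 0]
        cost = nearest.sum()
        best = (0.0, None, None)
        non_med = [h for h in range(n) if h not in medoids]
        for i_pos in range(k):
            base = np.where(nearest_idx == i_pos, second, nearest)
            cand = np.minimum(base[None, :], D[non_med, :])
            new_costs = cand.sum(axis=1)
            j = int(np.argmin(new_costs))
            delta = new_costs[j] - cost
            if delta < best[0] - 1e-12:
                best = (delta, i_pos, non_med[j])
        if best[1] is None:
            return medoids, float(cost)
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)


def pam_cluster(z_table: pd.DataFrame, k: int, seed: int = 0,
                removed_outliers: list[str] | None = None) -> ClusterModel:
    """Partition accessions around ``k`` medoids on Euclidean distances.

    Deterministic: BUILD is greedy, SWAP accepts the best strictly
    improving exchange, and ties resolve to the lowest accession id via
    the sorted row order.  Cluster labels are renumbered by descending
    cluster size for report stability.
    """
    n = len(z_table)
    if not (1 < k < n):
        raise ConfigError(f"k must satisfy 1 < k < n (k={k}, n={n})")
    z_table = z_table.sort_index()
    X = z_table.to_numpy(float)
    D = cdist(X, X)
    med_idx, cost = _pam_build_swap(D, k)
    assign = np.argmin(D[:, med_idx], axis=1)
    # renumber by descending size (ties: lower medoid id first)
    sizes = [( -np.sum(assign == i), z_table.index[med_idx[i]]) for i in range(k)]
    order = sorted(range(k), key=lambda i: sizes[i])
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[a] for a in assign], index=z_table.index, name="cluster")
    medoids = [str(z_table.index[med_idx[i]]) for i in order]
    sil = float(silhouette_score(X, labels.to_numpy())) if k >= 2 else 0.0
    wss = _wss(X, assign)
    return ClusterModel(k=k, medoids=medoids, labels=labels, silhouette=sil,
                        total_cost=cost, wss=wss,
                        removed_outliers=removed_outliers or [])


def _wss(X: np.ndarray, assign: np.ndarray) -> float:
    wss = 0.0
    for c in np.unique(assign):
        sub = X[assign == c]
        wss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return wss


def wss_curve(z_table: pd.DataFrame, k_range=range(1, 11)) -> pd.Series:
    """Within-cluster sum of squares (to cluster means) as a function of k."""
    z_table = z_table.sort_index()
    X = z_table.to_numpy(float)
    n = len(X)
    out = {}
    for k in k_range:
        if k <= 0 or k > n:
            continue
        if k == 1:
            out[k] = float(((X - X.mean(axis=0)) ** 2).sum())
        elif k == n:
            out[k] = 0.0
        else:
            D = cdist(X, X)
            med_idx, _ = _pam_build_swap(D, k)
            assign = np.argmin(D[:, med_idx], axis=1)
            out[k] = _wss(X, assign)
    return pd.Series(out, name="wss")


# ---------------------------------------------------------------------------
# Variety enrichment
# ---------------------------------------------------------------------------

def variety_enrichment(labels: pd.Series, variety: pd.Series) -> pd.DataFrame:
    """Two-sided Fisher exact test per (cluster, variety) pair.

    The 2x2 table partitions the variety-assigned accessions by membership
    of the cluster and assignment to the variety; Holm adjusts over the
    whole family.
    """
    variety = variety.dropna()
    shared = labels.index.intersection(variety.index)
    if len(shared) == 0:
        raise DataError("no accessions with variety assignments")
    lab = labels.loc[shared]
    var = variety.loc[shared].astype(str)
    rows = []
    for cl in sorted(lab.unique()):
        in_cl = lab == cl
        for v in sorted(var.unique()):
            is_v = var == v
            a = int((in_cl & is_v).sum())
            b = int((in_cl & ~is_v).sum())
            c = int((~in_cl & is_v).sum())
            d = int((~in_cl & ~is_v).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"cluster": cl, "variety": v,
                         "in_cluster_variety": a, "in_cluster_other": b,
                         "out_cluster_variety": c, "out_cluster_other": d,
                         "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Procrustes concordance
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    rotation: np.ndarray
    scale: float
    translation_observed: np.ndarray
    translation_predicted: np.ndarray
    m2: float
    residuals: pd.Series
    p_perm: float | None = None
    n_perm: int | None = None


def procrustes(observed: pd.DataFrame, predicted: pd.DataFrame,
               permutation_test: bool = False, n_perm: int = 999,
               seed: int = 0) -> ProcrustesResult:
    """Symmetric Procrustes superimposition of predicted onto observed.

    Both matrices are column-centered and scaled to unit total sum of
    squares; the optimal rotation comes from the SVD of the cross-product.
    ``m2`` is the residual sum of squares after superimposition.  The
    optional permutation test permutes rows of the predicted matrix.
    """
    if list(observed.columns) != list(predicted.columns):
        raise SchemaError("observed and predicted must share trait columns")
    shared = observed.index.intersection(predicted.index)
    if len(shared) < 3:
        raise SchemaError("need at least 3 shared accessions")
    X = observed.loc[shared].to_numpy(float)
    Y = predicted.loc[shared].to_numpy(float)
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    nx = np.linalg.norm(Xc)
    ny = np.linalg.norm(Yc)
    if nx == 0 or ny == 0:
        raise DataError("a matrix is constant; Procrustes undefined")
    Xc, Yc = Xc / nx, Yc / ny

    def _m2(A, B):
        U, s, Vt = np.linalg.svd(B.T @ A)
        R = U @ Vt
        c = s.sum()
        resid = A - c * (B @ R)
        return float((resid ** 2).sum()), R, c, resid

    m2, R, c, resid = _m2(Xc, Yc)
    res_rows = pd.Series(np.sqrt((resid ** 2).sum(axis=1)), index=shared)
    p_perm = None
    if permutation_test:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(Yc))
            m2p, *_ = _m2(Xc, Yc[perm])
            if m2p <= m2:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return ProcrustesResult(rotation=R, scale=c, translation_observed=mx,
                            translation_predicted=my, m2=m2,
                            residuals=res_rows, p_perm=p_perm,
                            n_perm=n_perm if permutation_test else None)
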