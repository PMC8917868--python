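"""Lattice-contiguous metaclustering of SOM units with AIC/BIC selection.

SOM units are grouped by a constrained k-means variant in which every
cluster must stay connected on the hexagonal lattice: clusters grow
greedily from k seed units by repeatedly attaching the cheapest adjacent
unassigned unit, then boundary units are reassigned between adjacent
clusters while preserving contiguity until the residual sum of squares
stops improving.  The number of metaclusters is selected by AIC (default)
or BIC under a spherical-Gaussian likelihood over unit weights.

Downstream utilities compute metacluster eigen-profiles (mean member-unit
weights), condition-wise Wilcoxon hypothesis tests with BH correction,
mean log2 fold changes, and experiment hierarchies over profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from somgrn.som import AssignmentMap, SOMModel

logger = logging.getLogger(__name__)


@dataclass
class Metaclustering:
    """unit -> metacluster label (1..k), with model-selection bookkeeping."""

    labels: np.ndarray  # (n_units,), values in 1..k
    k: int
    rss: float
    aic: float
    bic: float
    criterion: str = "AIC"
    trial_rss: list[float] = field(default_factory=list)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _is_connected(units: np.ndarray, adjacency: dict[int, set[int]]) -> bool:
    if len(units) == 0:
        return False
    uset = set(units.tolist())
    stack = [next(iter(uset))]
    seen = {stack[0]}
    while stack:
        u = stack.pop()
        for v in adjacency[u] & uset:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(uset)


def check_contiguity(mc: Metaclustering, adjacency: dict[int, set[int]]) -> bool:
    """True iff every metacluster's unit set is lattice-connected."""
    return all(_is_connected(mc.members(lab), adjacency) for lab in range(1, mc.k + 1))


def _rss(weights: np.ndarray, labels: np.ndarray, k: int) -> float:
    rss = 0.0
    for lab in range(1, k + 1):
        m = labels == lab
        if m.any():
            cent = weights[m].mean(axis=0)
            rss += float(((weights[m] - cent) ** 2).sum())
    return rss


def _grow_regions(
    weights: np.ndarray,
    adjacency: dict[int, set[int]],
    seeds: np.ndarray,
) -> np.ndarray:
    """Greedy region growing from k seed units; returns labels in 1..k."""
    n = len(weights)
    k = len(seeds)
    labels = np.zeros(n, dtype=int)
    sums = np.zeros((k, weights.shape[1]))
    counts = np.zeros(k, dtype=int)
    for i, s in enumerate(seeds):
        labels[s] = i + 1
        sums[i] = weights[s]
        counts[i] = 1
    frontier: set[int] = set()
    for s in seeds:
        frontier |= {v for v in adjacency[s] if labels[v] == 0}
    while True:
        unassigned_adjacent = [u for u in frontier if labels[u] == 0]
        if not unassigned_adjacent:
            remaining = np.flatnonzero(labels == 0)
            if len(remaining) == 0:
                break
            # lattice is connected, so some unassigned unit borders a cluster
            unassigned_adjacent = [
                u for u in remaining if any(labels[v] > 0 for v in adjacency[u])
            ]
        best_u, best_lab, best_d = -1, -1, np.inf
        for u in unassigned_adjacent:
            neigh_labels = {labels[v] for v in adjacency[u]} - {0}
            for lab in neigh_labels:
                cent = sums[lab - 1] / counts[lab - 1]
                d = float(((weights[u] - cent) ** 2).sum())
                if d < best_d or (d == best_d and (u, lab) < (best_u, best_lab)):
                    best_u, best_lab, best_d = u, lab, d
        labels[best_u] = best_lab
        sums[best_lab - 1] += weights[best_u]
        counts[best_lab - 1] += 1
        frontier.discard(best_u)
        frontier |= {v for v in adjacency[best_u] if labels[v] == 0}
    return labels


def _refine_boundaries(
    weights: np.ndarray,
    labels: np.ndarray,
    adjacency: dict[int, set[int]],
    k: int,
    max_iter: int = 100,
) -> np.ndarray:
    """Contiguity-preserving reassignment of boundary units until RSS stalls."""
    labels = labels.copy()
    for _ in range(max_iter):
        moved = False
        cents = np.zeros((k, weights.shape[1]))
        counts = np.zeros(k, dtype=int)
        for lab in range(1, k + 1):
            m = labels == lab
            counts[lab - 1] = m.sum()
            if m.any():
                cents[lab - 1] = weights[m].mean(axis=0)
        for u in range(len(weights)):
            cur = labels[u]
            if counts[cur - 1] <= 1:
                continue  # never empty a cluster
            neigh = {labels[v] for v in adjacency[u]} - {cur}
            if not neigh:
                continue
            d_cur = float(((weights[u] - cents[cur - 1]) ** 2).sum())
            best_lab, best_gain = cur, 0.0
            for lab in sorted(neigh):
                d_new = float(((weights[u] - cents[lab - 1]) ** 2).sum())
                gain = d_cur - d_new
                if gain > best_gain:
                    best_lab, best_gain = lab, gain
            if best_lab == cur:
                continue
            # donor must stay connected without u
            donor = np.flatnonzero(labels == cur)
            if not _is_connected(donor[donor != u], adjacency):
                continue
            labels[u] = best_lab
            counts[cur - 1] -= 1
            counts[best_lab - 1] += 1
            moved = True
        if not moved:
            break
    return labels


def _information_criteria(
    weights: np.ndarray, labels: np.ndarray, rss: float, k: int
) -> tuple[float, float]:
    """AIC/BIC under the spherical-Gaussian mixture likelihood.

    The x-means construction: pooled ML variance sigma^2 = RSS / (d (n - k)),
    log-likelihood including the mixture-weight (cluster size) term, and
    parameter count p = k (d + 1) (k centroids of dimension d plus mixture
    weights/variance bookkeeping per cluster).
    """
    n, d = weights.shape
    sizes = np.array([(labels == lab).sum() for lab in range(1, k + 1)], dtype=float)
    var = max(rss / (d * max(n - k, 1)), 1e-12)
    ll = (
        float(np.sum(sizes * np.log(np.maximum(sizes, 1))))
        - n * np.log(n)
        - 0.5 * n * d * np.log(2 * np.pi * var)
        - 0.5 * d * (n - k)
    )
    p = k * (d + 1)
    aic = -2.0 * ll + 2.0 * p
    bic = -2.0 * ll + p * np.log(n)
    return aic, bic


def constrained_kmeans(
    model: SOMModel,
    k: int,
    trials: int = 10,
    seed: int = 0,
) -> Metaclustering:
    """Best-of-restarts lattice-contiguous k-means over SOM unit weights."""
    weights = model.weights
    n = len(weights)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    adjacency = model.lattice.adjacency()
    rng = np.random.default_rng(seed)
    best_labels, best_rss = None, np.inf
    trial_rss: list[float] = []
    for _ in range(trials):
        seeds = rng.choice(n, size=k, replace=False)
        labels = _grow_regions(weights, adjacency, seeds)
        labels = _refine_boundaries(weights, labels, adjacency, k)
        rss = _rss(weights, labels, k)
        trial_rss.append(rss)
        if rss < best_rss:
            best_labels, best_rss = labels, rss
    aic, bic = _information_criteria(weights, best_labels, best_rss, k)
    return Metaclustering(
        labels=best_labels, k=k, rss=best_rss, aic=aic, bic=bic, trial_rss=trial_rss
    )


def select_k(
    model: SOMModel,
    k_range,
    criterion: str = "AIC",
    trials: int = 10,
    seed: int = 0,
) -> Metaclustering:
    """Run constrained k-means over ``k_range``; return the clustering with
    the best (lowest) AIC or BIC."""
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError(f"unknown criterion {criterion!r} (use 'AIC' or 'BIC')")
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    best = None
    for i, k in enumerate(ks):
        mc = constrained_kmeans(model, k, trials=trials, seed=seed + 7919 * i)
        mc.criterion = crit
        score = mc.aic if crit == "AIC" else mc.bic
        if best is None or score < (best.aic if crit == "AIC" else best.bic):
            best = mc
    return best


def metacluster_profiles(
    model: SOMModel,
    mc: Metaclustering,
    normalize: bool = False,
) -> pd.DataFrame:
    """Eigen-profiles: per metacluster, the mean of member-unit weight vectors.

    With ``normalize`` each profile is divided by its maximum (nonzero
    profiles get max exactly 1).
    """
    cols = model.columns or list(range(model.weights.shape[1]))
    rows = []
    for lab in range(1, mc.k + 1):
        prof = model.weights[mc.members(lab)].mean(axis=0)
        rows.append(prof)
    out = pd.DataFrame(rows, index=range(1, mc.k + 1), columns=cols)
    if normalize:
        mx = out.to_numpy().max(axis=1, keepdims=True)
        mx = np.where(mx == 0, 1.0, mx)
        out = pd.DataFrame(out.to_numpy() / mx, index=out.index, columns=out.columns)
    return out


def member_profiles(matrix: pd.DataFrame, item_metaclusters: pd.Series) -> pd.DataFrame:
    """Mean raw (e.g. TPM) profile over member items per metacluster.

    Unlike :func:`metacluster_profiles`, which averages SOM unit weights in
    the (possibly transformed) training space, this averages the original
    matrix rows of the member items — the form the expression filter uses.
    """
    rows = {}
    for lab in sorted(item_metaclusters.unique()):
        items = item_metaclusters.index[item_metaclusters == lab].intersection(matrix.index)
        if len(items):
            rows[int(lab)] = matrix.loc[items].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def assign_items_to_metaclusters(assignment: AssignmentMap, mc: Metaclustering) -> pd.Series:
    """Compose item->unit with unit->metacluster, giving item -> metacluster."""
    units = assignment.unit.to_numpy()
    if units.max(initial=-1) >= len(mc.labels):
        raise KeyError("assignment refers to a unit missing from the metaclustering")
    return pd.Series(mc.labels[units], index=assignment.unit.index)


def hypothesis_test(
    item_metaclusters: pd.Series,
    matrix: pd.DataFrame,
    contrast: tuple[str, str],
    min_members: int = 5,
) -> pd.DataFrame:
    """Per-metacluster paired two-sided Wilcoxon signed-rank between two columns.

    Member genes' values in experiment A are paired against experiment B;
    zero differences are dropped (Wilcoxon convention); BH correction is
    applied across metaclusters within the contrast.  Exact null for n <= 25,
    normal approximation with continuity correction above.
    """
    col_a, col_b = contrast
    for c in (col_a, col_b):
        if c not in matrix.columns:
            raise KeyError(f"contrast column {c!r} not in matrix")
    rows = []
    for lab in sorted(item_metaclusters.unique()):
        items = item_metaclusters.index[item_metaclusters == lab]
        items = items.intersection(matrix.index)
        if len(items) < min_members:
            continue
        a = matrix.loc[items, col_a].to_numpy(dtype=float)
        b = matrix.loc[items, col_b].to_numpy(dtype=float)
        diff = a - b
        nz = diff[diff != 0]
        if len(nz) == 0:
            rows.append((lab, len(items), np.nan, 1.0, 0.0, True))
            continue
        method = "exact" if len(nz) <= 25 else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
        rows.append((lab, len(items), float(res.statistic), float(res.pvalue),
                     float(np.median(diff)), False))
    out = pd.DataFrame(
        rows, columns=["metacluster", "n", "statistic", "p", "median_diff", "degenerate"]
    ).set_index("metacluster")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["direction"] = np.sign(out["median_diff"]).astype(int)
    return out


def metacluster_foldchange(
    item_metaclusters: pd.Series,
    matrix: pd.DataFrame,
    tissue_column: str,
    reference_column: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Mean over member genes of log2((tissue + c) / (reference + c))."""
    out = {}
    for lab in sorted(item_metaclusters.unique()):
        items = item_metaclusters.index[item_metaclusters == lab].intersection(matrix.index)
        if len(items) == 0:
            logger.warning("metacluster %s has no members in matrix", lab)
            out[lab] = np.nan
            continue
        t = matrix.loc[items, tissue_column].to_numpy(dtype=float)
        r = matrix.loc[items, reference_column].to_numpy(dtype=float)
        out[lab] = float(np.mean(np.log2((t + pseudocount) / (r + pseudocount))))
    return pd.Series(out, name="log2fc")


def experiment_hierarchy(profiles: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage hierarchy over experiments with distance 1 - Pearson r.

    Returns the scipy linkage matrix and the leaf order (column labels).
    Zero-variance experiments get distance 1 to everything, with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >=2 experiments")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    bad = sd == 0
    if bad.any():
        logger.warning("zero-variance experiments: %s", list(profiles.columns[bad]))
        dist[bad, :] = 1.0
        dist[:, bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = average(squareform(dist, checks=False))
    order = [profiles.columns[i] for i in leaves_list(Z)]
    return Z, order
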