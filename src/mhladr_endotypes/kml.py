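"""Longitudinal k-means (KmL-style) for sparse three-point trajectories.

Trajectories live on a common three-column grid (sampling-window midpoints,
days 1.5 / 3.5 / 6.0). Missing entries are handled by a Gower-adjusted
Euclidean distance during clustering and copy-mean imputation afterwards;
partition quality is the Calinski-Harabasz criterion, and the best of many
random restarts is kept. A deterministic rule names the four clusters after
the published endotypes from their day-1 and day-6 center levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "DEFAULT_WINDOWS",
    "IncomparableTrajectoriesError",
    "TrajectoryCohort",
    "Partition",
    "gower_distance",
    "kmeans_longitudinal",
    "calinski_harabasz",
    "impute_copy_mean",
    "posterior_probabilities",
    "name_endotypes",
    "mean_assignment_probability",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = ((1, 2), (3, 4), (5, 7))
DEFAULT_GRID = (1.5, 3.5, 6.0)


class IncomparableTrajectoriesError(ValueError):
    """Two trajectories share no observed time point."""


@dataclass
class TrajectoryCohort:
    """Sparse per-patient trajectories on the three-window grid.

    matrix holds marker values (transformed scale) with NaN for missing
    windows; days holds the actual sampling day of each retained window.
    """

    patients: np.ndarray
    grid: np.ndarray
    matrix: np.ndarray
    days: np.ndarray
    cohort: np.ndarray

    def __post_init__(self) -> None:
        n, t = self.matrix.shape
        if t != len(self.grid):
            raise ValueError("matrix width does not match grid length")
        if n != len(self.patients):
            raise ValueError("matrix height does not match patient count")
        obs = ~np.isnan(self.matrix)
        if not obs.any(axis=1).all():
            empty = self.patients[~obs.any(axis=1)]
            raise ValueError(f"patients with zero observed windows: {list(empty[:5])}")

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_long(
        cls,
        data: pd.DataFrame,
        value_col: str = "mhla_dr_t",
        windows=DEFAULT_WINDOWS,
        grid=DEFAULT_GRID,
    ) -> "TrajectoryCohort":
        """Pivot a long table (patient_id, day, value[, cohort]) onto the grid.

        Each observation is assigned to the window containing its day;
        multiple observations in one window are averaged (days too). Days
        outside every window are rejected.
        """
        pids = pd.unique(data["patient_id"])
        idx = {p: i for i, p in enumerate(pids)}
        n, t = len(pids), len(windows)
        matrix = np.full((n, t), np.nan)
        days = np.full((n, t), np.nan)
        counts = np.zeros((n, t))
        for pid, day, val in zip(data["patient_id"], data["day"], data[value_col]):
            w = next((j for j, (lo, hi) in enumerate(windows) if lo <= day <= hi), None)
            if w is None:
                raise ValueError(f"day {day} (patient {pid!r}) falls outside every sampling window")
            i = idx[pid]
            if counts[i, w] == 0:
                matrix[i, w] = val
                days[i, w] = day
            else:  # average duplicates within a window
                matrix[i, w] = (matrix[i, w] * counts[i, w] + val) / (counts[i, w] + 1)
                days[i, w] = (days[i, w] * counts[i, w] + day) / (counts[i, w] + 1)
            counts[i, w] += 1
        if "cohort" in data.columns:
            cohort = data.groupby("patient_id", sort=False)["cohort"].first().reindex(pids).to_numpy()
        else:
            cohort = np.array(["all"] * n, dtype=object)
        return cls(
            patients=np.asarray(pids),
            grid=np.asarray(grid, dtype=float),
            matrix=matrix,
            days=days,
            cohort=cohort,
        )


@dataclass
class Partition:
    """Result of one best-of-restarts longitudinal k-means run."""

    k: int
    assignment: np.ndarray
    centers: np.ndarray
    imputed: np.ndarray
    ch: float
    posterior: np.ndarray
    names: dict | None = None
    n_restarts: int = 0
    best_restart_seed: int = 0
    n_redrawn_restarts: int = 0

    def cluster_of(self, label: str) -> int:
        """Cluster index carrying an endotype name."""
        if not self.names:
            raise ValueError("partition has no endotype names attached")
        for idx, name in self.names.items():
            if name == label:
                return idx
        raise KeyError(label)


def gower_distance(x, y, n_times: int | None = None) -> float:
    """Missing-data-adjusted Euclidean distance between two trajectories.

    d = sqrt((T / |O|) * sum_{t in O} (x_t - y_t)^2) where O is the set of
    time indices observed in both trajectories and T the grid length; the
    rescaling makes distances over different missingness patterns comparable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = n_times if n_times is not None else x.size
    both = ~np.isnan(x) & ~np.isnan(y)
    m = int(both.sum())
    if m == 0:
        raise IncomparableTrajectoriesError("trajectories share no observed time point")
    return float(np.sqrt(t / m * np.sum((x[both] - y[both]) ** 2)))


def _sq_distances_to_centers(matrix: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Gower distance of every patient (rows, may have NaN) to every
    complete center. Returns an (n, k) array."""
    obs = ~np.isnan(matrix)
    t = matrix.shape[1]
    n_obs = obs.sum(axis=1)
    diff = np.where(obs[:, None, :], matrix[:, None, :] - centers[None, :, :], 0.0)
    ss = np.einsum("nkt,nkt->nk", diff, diff)
    return ss * (t / n_obs)[:, None]


def _gower_objective(matrix: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> float:
    d2 = _sq_distances_to_centers(matrix, centers)
    return float(d2[np.arange(len(assignment)), assignment].sum())


def _update_centers(matrix: np.ndarray, assignment: np.ndarray, centers: np.ndarray, k: int) -> np.ndarray:
    """Per-cluster, per-time mean of observed values, weighted by each
    patient's Gower factor T/|O_i| so the update exactly minimizes the
    clustering objective; an all-missing cell retains the previous value."""
    new = centers.copy()
    t = matrix.shape[1]
    obs = ~np.isnan(matrix)
    w = t / obs.sum(axis=1)
    for c in range(k):
        sel = assignment == c
        if not sel.any():
            continue
        rows = matrix[sel]
        rw = (w[sel][:, None] * obs[sel]).astype(float)
        num = np.nansum(rows * w[sel][:, None], axis=0)
        den = rw.sum(axis=0)
        has = den > 0
        new[c, has] = num[has] / den[has]
    return new


def _single_restart(matrix, grand_mean, rng, k, max_iter=100):
    """One k-means restart. Returns (assignment, centers, objective_trace) or
    None when an empty cluster forces a redraw."""
    n = matrix.shape[0]
    idx = rng.choice(n, size=k, replace=False)
    centers = matrix[idx].copy()
    for c in range(k):
        miss = np.isnan(centers[c])
        centers[c, miss] = grand_mean[miss]
    assignment = None
    trace = []
    for _ in range(max_iter):
        d2 = _sq_distances_to_centers(matrix, centers)
        new_assignment = d2.argmin(axis=1)
        if len(np.unique(new_assignment)) < k:
            return None
        trace.append(float(d2[np.arange(n), new_assignment].sum()))
        if assignment is not None and np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        centers = _update_centers(matrix, assignment, centers, k)
    return assignment, centers, trace


def kmeans_longitudinal(
    cohort: TrajectoryCohort,
    k: int = 4,
    n_restarts: int = 1000,
    seed: int = 0,
    max_iter: int = 100,
    max_redraws_per_restart: int = 100,
) -> Partition:
    """Best-of-restarts longitudinal k-means.

    Each restart seeds centers from k distinct patients (missing seed-center
    entries filled with the column grand mean), alternates Gower-distance
    assignment and Gower-weighted observed-mean center updates (the exact
    minimizer of the objective, reducing to the plain mean on complete
    data) until assignments stabilize,
    imputes via copy-mean and scores the partition by Calinski-Harabasz. The
    restart with the highest criterion wins (ties: lowest restart index).
    Restart r draws from seed ``seed + r``; a restart hitting an empty
    cluster is redrawn from the same stream (counted).
    """
    matrix = cohort.matrix
    n = matrix.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of patients ({n})")
    grand_mean = np.nanmean(matrix, axis=0)

    best = None
    n_redrawn = 0
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        result = None
        for _ in range(max_redraws_per_restart):
            result = _single_restart(matrix, grand_mean, rng, k, max_iter)
            if result is not None:
                break
            n_redrawn += 1
        if result is None:
            logger.warning("restart %d: could not avoid empty clusters; skipped", r)
            continue
        assignment, centers, _trace = result
        imputed = impute_copy_mean(cohort, assignment)
        ch = calinski_harabasz(imputed, assignment) if n > k else np.inf
        if best is None or ch > best[0]:
            best = (ch, r, assignment, centers, imputed)
    if best is None:
        raise RuntimeError("all restarts failed to produce a non-degenerate partition")
    if n_redrawn:
        logger.info("redrew %d restart initialization(s) after empty clusters", n_redrawn)

    ch, r_best, assignment, centers, imputed = best
    posterior = posterior_probabilities(imputed, centers, assignment)
    return Partition(
        k=k,
        assignment=assignment,
        centers=centers,
        imputed=imputed,
        ch=float(ch),
        posterior=posterior,
        n_restarts=n_restarts,
        best_restart_seed=seed + r_best,
        n_redrawn_restarts=n_redrawn,
    )


def calinski_harabasz(imputed: np.ndarray, assignment: np.ndarray) -> float:
    """Calinski-Harabasz criterion [trace(B)/(k-1)] / [trace(W)/(n-k)].

    Computed on the complete (imputed) matrix. Perfect separation
    (trace(W) = 0) returns +inf.
    """
    imputed = np.asarray(imputed, dtype=float)
    assignment = np.asarray(assignment)
    n = imputed.shape[0]
    clusters = np.unique(assignment)
    k = clusters.size
    if k < 2:
        raise ValueError("need >= 2 clusters")
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    grand = imputed.mean(axis=0)
    trace_b = 0.0
    trace_w = 0.0
    for c in clusters:
        rows = imputed[assignment == c]
        mu = rows.mean(axis=0)
        trace_b += rows.shape[0] * float(np.sum((mu - grand) ** 2))
        trace_w += float(np.sum((rows - mu) ** 2))
    if trace_w == 0.0:
        return float("inf")
    return (trace_b / (k - 1)) / (trace_w / (n - k))


def impute_copy_mean(cohort: TrajectoryCohort, assignment: np.ndarray) -> np.ndarray:
    """Copy-mean imputation: linear interpolation plus the cluster mean's
    deviation from its own interpolation.

    Interior gaps: patient's linear interpolation between flanking observed
    values, shifted by (cluster mean at t) - (linear interpolation of the
    cluster mean between the same flanking times). Leading/trailing gaps:
    nearest observed patient value plus the cluster-mean level difference.
    A cluster-time cell with no observations falls back to the grand mean.
    """
    matrix = cohort.matrix
    grid = cohort.grid
    n, t = matrix.shape
    grand = np.nanmean(matrix, axis=0)

    means = {}
    for c in np.unique(assignment):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns expected
            mu = np.nanmean(matrix[assignment == c], axis=0)
        miss = np.isnan(mu)
        if miss.any():
            logger.info("cluster %s: no observations at grid columns %s; grand-mean fallback", c, np.nonzero(miss)[0])
            mu[miss] = grand[miss]
        means[c] = mu

    imputed = matrix.copy()
    for i in range(n):
        obs = np.nonzero(~np.isnan(matrix[i]))[0]
        if obs.size == 0:
            raise ValueError(f"patient {cohort.patients[i]!r} has zero observations")
        if obs.size == t:
            continue
        mu = means[assignment[i]]
        for j in range(t):
            if not np.isnan(matrix[i, j]):
                continue
            left = obs[obs < j]
            right = obs[obs > j]
            if left.size and right.size:  # interior gap
                j0, j1 = left[-1], right[0]
                w = (grid[j] - grid[j0]) / (grid[j1] - grid[j0])
                pat = matrix[i, j0] + w * (matrix[i, j1] - matrix[i, j0])
                mean_interp = mu[j0] + w * (mu[j1] - mu[j0])
                imputed[i, j] = pat + (mu[j] - mean_interp)
            else:  # leading or trailing gap
                j0 = right[0] if right.size else left[-1]
                imputed[i, j] = matrix[i, j0] + (mu[j] - mu[j0])
    return imputed


def posterior_probabilities(imputed: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Gaussian-kernel assignment probabilities.

    p_ik proportional to exp(-d_ik^2 / (2 sigma^2)) with d the Euclidean
    distance of the imputed trajectory to each center and sigma^2 the pooled
    mean squared distance of patients to their own center. A degenerate
    sigma^2 = 0 yields one-hot rows.
    """
    diff = imputed[:, None, :] - centers[None, :, :]
    d2 = np.einsum("nkt,nkt->nk", diff, diff)
    n = imputed.shape[0]
    own = d2[np.arange(n), assignment]
    sigma2 = own.mean()
    if sigma2 == 0.0:
        post = np.zeros_like(d2)
        post[np.arange(n), assignment] = 1.0
        return post
    z = -d2 / (2.0 * sigma2)
    z -= z.max(axis=1, keepdims=True)
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)
    return post


def mean_assignment_probability(partition: Partition) -> float:
    """Mean over patients of the posterior probability of the assigned cluster."""
    n = partition.posterior.shape[0]
    return float(partition.posterior[np.arange(n), partition.assignment].mean())


def name_endotypes(centers_abc: np.ndarray) -> dict:
    """Deterministic endotype naming from centers on the original AB/C scale.

    For k=4: the cluster with the steepest D6-D1 decline is Decliners; among
    the rest the lowest D6 level is Non-improvers, the highest D6 level High
    expressors, and the remaining cluster Improvers. Ties break toward the
    lower D1 level. Other k get generic labels C1..Ck.
    """
    centers_abc = np.asarray(centers_abc, dtype=float)
    k = centers_abc.shape[0]
    if k != 4:
        return {i: f"C{i + 1}" for i in range(k)}
    d1 = centers_abc[:, 0]
    d6 = centers_abc[:, -1]
    delta = d6 - d1
    # most negative slope; ties toward lower D1
    order = np.lexsort((d1, delta))
    decliner = int(order[0])
    rest = [i for i in range(4) if i != decliner]
    rest_sorted = sorted(rest, key=lambda i: (d6[i], d1[i]))
    names = {decliner: "Decliners", rest_sorted[0]: "Non-improvers", rest_sorted[2]: "High expressors", rest_sorted[1]: "Improvers"}
    return names
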