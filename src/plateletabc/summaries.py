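"""Discriminative summary statistics learning (DSSL).

ABC needs a distance between an observed and a simulated deposition series.
Rather than hand-picking summary statistics, a low-dimensional linear
projection L of a polynomial feature expansion of the series is learned by
large-margin nearest-neighbor (LMNN) metric learning on a labelled cohort:
the induced Mahalanobis distance d(x1, x2) = ||L(f(x1) - f(x2))||_2 pulls
same-group neighbors together while pushing differently-labelled "impostors"
out of each point's neighborhood by a unit margin.  The Euclidean distance
in the learned 2-D summary space then serves as the ABC distance.

The LMNN objective minimised over L is

    (1 - mu) * sum_{i, j->i} ||L(x_i - x_j)||^2
    + mu * sum_{i, j->i, l} [1 + ||L(x_i - x_j)||^2 - ||L(x_i - x_l)||^2]_+

where j->i runs over the k target neighbors of i (nearest same-label points
in input space, fixed up front), l over differently-labelled points, and
[.]_+ is the hinge.  Optimisation is plain gradient descent on L with an
adaptive step, started from the top principal components, so the fit is
deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import pairwise_distances, rand_score

from .cohort import CohortDataset
from .simulator import DepositionTimeSeries

__all__ = [
    "FeatureExpansion",
    "SummaryProjection",
    "expand_features",
    "fit_discriminative_projection",
    "summary_distance",
    "tune_projection_by_rand_index",
    "cluster_rand_index",
]


@dataclasses.dataclass(frozen=True)
class FeatureExpansion:
    """Recipe for the polynomial expansion of a flattened series.

    The expanded vector is the concatenation of the elementwise powers
    ``x**o`` for each order ``o`` (ascending) followed, optionally, by the
    pairwise cross products ``x_i * x_j`` (i < j) of the order-1 block.
    """

    orders: tuple[int, ...] = (1, 2, 3)
    include_cross_products: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        orders = tuple(sorted(set(int(o) for o in self.orders)))
        if 1 not in orders:
            raise ValueError("orders must contain 1")
        if any(o < 1 for o in orders):
            raise ValueError("orders must be positive")
        object.__setattr__(self, "orders", orders)

    def output_dim(self, input_dim: int) -> int:
        d = len(self.orders) * input_dim
        if self.include_cross_products:
            d += input_dim * (input_dim - 1) // 2
        return d


def expand_features(x: Sequence[float], expansion: FeatureExpansion) -> np.ndarray:
    """Deterministic polynomial expansion of one flattened series vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input vector")
    blocks = [x**o for o in expansion.orders]
    if expansion.include_cross_products:
        i, j = np.triu_indices(len(x), k=1)
        blocks.append(x[i] * x[j])
    return np.concatenate(blocks)


def _expand_matrix(X: np.ndarray, expansion: FeatureExpansion) -> np.ndarray:
    return np.vstack([expand_features(row, expansion) for row in X])


def _safe_std(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features (e.g. the t=0 points) pass through
    return sd


@dataclasses.dataclass
class SummaryProjection:
    """A trained linear summary map and its preprocessing constants.

    ``project`` standardizes the raw vector with the training statistics,
    expands it, standardizes the expanded features, and applies L.  The
    induced distance ``||L f(x1) - L f(x2)||`` is a pseudo-metric for any L
    (M = L^T L is positive semi-definite by construction).
    """

    L: np.ndarray                    # (n_components, expanded_dim)
    expansion: FeatureExpansion
    input_mean: np.ndarray
    input_std: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    k_neighbors: int = 3

    @property
    def mahalanobis_matrix(self) -> np.ndarray:
        """M = L^T L defining the learned Mahalanobis distance."""
        return self.L.T @ self.L

    def _as_vector(self, x: "DepositionTimeSeries | np.ndarray") -> np.ndarray:
        if isinstance(x, DepositionTimeSeries):
            return x.as_vector()
        return np.asarray(x, dtype=float)

    def project(self, x: "DepositionTimeSeries | np.ndarray") -> np.ndarray:
        v = (self._as_vector(x) - self.input_mean) / self.input_std
        f = (expand_features(v, self.expansion) - self.feature_mean) / self.feature_std
        return self.L @ f

    def project_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.vstack([self.project(row) for row in np.asarray(X, dtype=float)])


def summary_distance(
    x1: "DepositionTimeSeries | np.ndarray",
    x2: "DepositionTimeSeries | np.ndarray",
    proj: SummaryProjection,
) -> float:
    """Euclidean distance between the learned summaries of two series."""
    if isinstance(x1, DepositionTimeSeries) and isinstance(x2, DepositionTimeSeries):
        if not np.array_equal(x1.times, x2.times):
            raise ValueError("series have mismatched observation grids")
    return float(np.linalg.norm(proj.project(x1) - proj.project(x2)))


# ---------------------------------------------------------------------------
# LMNN fit
# ---------------------------------------------------------------------------

def _target_neighbors(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """(n, k) indices of the k nearest same-label points in input space."""
    D = pairwise_distances(X)
    np.fill_diagonal(D, np.inf)
    out = np.empty((len(X), k), dtype=int)
    for i in range(len(X)):
        same = np.flatnonzero((y == y[i]) & (np.arange(len(X)) != i))
        order = same[np.argsort(D[i, same], kind="stable")]
        out[i] = order[:k]
    return out


def _lmnn_objective_grad(
    L: np.ndarray, X: np.ndarray, y: np.ndarray, targets: np.ndarray, mu: float
) -> tuple[float, np.ndarray]:
    """Objective value and dL gradient of the pull/push LMNN loss."""
    Z = X @ L.T                               # (n, r)
    n = len(X)
    sq = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)  # (n, n)

    # Laplacian-weighted Gram assembly: sum_w (x_a - x_b)(x_a - x_b)^T = X^T Lap X
    W = np.zeros((n, n))
    pull = 0.0
    push = 0.0
    for i in range(n):
        diff_mask = y != y[i]
        for j in targets[i]:
            pull += sq[i, j]
            W[i, j] += (1.0 - mu)
            margin = 1.0 + sq[i, j] - sq[i, diff_mask]
            active = margin > 0
            push += float(margin[active].sum())
            if active.any():
                W[i, j] += mu * active.sum()
                idx = np.flatnonzero(diff_mask)[active]
                W[i, idx] -= mu
    # symmetrise pair weights into a Laplacian
    Wsym = W + W.T
    lap = np.diag(Wsym.sum(axis=1)) - Wsym
    grad = L @ (X.T @ lap @ X)
    obj = (1.0 - mu) * pull + mu * push
    return obj, grad


def fit_discriminative_projection(
    cohort: "CohortDataset | tuple[np.ndarray, np.ndarray]",
    expansion: FeatureExpansion | None = None,
    k_neighbors: int = 3,
    regularization: float = 0.5,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> SummaryProjection:
    """Learn the discriminative summary projection from a labelled cohort.

    Parameters
    ----------
    cohort
        A :class:`CohortDataset`, or a ``(X, labels)`` pair with X of shape
        (n_samples, n_raw_features).
    regularization
        The pull/push trade-off mu in (0, 1); larger values weight margin
        violations more heavily.
    """
    expansion = expansion if expansion is not None else FeatureExpansion()
    if isinstance(cohort, CohortDataset):
        X_raw = cohort.series_matrix()
        y = np.asarray(cohort.labels)
    else:
        X_raw, y = cohort
        X_raw = np.asarray(X_raw, dtype=float)
        y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two groups to learn a discriminative projection")
    if counts.min() <= k_neighbors:
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the smallest "
            f"group size ({counts.min()})"
        )
    if not 0 < regularization < 1:
        raise ValueError("regularization (mu) must lie in (0, 1)")

    if expansion.standardize:
        in_mean, in_std = X_raw.mean(axis=0), _safe_std(X_raw)
    else:
        in_mean = np.zeros(X_raw.shape[1])
        in_std = np.ones(X_raw.shape[1])
    Xs = (X_raw - in_mean) / in_std
    F = _expand_matrix(Xs, expansion)
    if expansion.standardize:
        f_mean, f_std = F.mean(axis=0), _safe_std(F)
    else:
        f_mean = np.zeros(F.shape[1])
        f_std = np.ones(F.shape[1])
    F = (F - f_mean) / f_std

    targets = _target_neighbors(F, y, k_neighbors)

    # deterministic PCA initialisation plus a tiny seeded perturbation
    rng = np.random.default_rng(seed)
    Fc = F - F.mean(axis=0)
    _, _, vt = np.linalg.svd(Fc, full_matrices=False)
    L = vt[:n_components].copy()
    L *= np.sign(L[:, :1])  # fix SVD sign ambiguity
    L += 1e-3 * rng.standard_normal(L.shape)

    step = 1e-4
    obj, grad = _lmnn_objective_grad(L, F, y, targets, regularization)
    converged = False
    for _ in range(max_iter):
        L_new = L - step * grad
        obj_new, grad_new = _lmnn_objective_grad(L_new, F, y, targets, regularization)
        if obj_new < obj:
            if obj - obj_new < tol * max(1.0, abs(obj)):
                L, obj = L_new, obj_new
                converged = True
                break
            L, obj, grad = L_new, obj_new, grad_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-14:
                converged = True
                break
    if not converged:
        warnings.warn("LMNN did not converge; returning best iterate", RuntimeWarning)

    return SummaryProjection(
        L=L,
        expansion=expansion,
        input_mean=in_mean,
        input_std=in_std,
        feature_mean=f_mean,
        feature_std=f_std,
        k_neighbors=k_neighbors,
    )


# ---------------------------------------------------------------------------
# hyperparameter tuning by rand index
# ---------------------------------------------------------------------------

def cluster_rand_index(
    proj: SummaryProjection, X_raw: np.ndarray, labels: Sequence[str]
) -> float:
    """Rand index of agglomerative (Ward/Euclidean) clustering in summary space."""
    Z = proj.project_matrix(X_raw)
    n_groups = len(set(labels))
    pred = AgglomerativeClustering(n_clusters=n_groups).fit_predict(Z)
    return float(rand_score(np.asarray(labels), pred))


def tune_projection_by_rand_index(
    cohort: "CohortDataset | tuple[np.ndarray, np.ndarray]",
    candidates: Iterable[dict],
) -> tuple[SummaryProjection, float]:
    """Grid search over fit hyperparameters, scored by clustering rand index.

    Each candidate is a keyword dictionary for
    :func:`fit_discriminative_projection`.  Ties break toward the first
    candidate in grid order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate grid is empty")
    if isinstance(cohort, CohortDataset):
        X_raw, y = cohort.series_matrix(), np.asarray(cohort.labels)
    else:
        X_raw, y = np.asarray(cohort[0], dtype=float), np.asarray(cohort[1])
    best: tuple[SummaryProjection, float] | None = None
    for kwargs in candidates:
        proj = fit_discriminative_projection((X_raw, y), **kwargs)
        ri = cluster_rand_index(proj, X_raw, y)
        if best is None or ri > best[1]:
            best = (proj, ri)
    return best


def default_candidate_grid() -> list[dict]:
    """A small deterministic hyperparameter grid for tuning."""
    grid = []
    for k in (2, 3):
        for mu in (0.3, 0.5, 0.7):
            grid.append({"k_neighbors": k, "regularization": mu})
    return grid
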