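"""Feature standardization, k-means, Gaussian mixtures and elbow selection.

Both clustering routines are written for full transparency of their
internals: k-means records the within-cluster sum of squares (WCSS) at
every Lloyd iteration and the EM fitter records the total log-likelihood
at every step, so monotonicity — the basic correctness certificate of
each algorithm — is checkable on every run. Initialization uses the
k-means++ seeding of scikit-learn; all randomness flows from a single
integer seed through numpy's SeedSequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import DegenerateInputError, NumericalError
from .texture import FeatureTable

__all__ = [
    "standardize",
    "KMeansModel",
    "kmeans_fit",
    "ElbowResult",
    "elbow_select",
    "select_knee",
    "GMMModel",
    "gmm_fit",
    "predict_labels",
]

logger = logging.getLogger(__name__)


def standardize(ft: FeatureTable) -> FeatureTable:
    """Center each column and scale to unit (population) variance.

    Zero-variance columns map to all zeros. The per-column (mean, sd)
    pair is stored on the returned table for the inverse transform.
    """
    if len(ft) < 2:
        raise DegenerateInputError("standardization needs at least 2 rows")
    mean = ft.X.mean(axis=0)
    sd = ft.X.std(axis=0)  # population sd
    z = np.where(sd > 0, (ft.X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return FeatureTable(
        ids=ft.ids.copy(),
        X=z,
        column_names=ft.column_names,
        standardized=True,
        standardization=(mean, sd),
    )


def _as_matrix(ft: FeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(ft, FeatureTable):
        return ft.X
    return np.asarray(ft, dtype=np.float64)


def _wcss(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    wcss: float
    seed: int
    n_init: int
    n_iter: int
    wcss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _lloyd(X: np.ndarray, k: int, rs: int, max_iter: int, tol: float):
    """One k-means++-initialized Lloyd run; returns (centroids, labels, trace)."""
    n = len(X)
    if k == n:
        centroids = X.copy()
        labels = np.arange(n)
        return centroids, labels, np.array([0.0])
    centroids, _ = kmeans_plusplus(X, n_clusters=k, random_state=rs)
    trace = []
    labels = np.zeros(n, dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # Empty-cluster repair: reseed from the points farthest from their
        # centroid, one distinct point per empty cluster.
        empty = [c for c in range(k) if not (labels == c).any()]
        if empty:
            order = np.argsort(d2[np.arange(n), labels])[::-1]
            for c, far in zip(empty, order):
                centroids[c] = X[far]
                labels[far] = c
        new_centroids = np.vstack(
            [
                X[labels == c].mean(axis=0) if (labels == c).any() else centroids[c]
                for c in range(k)
            ]
        )
        trace.append(_wcss(X, new_centroids, labels))
        shift = np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max()
        centroids = new_centroids
        if shift < tol:
            break
    # Final reassignment so every label is nearest its centroid.
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    trace.append(_wcss(X, centroids, labels))
    # Hartigan refinement: single-point moves escape Lloyd fixed points
    # that are not single-swap optimal (Lloyd alone can converge with no
    # pairwise-reachable path to the optimum even on tiny instances).
    labels, centroids = _hartigan_refine(X, labels, centroids)
    trace.append(_wcss(X, centroids, labels))
    return centroids, labels, np.asarray(trace)


def _hartigan_refine(X, labels, centroids, max_sweeps: int = 50):
    """Greedy single-point reassignments until no move lowers the WCSS.

    Moving x from cluster A (size nA > 1) to B changes the objective by
    nB/(nB+1) ||x - cB||^2 - nA/(nA-1) ||x - cA||^2; apply any strictly
    improving move, updating centroids incrementally.
    """
    labels = labels.copy()
    centroids = centroids.copy()
    k = len(centroids)
    sizes = np.bincount(labels, minlength=k).astype(float)
    sums = np.vstack([X[labels == c].sum(axis=0) if sizes[c] else
                      np.zeros(X.shape[1]) for c in range(k)])
    for _ in range(max_sweeps):
        improved = False
        for i in range(len(X)):
            a = labels[i]
            if sizes[a] <= 1:
                continue
            x = X[i]
            loss_out = sizes[a] / (sizes[a] - 1) * ((x - centroids[a]) ** 2).sum()
            gains = sizes / (sizes + 1) * ((x - centroids) ** 2).sum(axis=1)
            gains[a] = np.inf
            b = int(gains.argmin())
            if gains[b] < loss_out - 1e-12:
                sums[a] -= x
                sums[b] += x
                sizes[a] -= 1
                sizes[b] += 1
                centroids[a] = sums[a] / sizes[a]
                centroids[b] = sums[b] / sizes[b]
                labels[i] = b
                improved = True
        if not improved:
            break
    return labels, centroids


def kmeans_fit(
    ft: FeatureTable | np.ndarray,
    k: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> KMeansModel:
    """Lloyd's algorithm with k-means++ restarts; best restart by WCSS.

    Iteration stops when the largest centroid shift drops below ``tol``.
    Empty clusters are repaired by reseeding from the farthest point.
    """
    X = _as_matrix(ft)
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_init)]
    best = None
    for rs in restart_seeds:
        centroids, labels, trace = _lloyd(X, k, rs, max_iter, tol)
        wcss = trace[-1]
        if best is None or wcss < best[0]:
            best = (wcss, centroids, labels, trace)
    wcss, centroids, labels, trace = best
    return KMeansModel(
        k=k,
        centroids=centroids,
        labels=labels,
        wcss=float(wcss),
        seed=seed,
        n_init=n_init,
        n_iter=len(trace),
        wcss_trace=trace,
    )


@dataclass
class ElbowResult:
    k_range: np.ndarray
    wcss_curve: np.ndarray
    selected_k: int
    curvature_scores: dict[int, float]
    drop_ratios: dict[int, float] = field(default_factory=dict)


def elbow_select(
    ft: FeatureTable | np.ndarray,
    k_min: int = 1,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> ElbowResult:
    """Pick the cluster count at the knee of the WCSS-vs-k curve.

    The knee is automated as the interior k with the largest relative
    drop wcss(k-1)/wcss(k): past the true cluster count the objective
    stops falling by whole factors, so the last large ratio marks the
    knee. Discrete second differences wcss(k-1) - 2 wcss(k) + wcss(k+1)
    (the curvature reading of the same curve) are also returned, along
    with the full curve, so a user can override the choice visually,
    which is how the heuristic is traditionally applied.
    """
    X = _as_matrix(ft)
    n = len(X)
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds the number of rows n={n}")
    if k_max < k_min + 2:
        raise ValueError("k_max must be at least k_min + 2 to have an interior knee")
    ks = np.arange(k_min, k_max + 1)
    wcss = np.array([kmeans_fit(X, int(k), seed=seed, n_init=n_init).wcss for k in ks])
    return select_knee(ks, wcss)


def select_knee(ks: np.ndarray, wcss: np.ndarray) -> ElbowResult:
    """Knee selection on a precomputed WCSS curve (see elbow_select)."""
    ks = np.asarray(ks)
    wcss = np.asarray(wcss, dtype=float)
    scale = max(wcss.max(), 1.0)
    if np.any(np.diff(wcss) > 1e-8 * scale):
        logger.warning("WCSS curve is not monotonically non-increasing; "
                       "consider more restarts")
    floor = 1e-12 * scale  # guard against division by a fully-explained fit
    scores = {
        int(ks[i]): float(wcss[i - 1] - 2 * wcss[i] + wcss[i + 1])
        for i in range(1, len(ks) - 1)
    }
    ratios = {
        int(ks[i]): float(wcss[i - 1] / max(wcss[i], floor))
        for i in range(1, len(ks) - 1)
    }
    if max(scores.values()) <= 1e-12 * scale:
        logger.warning("no distinct elbow: the WCSS curve has no positive curvature")
    selected = max(ratios, key=lambda k: (ratios[k], -k))
    return ElbowResult(
        k_range=ks,
        wcss_curve=wcss,
        selected_k=int(selected),
        curvature_scores=scores,
        drop_ratios=ratios,
    )


@dataclass
class GMMModel:
    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d), full
    responsibilities: np.ndarray  # (n, k)
    loglik_trace: np.ndarray
    labels: np.ndarray
    seed: int


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"covariance matrix is singular despite regularization "
            f"(min diag {cov.diagonal().min():.3e})"
        ) from exc
    diff = X - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _em(X: np.ndarray, k: int, seed: int, max_iter: int, tol: float, reg: float):
    n, d = X.shape
    km = kmeans_fit(X, k, seed=seed, n_init=1)
    means = km.centroids.copy()
    resp = np.zeros((n, k))
    resp[np.arange(n), km.labels] = 1.0
    weights = resp.sum(axis=0) / n
    covs = np.empty((k, d, d))
    trace = []
    log_prob = np.empty((n, k))
    for it in range(max_iter + 1):
        # M-step (skipped before the first E-step only when it == 0 and we
        # already have responsibilities from the k-means hard assignment).
        nk = resp.sum(axis=0) + 10 * np.finfo(float).eps
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        for c in range(k):
            diff = X - means[c]
            covs[c] = (resp[:, c][:, None] * diff).T @ diff / nk[c]
            covs[c].flat[:: d + 1] += reg
        # E-step
        for c in range(k):
            log_prob[:, c] = np.log(weights[c] + 1e-300) + _log_gaussian(
                X, means[c], covs[c]
            )
        norm = logsumexp(log_prob, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_prob - norm[:, None])
        trace.append(loglik)
        if it > 0 and trace[-1] - trace[-2] < tol:
            break
    return weights, means, covs, resp, np.asarray(trace)


def gmm_fit(
    ft: FeatureTable | np.ndarray,
    k: int,
    seed: int,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-3,
    reg_covar: float = 1e-6,
) -> GMMModel:
    """Full-covariance Gaussian mixture fit by expectation-maximization.

    Means are initialized from a k-means run; each restart uses a
    different derived seed and the restart with the highest final
    log-likelihood wins. Covariances get a ridge ``reg_covar`` on the
    diagonal. Convergence: log-likelihood gain below ``tol``. Labels are
    the argmax of the posterior responsibilities.
    """
    X = _as_matrix(ft)
    n, d = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if n <= d:
        raise ValueError(f"full covariances need n > d (n={n}, d={d})")
    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_init)]
    best = None
    for rs in restart_seeds:
        fit = _em(X, k, rs, max_iter, tol, reg_covar)
        if best is None or fit[4][-1] > best[4][-1]:
            best = fit
    weights, means, covs, resp, trace = best
    return GMMModel(
        k=k,
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=resp,
        loglik_trace=trace,
        labels=resp.argmax(axis=1),
        seed=seed,
    )


def predict_labels(model: KMeansModel | GMMModel, ft: FeatureTable | np.ndarray) -> np.ndarray:
    """Assign each row to a cluster of a fitted model.

    Nearest centroid for k-means; maximum posterior responsibility for a
    Gaussian mixture.
    """
    X = _as_matrix(ft)
    if isinstance(model, KMeansModel):
        if X.shape[1] != model.centroids.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {model.centroids.shape[1]}"
            )
        d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {model.means.shape[1]}"
        )
    log_prob = np.empty((len(X), model.k))
    for c in range(model.k):
        log_prob[:, c] = np.log(model.weights[c] + 1e-300) + _log_gaussian(
            X, model.means[c], model.covariances[c]
        )
    return log_prob.argmax(axis=1)
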