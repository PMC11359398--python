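"""Internal cluster-quality indices and inter-method agreement indices.

Internal quality is measured without ground truth: the silhouette
coefficient (how much closer each patch is to its own cluster than to
the nearest other cluster, in [-1, 1]) and the Davies–Bouldin index
(average worst-case ratio of intra-cluster scatter to centroid
separation; lower is better). Agreement between two labelings — e.g.
k-means vs a Gaussian mixture — is summarized by the contingency table,
the Adjusted Rand Index and Normalized Mutual Information, all invariant
to label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as _skm
from sklearn.metrics.cluster import contingency_matrix as _sk_contingency

from .errors import DegenerateInputError, NumericalError

__all__ = [
    "silhouette_score",
    "davies_bouldin",
    "contingency_table",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "match_labels",
    "EvaluationReport",
    "AgreementReport",
    "evaluate_clustering",
    "compare_labelings",
]


def _check_pair(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    return a, b


def silhouette_score(X: np.ndarray, labels) -> float:
    """Mean silhouette coefficient with Euclidean distance.

    Per point, a = mean distance to own-cluster peers and b = smallest
    mean distance to another cluster; s = (b - a)/max(a, b), with
    singleton clusters contributing 0 and a = b = 0 mapping to 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).ravel()
    k = len(np.unique(labels))
    if k < 2 or k >= len(labels):
        raise DegenerateInputError(
            f"silhouette undefined for k={k} clusters on n={len(labels)} points"
        )
    return float(_skm.silhouette_score(X, labels, metric="euclidean"))


def davies_bouldin(X: np.ndarray, labels) -> float:
    """Davies–Bouldin index: (1/k) sum_i max_{j!=i} (s_i + s_j) / d_ij.

    s_i is the mean Euclidean distance of cluster-i points to their
    centroid and d_ij the distance between centroids i and j.

    Raises
    ------
    NumericalError
        If two clusters share a centroid while carrying positive scatter
        (the ratio diverges).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    k = len(classes)
    if k < 2:
        raise DegenerateInputError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    scatter = np.array(
        [
            np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(classes)
        ]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            if sep[i, j] == 0.0:
                if scatter[i] + scatter[j] > 0.0:
                    raise NumericalError(
                        f"clusters {classes[i]} and {classes[j]} share a centroid "
                        "with positive scatter; Davies-Bouldin ratio diverges"
                    )
                continue  # coincident degenerate singletons contribute 0
            worst = max(worst, (scatter[i] + scatter[j]) / sep[i, j])
        total += worst
    return total / k


def contingency_table(labels_a, labels_b) -> np.ndarray:
    """k1 x k2 co-assignment counts; entry (i, j) counts points with
    a-label i and b-label j (labels in sorted unique order)."""
    a, b = _check_pair(labels_a, labels_b)
    if len(a) < 1:
        raise ValueError("need at least one point")
    return np.asarray(_sk_contingency(a, b))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Pair-counting partition agreement corrected for chance; <= 1.

    1 for identical partitions, about 0 for independent random
    labelings. When both labelings are trivial (the chance-corrected
    denominator vanishes) the value is 1 for identical partitions and 0
    otherwise.
    """
    a, b = _check_pair(labels_a, labels_b)
    if len(a) < 2:
        raise ValueError("ARI needs at least two points")
    return float(_skm.adjusted_rand_score(a, b))


def normalized_mutual_information(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Mutual information normalized by the mean of the two entropies.

    Natural-log entropies from empirical frequencies; ``average`` picks
    the normalization mean ("arithmetic" by default, "geometric"
    available). Both entropies zero (two constant labelings) gives 1;
    one constant labeling against a non-trivial one gives 0.
    """
    a, b = _check_pair(labels_a, labels_b)
    if len(a) < 1:
        raise ValueError("NMI needs at least one point")
    return float(_skm.normalized_mutual_info_score(a, b, average_method=average))


def match_labels(contingency: np.ndarray) -> dict[int, int]:
    """Map row labels to column labels maximizing the matched diagonal.

    Presentation aid only (Hungarian assignment on the contingency
    table); ARI and NMI never depend on any matching.
    """
    cont = np.asarray(contingency)
    rows, cols = linear_sum_assignment(-cont)
    return {int(r): int(c) for r, c in zip(rows, cols)}


@dataclass(frozen=True)
class EvaluationReport:
    silhouette: float
    davies_bouldin: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
            "n": self.n,
            "k": self.k,
        }


@dataclass(frozen=True)
class AgreementReport:
    contingency: np.ndarray
    ari: float
    nmi: float

    def to_dict(self) -> dict:
        return {
            "contingency": self.contingency.tolist(),
            "ari": self.ari,
            "nmi": self.nmi,
        }


def evaluate_clustering(X: np.ndarray, labels) -> EvaluationReport:
    """Silhouette + Davies-Bouldin for one labeling of a feature matrix."""
    labels = np.asarray(labels).ravel()
    return EvaluationReport(
        silhouette=silhouette_score(X, labels),
        davies_bouldin=davies_bouldin(X, labels),
        n=len(labels),
        k=len(np.unique(labels)),
    )


def compare_labelings(labels_a, labels_b) -> AgreementReport:
    """Contingency table, ARI and NMI between two labelings."""
    return AgreementReport(
        contingency=contingency_table(labels_a, labels_b),
        ari=adjusted_rand_index(labels_a, labels_b),
        nmi=normalized_mutual_information(labels_a, labels_b),
    )
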