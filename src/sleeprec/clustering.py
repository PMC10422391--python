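"""Sleep-pattern discovery by K-means clustering.

Wearable sleep features (snoring, noise, sleep time, movement, BMI) are
weakly correlated across users, so pattern labels are *defined* by
clustering rather than taken from any external standard.  The number of
patterns k is chosen in two steps: an elbow curve (within-cluster sum of
squared distances against k) shortlists candidates, and the mean
silhouette score decides.

The K-means here is a from-scratch Lloyd's algorithm with k-means++
seeding and multiple restarts; scikit-learn is intentionally not used for
the fit (it serves as an independent cross-check in the test suite).
"""

from __future__ import annotations

import json

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin

from .profiles import FeatureNormalizer, UserProfile

DEFAULT_K_RANGE = tuple(range(1, 9))


# ---------------------------------------------------------------------------
# core K-means primitives


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: sample centers proportional to squared distance."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = cdist(X, centers[:1], "sqeuclidean")[:, 0]
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, cdist(X, centers[j : j + 1], "sqeuclidean")[:, 0])
    return centers


def lloyd_iterations(X, centers, tol=1e-6, max_iter=300):
    """Run Lloyd's algorithm from given centers.

    Returns ``(centers, labels, inertia, history)`` where ``history`` is the
    inertia recorded at every assignment step — non-increasing by
    construction, which the test suite asserts.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    centers = np.array(centers, dtype=float, copy=True)
    history = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(n), labels].sum()))
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            members = labels == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
            else:
                # empty cluster: reseed at the point farthest from its center
                new_centers[j] = X[d2[np.arange(n), labels].argmax()]
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift < tol:
            break
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    history.append(inertia)
    return centers, labels, inertia, history


def fit_kmeans(X, k, *, restarts=10, tol=1e-6, max_iter=300, rng=None):
    """Best-of-restarts K-means; returns (centers, labels, inertia, history)."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("K-means input contains non-finite values")
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"infeasible k={k} for n={n} points")
    rng = np.random.default_rng(rng)
    best = None
    for _ in range(restarts):
        centers0 = _kmeans_pp_init(X, k, rng)
        result = lloyd_iterations(X, centers0, tol=tol, max_iter=max_iter)
        if best is None or result[2] < best[2]:
            best = result
    return best


def elbow_curve(X, k_range=DEFAULT_K_RANGE, *, restarts=10, tol=1e-6, max_iter=300, rng=None):
    """Within-cluster sum of squared distances for each candidate k."""
    X = np.asarray(X, dtype=float)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    if max(k_range) > X.shape[0]:
        raise ValueError(f"infeasible k={max(k_range)} for n={X.shape[0]} points")
    rng = np.random.default_rng(rng)
    return {
        int(k): fit_kmeans(X, k, restarts=restarts, tol=tol, max_iter=max_iter, rng=rng)[2]
        for k in k_range
    }


def silhouette_scores(X, labels):
    """Per-point silhouette s(i) = (b - a) / max(a, b) and its mean.

    a(i) is the mean distance to co-members of the point's own cluster,
    b(i) the smallest mean distance to any other cluster.  Points in
    singleton clusters score 0, as does the degenerate a = b = 0 case.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    n = X.shape[0]
    D = cdist(X, X)
    # mean distance from every point to every cluster
    M = np.column_stack([D[:, labels == c].mean(axis=1) for c in uniq])
    sizes = np.array([(labels == c).sum() for c in uniq])
    own_col = np.searchsorted(uniq, labels)
    own_size = sizes[own_col]
    s = np.zeros(n)
    nonsingle = own_size > 1
    # exclude self-distance (0) from the own-cluster mean
    a = np.where(nonsingle, M[np.arange(n), own_col] * own_size / np.maximum(own_size - 1, 1), 0.0)
    M_other = M.copy()
    M_other[np.arange(n), own_col] = np.inf
    b = M_other.min(axis=1)
    denom = np.maximum(a, b)
    valid = nonsingle & (denom > 0)
    s[valid] = (b[valid] - a[valid]) / denom[valid]
    return s, float(s.mean())


def select_k(inertia_by_k: dict, silhouette_by_k: dict) -> int:
    """Pick k maximising mean silhouette (ties -> smallest k).

    The elbow curve is kept as a diagnostic shortlist; the silhouette
    decides, mirroring the two-step selection procedure.
    """
    if not silhouette_by_k:
        raise ValueError("no candidate k with a defined silhouette")
    ks = sorted(int(k) for k in silhouette_by_k)
    best = max(ks, key=lambda k: (silhouette_by_k[k], -k))
    return int(best)


# ---------------------------------------------------------------------------
# estimator


class SleepPatternClusterer(BaseEstimator, ClusterMixin):
    """K-means sleep-pattern model with automatic cluster-count selection.

    Parameters
    ----------
    k : "auto" or int
        Number of pattern labels; "auto" selects by mean silhouette over
        ``k_range`` (elbow curve retained as a diagnostic).
    k_range : sequence of int
        Candidate cluster counts, default 1..8.
    restarts, tol, max_iter
        Lloyd's-algorithm controls (best of ``restarts`` k-means++ runs).
    normalize : bool
        Z-score features before clustering so no unit dominates.
    feature_subset : sequence of int or None
        Column indices to cluster on (None = all five).  Whether the
        movement feature should join the snoring / sound / sleep-time /
        BMI quartet is an open modelling question; it participates by
        default and can be dropped with ``feature_subset=(0, 2, 3, 4)``.
    random_state : int or None
        Seed for reproducible fits.

    Attributes
    ----------
    k_ : selected number of patterns
    centroids_ : (k, n_features) centroids in normalized space
    labels_ : training-set pattern labels
    inertia_ : within-cluster sum of squared distances at k_
    inertia_by_k_, silhouette_by_k_ : selection diagnostics
    norm_ : fitted FeatureNormalizer (None when ``normalize=False``)
    """

    def __init__(self, k="auto", k_range=DEFAULT_K_RANGE, restarts=10,
                 tol=1e-6, max_iter=300, normalize=True, feature_subset=None,
                 random_state=None):
        self.k = k
        self.k_range = k_range
        self.restarts = restarts
        self.tol = tol
        self.max_iter = max_iter
        self.normalize = normalize
        self.feature_subset = feature_subset
        self.random_state = random_state

    def _select_columns(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X if self.feature_subset is None else X[:, list(self.feature_subset)]

    def fit(self, X, y=None):
        X = self._select_columns(X)
        if not np.all(np.isfinite(X)):
            raise ValueError("clustering input contains non-finite values")
        n = X.shape[0]
        if self.normalize:
            names = None
            if self.feature_subset is not None:
                from .profiles import FEATURE_NAMES

                names = tuple(FEATURE_NAMES[i] for i in self.feature_subset
                              if i < len(FEATURE_NAMES))
            self.norm_ = FeatureNormalizer(feature_names=names).fit(X)
            Z = self.norm_.transform(X)
        else:
            self.norm_ = None
            Z = X
        rng = np.random.default_rng(self.random_state)
        auto = isinstance(self.k, str) and self.k == "auto"
        if auto:
            candidates = [k for k in self.k_range if k <= n]
            if not candidates:
                raise ValueError("no feasible k in k_range")
        else:
            candidates = [int(self.k)]
            if candidates[0] < 2 or candidates[0] > n:
                raise ValueError(f"k must satisfy 2 <= k <= n, got {candidates[0]}")
        fits = {}
        self.inertia_by_k_ = {}
        self.silhouette_by_k_ = {}
        for k in candidates:
            fits[k] = fit_kmeans(Z, k, restarts=self.restarts, tol=self.tol,
                                 max_iter=self.max_iter, rng=rng)
            self.inertia_by_k_[k] = fits[k][2]
            if 2 <= k <= n - 1 and np.unique(fits[k][1]).size >= 2:
                self.silhouette_by_k_[k] = silhouette_scores(Z, fits[k][1])[1]
        self.k_ = select_k(self.inertia_by_k_, self.silhouette_by_k_) if auto else candidates[0]
        centers, labels, inertia, history = fits[self.k_]
        self.centroids_ = centers
        self.labels_ = labels
        self.inertia_ = inertia
        self.inertia_history_ = history
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "centroids_"):
            raise AttributeError("SleepPatternClusterer is not fitted yet")

    def normalize_features(self, X):
        """Map raw features into the model's clustering space."""
        self._check_fitted()
        X = self._select_columns(X)
        return self.norm_.transform(X) if self.norm_ is not None else X

    def transform(self, X):
        """Distances from each sample to each pattern centroid."""
        return cdist(self.normalize_features(X), self.centroids_)

    def predict(self, X):
        """Nearest-centroid pattern label (ties -> lowest label index)."""
        return self.transform(X).argmin(axis=1)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "k": int(self.k_),
            "centroids": self.centroids_.tolist(),
            "inertia_by_k": {str(k): v for k, v in self.inertia_by_k_.items()},
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k_.items()},
            "norm": self.norm_.to_dict() if self.norm_ is not None else None,
            "feature_subset": None if self.feature_subset is None else list(self.feature_subset),
            "random_state": self.random_state,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SleepPatternClusterer":
        subset = d.get("feature_subset")
        model = cls(k=d["k"], random_state=d.get("random_state"),
                    normalize=d.get("norm") is not None,
                    feature_subset=None if subset is None else tuple(subset))
        model.k_ = int(d["k"])
        model.centroids_ = np.asarray(d["centroids"], dtype=float)
        model.inertia_by_k_ = {int(k): v for k, v in d.get("inertia_by_k", {}).items()}
        model.silhouette_by_k_ = {int(k): v for k, v in d.get("silhouette_by_k", {}).items()}
        model.norm_ = FeatureNormalizer.from_dict(d["norm"]) if d.get("norm") else None
        model.inertia_ = model.inertia_by_k_.get(model.k_, float("nan"))
        model.n_features_in_ = model.centroids_.shape[1]
        return model

    @classmethod
    def load(cls, path) -> "SleepPatternClusterer":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_patterns(X, k, *, seed=None, restarts=10, tol=1e-6, max_iter=300,
                 normalize=False) -> SleepPatternClusterer:
    """Fit a pattern model at a fixed k (thin wrapper over the estimator).

    ``normalize=False`` by default: this entry point expects features
    already in normalized space.
    """
    model = SleepPatternClusterer(k=k, restarts=restarts, tol=tol, max_iter=max_iter,
                                  normalize=normalize, random_state=seed)
    return model.fit(X)


def assign_pattern(profile_or_x, model: SleepPatternClusterer):
    """Label of the nearest centroid for one profile or feature vector."""
    if isinstance(profile_or_x, UserProfile):
        x = profile_or_x.features
    else:
        x = np.asarray(profile_or_x, dtype=float)
    labels = model.predict(np.atleast_2d(x))
    return int(labels[0]) if x.ndim == 1 else labels
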