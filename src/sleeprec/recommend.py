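"""Rating prediction and top-N sleep-pattern recommendation.

The hybrid engine (:class:`PatternCFRecommender`) predicts a user's
rating of an unrated pattern as the similarity-weighted average of the
raw 1-5 ratings given by same-pattern neighbors:

    r_hat(u, j) = sum_i sim(u, i) * r(i, j) / sum_i sim(u, i)

Similarities come from the normalized [-1, 1] rating matrix; the weighted
average runs on raw ratings so predictions stay on the rating scale.
When no neighbor mass is available (a cold-start user, or zero total
similarity) the prediction is undefined and control falls through to a
feature-space k-nearest-neighbor fallback, which always returns a defined
value — a user with zero ratings therefore still receives a full-length
recommendation list.  Repeated feedback rounds densify the rating matrix
and sharpen the neighborhoods.

Baselines for comparison: global (unrestricted) user-based CF, a
content-based model scoring patterns by feature-space distance, and their
unweighted combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import SleepPatternClusterer
from .profiles import UserProfile, reconstruct_profile
from .ratings import RatingMatrix, SimilarityResult, neighbor_set

#: prediction when even the global rating pool is empty
EMPTY_MATRIX_PRIOR = 3.0


@dataclass(frozen=True)
class Prediction:
    uid: str
    smid: str
    r_predict: float
    support: int
    method: str

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r_predict)


@dataclass
class RecommendationList:
    uid: str
    entries: list = field(default_factory=list)  # (smid, r_predict), sorted desc
    n_requested: int = 0


def predict_rating(uid, smid, neighbors: list[SimilarityResult],
                   matrix: RatingMatrix) -> Prediction:
    """Similarity-weighted average of neighbor ratings for one pattern.

    Every neighbor must have rated ``smid`` (contract of the caller, which
    filters the neighbor set per item).  With no neighbors or zero total
    similarity the prediction is undefined (NaN) and the caller is
    expected to fall back.
    """
    j = matrix.smid_index(smid)
    sims = np.array([nb.sim for nb in neighbors], dtype=float)
    rates = np.empty(len(neighbors))
    for idx, nb in enumerate(neighbors):
        r = matrix.raw[matrix.uid_index(nb.uid_b), j]
        if np.isnan(r):
            raise ValueError(f"neighbor {nb.uid_b!r} has not rated {smid!r}")
        rates[idx] = r
    total = sims.sum()
    if len(neighbors) == 0 or total <= 0:
        return Prediction(str(uid), str(smid), float("nan"), 0, "undefined")
    value = float(np.dot(sims, rates) / total)
    return Prediction(str(uid), str(smid), value, len(neighbors), "pattern_cf")


def knn_fallback(uid, smid, Z: np.ndarray, matrix: RatingMatrix, k_nn: int = 5) -> Prediction:
    """Feature-space k-NN imputation: mean rating of the nearest raters.

    Neighbors are the ``k_nn`` users closest to ``uid`` in normalized
    feature space among those (from any pattern) who rated ``smid``.  If
    nobody rated it, the global mean rating is returned; on an empty
    matrix, the 3.0 midpoint prior.  Always defined — this is the
    cold-start guarantee.
    """
    i = matrix.uid_index(uid)
    j = matrix.smid_index(smid)
    raters = np.flatnonzero(~np.isnan(matrix.raw[:, j]))
    raters = raters[raters != i]
    if raters.size == 0:
        observed = matrix.raw[matrix.mask]
        if observed.size == 0:
            return Prediction(str(uid), str(smid), EMPTY_MATRIX_PRIOR, 0, "knn_fallback")
        return Prediction(str(uid), str(smid), float(observed.mean()), 0, "knn_fallback")
    dists = np.linalg.norm(Z[raters] - Z[i], axis=1)
    order = np.argsort(dists, kind="stable")[:k_nn]
    chosen = raters[order]
    value = float(matrix.raw[chosen, j].mean())
    return Prediction(str(uid), str(smid), value, int(chosen.size), "knn_fallback")


def combine_cf_cbf(p_cf: Prediction, p_cbf: Prediction) -> Prediction:
    """Unweighted mean of a CF and a CBF prediction."""
    value = float((p_cf.r_predict + p_cbf.r_predict) / 2.0)
    return Prediction(p_cf.uid, p_cf.smid, value, p_cf.support + p_cbf.support, "combo")


def _rank_entries(predictions: list[Prediction], smid_order: dict) -> list:
    """Sort by predicted rating descending; ties by catalogue order."""
    ranked = sorted(predictions, key=lambda p: (-p.r_predict, smid_order[p.smid]))
    return [(p.smid, p.r_predict) for p in ranked]


class _BaseRecommender(BaseEstimator):
    """Shared fit plumbing: features, clusterer, rating matrix."""

    def _fit_common(self, X, R, fit_clusterer: bool):
        if isinstance(R, RatingMatrix):
            matrix = R.copy()
        else:
            R = np.asarray(R, dtype=float)
            matrix = RatingMatrix(
                [f"U{i + 1:04d}" for i in range(R.shape[0])],
                [f"SM{j + 1}" for j in range(R.shape[1])],
                R.copy(),
            )
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(matrix.uids):
            raise ValueError("feature matrix and rating matrix disagree on user count")
        clusterer = getattr(self, "clusterer", None)
        if fit_clusterer:
            if clusterer is None:
                clusterer = SleepPatternClusterer(random_state=getattr(self, "random_state", None))
                clusterer.fit(X)
            elif not hasattr(clusterer, "centroids_"):
                clusterer.fit(X)
            self.clusterer_ = clusterer
            self.labels_ = clusterer.predict(X)
            self.Z_ = clusterer.normalize_features(X)
        else:
            self.clusterer_ = None
            self.labels_ = np.zeros(X.shape[0], dtype=int)
            self.Z_ = X
        self.matrix_ = matrix
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "matrix_"):
            raise AttributeError(f"{type(self).__name__} is not fitted yet")

    def predict_pair(self, uid, smid) -> Prediction:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, pairs) -> np.ndarray:
        """Predicted ratings (clipped to [1, 5]) for an iterable of (uid, smid)."""
        self._check_fitted()
        out = np.array([self.predict_pair(u, s).r_predict for u, s in pairs], dtype=float)
        return np.clip(out, 1.0, 5.0)

    def recommend(self, uid, n: int, exclude=None) -> RecommendationList:
        """Top-n unrated patterns for ``uid`` by predicted rating."""
        self._check_fitted()
        if n <= 0:
            raise ValueError("n must be positive")
        exclude = set() if exclude is None else {str(s) for s in exclude}
        candidates = [s for s in self.matrix_.unrated_smids(uid) if s not in exclude]
        preds = [self.predict_pair(uid, s) for s in candidates]
        order = {s: j for j, s in enumerate(self.matrix_.smids)}
        return RecommendationList(str(uid), _rank_entries(preds, order)[:n], n)


class PatternCFRecommender(_BaseRecommender):
    """Within-pattern user-based CF with feedback and a k-NN fallback.

    The hybrid engine: neighbors are restricted to users assigned the
    same sleep-pattern label, weighted by co-rated cosine similarity;
    undefined predictions fall through to feature-space k-NN, so every
    user — including one with zero ratings — gets a full recommendation
    list.  Feedback ratings are folded back into the matrix (and the
    user's profile) via :meth:`add_rating`.

    Parameters
    ----------
    clusterer : fitted or unfitted SleepPatternClusterer, optional
        Pattern model; fitted on the training features when absent.
    tau : float
        Similarity threshold; neighbors below it are dropped.  The
        default 0.0 keeps only non-negatively similar users.
    max_neighbors : int or None
        Cap on the neighbor list.
    k_nn : int
        Fallback neighborhood size in feature space.
    """

    def __init__(self, clusterer=None, tau=0.0, max_neighbors=None, k_nn=5, random_state=None):
        self.clusterer = clusterer
        self.tau = tau
        self.max_neighbors = max_neighbors
        self.k_nn = k_nn
        self.random_state = random_state

    def fit(self, X, R, profiles: list[UserProfile] | None = None):
        self._fit_common(X, R, fit_clusterer=True)
        self.profiles_ = {p.uid: p for p in profiles} if profiles else {}
        for uid, label in zip(self.matrix_.uids, self.labels_):
            if uid in self.profiles_:
                self.profiles_[uid].pattern_label = int(label)
        self._nbr_cache: dict = {}
        return self

    def neighbor_set(self, uid) -> list[SimilarityResult]:
        self._check_fitted()
        # memoised per user against the matrix write counter: a recommend
        # call predicts several items for one user on an unchanged matrix
        key = str(uid)
        cached = self._nbr_cache.get(key)
        if cached is not None and cached[0] == self.matrix_.version:
            return cached[1]
        nbrs = neighbor_set(uid, self.matrix_, self.labels_, tau=self.tau,
                            max_neighbors=self.max_neighbors)
        self._nbr_cache[key] = (self.matrix_.version, nbrs)
        return nbrs

    def predict_pair(self, uid, smid) -> Prediction:
        self._check_fitted()
        j = self.matrix_.smid_index(smid)
        nbrs = [nb for nb in self.neighbor_set(uid)
                if not np.isnan(self.matrix_.raw[self.matrix_.uid_index(nb.uid_b), j])]
        pred = predict_rating(uid, smid, nbrs, self.matrix_)
        if not pred.defined:
            pred = knn_fallback(uid, smid, self.Z_, self.matrix_, k_nn=self.k_nn)
        return pred

    def add_rating(self, uid, smid, rating) -> None:
        """Fold a feedback rating into the matrix and the user's profile."""
        self._check_fitted()
        self.matrix_.set(uid, smid, rating)
        if uid in self.profiles_:
            reconstruct_profile(self.profiles_[uid], smid, rating)

    def refit_patterns(self, X=None) -> None:
        """Refit the pattern model (features are unchanged by feedback, so
        this is a hook for pipelines where profiles do evolve)."""
        self._check_fitted()
        if X is None:
            return
        self.clusterer_.fit(X)
        self.labels_ = self.clusterer_.predict(X)


class GlobalCFRecommender(_BaseRecommender):
    """Unrestricted user-based CF baseline (no pattern gating, no feedback).

    Same weighted-average formula as the hybrid engine, but neighbors are
    drawn from the whole population.  Undefined predictions fall back to
    the item mean, then the global mean, then the 3.0 prior (a rating
    must always be produced for scoring); there is no feature-space k-NN
    branch here.
    """

    def __init__(self, tau=0.0, max_neighbors=None):
        self.tau = tau
        self.max_neighbors = max_neighbors

    def fit(self, X, R):
        return self._fit_common(X, R, fit_clusterer=False)

    def predict_pair(self, uid, smid) -> Prediction:
        self._check_fitted()
        j = self.matrix_.smid_index(smid)
        nbrs = neighbor_set(uid, self.matrix_, self.labels_, tau=self.tau,
                            max_neighbors=self.max_neighbors)
        nbrs = [nb for nb in nbrs
                if not np.isnan(self.matrix_.raw[self.matrix_.uid_index(nb.uid_b), j])]
        pred = predict_rating(uid, smid, nbrs, self.matrix_)
        if pred.defined:
            return Prediction(pred.uid, pred.smid, pred.r_predict, pred.support, "cf_global")
        col = self.matrix_.raw[:, j]
        col = col[~np.isnan(col)]
        if col.size:
            return Prediction(str(uid), str(smid), float(col.mean()), int(col.size), "item_mean")
        observed = self.matrix_.raw[self.matrix_.mask]
        value = float(observed.mean()) if observed.size else EMPTY_MATRIX_PRIOR
        return Prediction(str(uid), str(smid), value, 0, "global_mean")


class ContentRecommender(_BaseRecommender):
    """Content-based baseline: rating as a linear function of distance.

    Predicts r_hat = clip(5 - beta * dist(z_u, c_j), 1, 5) where c_j is
    the pattern's position in normalized feature space and beta is
    calibrated by least squares on the observed training ratings.  When
    ``item_centroids`` is not supplied, each pattern's position is
    estimated from the data as the positive-part rating-weighted mean of
    its raters' features (users who liked a pattern sit near its center).
    """

    def __init__(self, clusterer=None, item_centroids=None):
        self.clusterer = clusterer
        self.item_centroids = item_centroids

    def fit(self, X, R):
        self._fit_common(X, R, fit_clusterer=self.clusterer is not None)
        if self.clusterer_ is None:
            from .profiles import FeatureNormalizer

            norm = FeatureNormalizer().fit(np.asarray(X, dtype=float))
            self.Z_ = norm.transform(X)
            self._norm = norm
        if self.item_centroids is not None:
            self.item_centroids_ = np.asarray(self.item_centroids, dtype=float)
        else:
            self.item_centroids_ = self._estimate_item_centroids()
        self.beta_ = self._calibrate_beta()
        return self

    def _estimate_item_centroids(self) -> np.ndarray:
        raw = self.matrix_.raw
        centers = np.zeros((len(self.matrix_.smids), self.Z_.shape[1]))
        pop_mean = self.Z_.mean(axis=0)
        for j in range(raw.shape[1]):
            rated = ~np.isnan(raw[:, j])
            w = np.maximum(raw[rated, j] - 3.0, 0.0)
            if w.sum() > 0:
                centers[j] = np.average(self.Z_[rated], axis=0, weights=w)
            elif rated.any():
                centers[j] = self.Z_[rated].mean(axis=0)
            else:
                centers[j] = pop_mean
        return centers

    def _calibrate_beta(self) -> float:
        # least squares on  5 - r = beta * d  through the origin
        rows, cols = np.nonzero(self.matrix_.mask)
        if rows.size == 0:
            return 0.0
        d = np.linalg.norm(self.Z_[rows] - self.item_centroids_[cols], axis=1)
        r = self.matrix_.raw[rows, cols]
        denom = float(np.dot(d, d))
        return float(np.dot(d, 5.0 - r) / denom) if denom > 0 else 0.0

    def predict_pair(self, uid, smid) -> Prediction:
        self._check_fitted()
        i = self.matrix_.uid_index(uid)
        j = self.matrix_.smid_index(smid)
        d = float(np.linalg.norm(self.Z_[i] - self.item_centroids_[j]))
        value = float(np.clip(5.0 - self.beta_ * d, 1.0, 5.0))
        return Prediction(str(uid), str(smid), value, 0, "cbf")


class CombinedRecommender(_BaseRecommender):
    """Unweighted mean of the global-CF and content-based baselines."""

    def __init__(self, cf: GlobalCFRecommender | None = None,
                 cbf: ContentRecommender | None = None):
        self.cf = cf
        self.cbf = cbf

    def fit(self, X, R):
        self.cf_ = self.cf if self.cf is not None and hasattr(self.cf, "matrix_") \
            else (self.cf or GlobalCFRecommender()).fit(X, R)
        self.cbf_ = self.cbf if self.cbf is not None and hasattr(self.cbf, "matrix_") \
            else (self.cbf or ContentRecommender()).fit(X, R)
        self.matrix_ = self.cf_.matrix_
        return self

    def predict_pair(self, uid, smid) -> Prediction:
        self._check_fitted()
        return combine_cf_cbf(self.cf_.predict_pair(uid, smid),
                              self.cbf_.predict_pair(uid, smid))


# ---------------------------------------------------------------------------
# feedback loop


def top_n(uid, n, recommender: _BaseRecommender, exclude=None) -> RecommendationList:
    """Functional wrapper over :meth:`recommend`."""
    return recommender.recommend(uid, n, exclude=exclude)


def hybrid_round(recommender: PatternCFRecommender, uid, n, feedback_fn,
                 exclude=None) -> RecommendationList:
    """One feedback loop for one user.

    Recommends top-n unrated patterns, solicits a rating of the top entry
    via ``feedback_fn(uid, smid) -> int`` and folds it back into the
    rating matrix and profile.  An empty recommendation list (everything
    rated) is returned as-is.
    """
    recs = recommender.recommend(uid, n, exclude=exclude)
    if recs.entries:
        smid = recs.entries[0][0]
        rating = feedback_fn(uid, smid)
        recommender.add_rating(uid, smid, rating)
    return recs


def run_feedback_loop(recommender: PatternCFRecommender, feedback_fn, rounds: int,
                      n: int = 1, refit_every: int = 10, exclude=None,
                      callback=None) -> list:
    """Run feedback rounds over every user.

    ``exclude`` maps uid -> set of smids never to solicit feedback on
    (used by the evaluation harness to keep held-out pairs untouched).
    ``callback(recommender)`` is evaluated before the first round and
    after each round; its values are returned as the loop history.
    """
    history = []
    if callback is not None:
        history.append(callback(recommender))
    exclude = exclude or {}
    for r in range(1, rounds + 1):
        for uid in recommender.matrix_.uids:
            hybrid_round(recommender, uid, n, feedback_fn, exclude=exclude.get(uid))
        if refit_every and r % refit_every == 0:
            recommender.refit_patterns()
        if callback is not None:
            history.append(callback(recommender))
    return history
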