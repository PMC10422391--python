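"""Prediction, fallback, top-N ranking and the feedback loop."""

import numpy as np
import pytest

from sleeprec.clustering import SleepPatternClusterer
from sleeprec.ratings import RatingMatrix, SimilarityResult
from sleeprec.recommend import (
    CombinedRecommender,
    ContentRecommender,
    GlobalCFRecommender,
    PatternCFRecommender,
    combine_cf_cbf,
    hybrid_round,
    knn_fallback,
    predict_rating,
    run_feedback_loop,
)

from conftest import random_rating_matrix


def _nbrs(uid, sims_by_uid):
    return [SimilarityResult(uid, b, s, 1) for b, s in sims_by_uid.items()]


class TestPredictRating:
    def _matrix(self, ratings_by_uid, smid="SM1"):
        uids = list(ratings_by_uid)
        raw = np.array([[ratings_by_uid[u]] for u in uids], dtype=float)
        return RatingMatrix(uids, [smid], raw)

    def test_equal_weights_give_plain_mean(self):
        m = self._matrix({"u": np.nan, "a": 4, "b": 2})
        p = predict_rating("u", "SM1", _nbrs("u", {"a": 1.0, "b": 1.0}), m)
        assert p.r_predict == pytest.approx(3.0)

    def test_single_neighbor_weight_cancels(self):
        m = self._matrix({"u": np.nan, "a": 5})
        p = predict_rating("u", "SM1", _nbrs("u", {"a": 0.5}), m)
        assert p.r_predict == pytest.approx(5.0)

    def test_weighted_average_example(self):
        # (0.8 * 5 + 0.2 * 1) / 1.0 = 4.2
        m = self._matrix({"u": np.nan, "a": 5, "b": 1})
        p = predict_rating("u", "SM1", _nbrs("u", {"a": 0.8, "b": 0.2}), m)
        assert p.r_predict == pytest.approx(4.2)
        assert p.method == "pattern_cf"

    def test_no_neighbors_is_undefined(self):
        m = self._matrix({"u": np.nan})
        p = predict_rating("u", "SM1", [], m)
        assert not p.defined and p.method == "undefined"

    def test_zero_similarity_mass_is_undefined(self):
        m = self._matrix({"u": np.nan, "a": 4})
        p = predict_rating("u", "SM1", _nbrs("u", {"a": 0.0}), m)
        assert not p.defined

    def test_neighbor_without_rating_violates_contract(self):
        m = self._matrix({"u": np.nan, "a": np.nan})
        with pytest.raises(ValueError, match="has not rated"):
            predict_rating("u", "SM1", _nbrs("u", {"a": 0.9}), m)

    def test_convex_combination_under_positive_sims(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            sims = rng.uniform(0.01, 1.0, size=k)
            rates = rng.integers(1, 6, size=k).astype(float)
            uids = ["u"] + [f"n{i}" for i in range(k)]
            raw = np.array([[np.nan]] + [[r] for r in rates])
            m = RatingMatrix(uids, ["SM1"], raw)
            nbrs = [SimilarityResult("u", f"n{i}", sims[i], 1) for i in range(k)]
            p = predict_rating("u", "SM1", nbrs, m)
            assert rates.min() - 1e-12 <= p.r_predict <= rates.max() + 1e-12


class TestKnnFallback:
    def test_single_rater_is_the_prediction(self):
        m = RatingMatrix(["u", "a"], ["SM1"], np.array([[np.nan], [4.0]]))
        Z = np.zeros((2, 5))
        assert knn_fallback("u", "SM1", Z, m).r_predict == pytest.approx(4.0)

    def test_empty_matrix_returns_midpoint_prior(self):
        m = RatingMatrix(["u", "a"], ["SM1"])
        p = knn_fallback("u", "SM1", np.zeros((2, 5)), m)
        assert p.r_predict == pytest.approx(3.0)

    def test_matches_brute_force_feature_sort(self, rng):
        for _ in range(25):
            n = 10
            Z = rng.normal(size=(n, 5))
            raw = rng.integers(1, 6, size=(n, 1)).astype(float)
            raw[0, 0] = np.nan
            miss = rng.random(n) < 0.3
            raw[miss, 0] = np.nan
            uids = [f"U{i}" for i in range(n)]
            m = RatingMatrix(uids, ["SM1"], raw)
            p = knn_fallback("U0", "SM1", Z, m, k_nn=3)
            raters = [i for i in range(1, n) if not np.isnan(raw[i, 0])]
            if not raters:
                observed = raw[~np.isnan(raw)]
                expected = observed.mean() if observed.size else 3.0
            else:
                # stable sort by distance preserves index order among ties
                ranked = sorted(raters, key=lambda i: np.linalg.norm(Z[i] - Z[0]))
                expected = np.mean([raw[i, 0] for i in ranked[:3]])
            assert p.r_predict == pytest.approx(expected)


class TestTopN:
    @pytest.fixture
    def engine(self, small_dataset):
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        rec = PatternCFRecommender(clusterer=clusterer)
        return rec.fit(small_dataset.features, small_dataset.ratings)

    def test_entries_sorted_descending_and_truncated(self, engine):
        uid = engine.matrix_.uids[0]
        full = engine.recommend(uid, len(engine.matrix_.smids))
        values = [r for _, r in full.entries]
        assert values == sorted(values, reverse=True)
        top2 = engine.recommend(uid, 2)
        assert top2.entries == full.entries[:2]

    def test_everything_rated_yields_empty_list(self, engine):
        uid = engine.matrix_.uids[0]
        for smid in engine.matrix_.unrated_smids(uid):
            engine.add_rating(uid, smid, 3)
        assert engine.recommend(uid, 3).entries == []

    def test_ties_break_by_catalogue_order(self):
        # a fresh user with an empty matrix: every prediction is the 3.0
        # prior, so the ranking must follow SM1, SM2, SM3
        m = RatingMatrix(["u", "v"], ["SM1", "SM2", "SM3"])
        X = np.vstack([np.arange(5), np.arange(5) + 1]).astype(float)
        clusterer = SleepPatternClusterer(k=2, normalize=False, random_state=0).fit(X)
        rec = PatternCFRecommender(clusterer=clusterer).fit(X, m)
        recs = rec.recommend("u", 3)
        assert [s for s, _ in recs.entries] == ["SM1", "SM2", "SM3"]

    def test_nonpositive_n_rejected(self, engine):
        with pytest.raises(ValueError, match="positive"):
            engine.recommend(engine.matrix_.uids[0], 0)

    def test_cold_start_user_gets_full_list(self, small_dataset):
        # wipe one user's ratings entirely: the k-NN fallback must still
        # produce a full-length, defined recommendation list
        matrix = small_dataset.ratings.copy()
        i = 4
        matrix.raw[i, :] = np.nan
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        rec = PatternCFRecommender(clusterer=clusterer).fit(small_dataset.features, matrix)
        recs = rec.recommend(matrix.uids[i], 3)
        assert len(recs.entries) == 3
        assert all(np.isfinite(r) and 1 <= r <= 5 for _, r in recs.entries)


class TestBaselines:
    def test_global_cf_equals_pattern_cf_with_one_cluster(self, small_dataset, rng):
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        pat = PatternCFRecommender(clusterer=clusterer).fit(
            small_dataset.features, small_dataset.ratings)
        pat.labels_ = np.zeros(len(pat.matrix_.uids), dtype=int)  # vacuous restriction
        pat._nbr_cache.clear()
        glob = GlobalCFRecommender().fit(small_dataset.features, small_dataset.ratings)
        for _ in range(20):
            i = int(rng.integers(len(pat.matrix_.uids)))
            uid = pat.matrix_.uids[i]
            smid = rng.choice(pat.matrix_.smids)
            a = pat.predict_pair(uid, smid)
            b = glob.predict_pair(uid, smid)
            if a.method == "pattern_cf" and b.method == "cf_global":
                assert a.r_predict == pytest.approx(b.r_predict, abs=1e-12)

    def test_global_cf_mean_example(self):
        raw = np.array([[np.nan, 5, 5], [2, 5, 5], [4, 1, 1]], dtype=float)
        m = RatingMatrix(["u", "a", "b"], ["SM1", "SM2", "SM3"], raw)
        glob = GlobalCFRecommender().fit(np.zeros((3, 5)), m)
        p = glob.predict_pair("u", "SM1")
        # u's normalized vector (1,1) has sim 1.0 with a and -1.0 with b;
        # only a passes tau=0, so the prediction is a's rating
        assert p.r_predict == pytest.approx(2.0)

    def test_cbf_beta_recovery_from_noiseless_linear_ratings(self):
        # users at graded distances from a known pattern center, rated by
        # the exact linear law 5 - beta * d with beta = sqrt(2/5)
        v = np.repeat(np.arange(5, dtype=float), 4)
        X = np.tile(v[:, None], (1, 5))
        X += np.arange(5) * 100  # distinct column offsets, same spread
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Z = (X - mu) / sd
        center = Z[np.argmax(v)]
        beta_true = np.sqrt(2.0 / 5.0)
        d = np.linalg.norm(Z - center, axis=1)
        ratings = 5.0 - beta_true * d
        assert np.allclose(ratings, np.rint(ratings))  # integers by design
        m = RatingMatrix([f"U{i}" for i in range(20)], ["SM1"], ratings[:, None])
        cbf = ContentRecommender(item_centroids=center[None, :]).fit(X, m)
        assert cbf.beta_ == pytest.approx(beta_true, rel=0.05)
        # user at the pattern centroid predicts the 5.0 ceiling
        at_center = int(np.argmax(v))
        assert cbf.predict_pair(f"U{at_center}", "SM1").r_predict == pytest.approx(5.0)

    def test_combined_prediction_is_the_mean(self):
        from sleeprec.recommend import Prediction

        p = combine_cf_cbf(Prediction("u", "SM1", 4.0, 2, "cf_global"),
                           Prediction("u", "SM1", 2.0, 0, "cbf"))
        assert p.r_predict == pytest.approx(3.0)
        assert p.method == "combo"

    def test_all_predictions_clipped_to_rating_scale(self, small_dataset, rng):
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        for model in (
            PatternCFRecommender(clusterer=clusterer).fit(small_dataset.features,
                                                          small_dataset.ratings),
            GlobalCFRecommender().fit(small_dataset.features, small_dataset.ratings),
            ContentRecommender(clusterer=clusterer).fit(small_dataset.features,
                                                        small_dataset.ratings),
        ):
            pairs = [(u, s) for u in small_dataset.uids[:10]
                     for s in small_dataset.ratings.smids]
            out = model.predict(pairs)
            assert np.all((out >= 1.0) & (out <= 5.0))


class TestFeedbackLoop:
    def test_round_updates_matrix_and_excludes_item(self, small_dataset):
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        rec = PatternCFRecommender(clusterer=clusterer).fit(
            small_dataset.features, small_dataset.ratings.copy())
        uid = next(u for u in rec.matrix_.uids if rec.matrix_.unrated_smids(u))
        recs = hybrid_round(rec, uid, 1, lambda u, s: 4)
        smid = recs.entries[0][0]
        assert rec.matrix_.get(uid, smid) == 4.0
        later = rec.recommend(uid, len(rec.matrix_.smids))
        assert smid not in [s for s, _ in later.entries]

    def test_loop_densifies_and_reports_history(self, small_dataset):
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(small_dataset.features)
        rec = PatternCFRecommender(clusterer=clusterer).fit(
            small_dataset.features, small_dataset.ratings.copy())
        before = rec.matrix_.n_observed

        history = run_feedback_loop(
            rec, lambda u, s: 5, rounds=2,
            callback=lambda r: r.matrix_.n_observed)
        assert len(history) == 3
        assert history[-1] >= history[0] > 0
        assert rec.matrix_.n_observed > before

    def test_profiles_receive_feedback(self, small_dataset):
        from sleeprec.profiles import build_profiles

        profiles, X, _ = build_profiles(small_dataset.records,
                                        small_dataset.demographics)
        clusterer = SleepPatternClusterer(k=3, random_state=0).fit(X)
        rec = PatternCFRecommender(clusterer=clusterer).fit(
            X, small_dataset.ratings.copy(), profiles=profiles)
        uid = next(u for u in rec.matrix_.uids if rec.matrix_.unrated_smids(u))
        hybrid_round(rec, uid, 1, lambda u, s: 2)
        prof = rec.profiles_[uid]
        assert prof.feedback_round == 1 and 2 in prof.ratings.values()
        assert prof.pattern_label is not None
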