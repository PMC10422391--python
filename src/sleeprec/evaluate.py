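"""Evaluation harness: MSE / MAPE and the four-model comparison.

Runs the full pipeline on a synthetic cohort — generate, split the
observed ratings 80/20 per user, cluster, fit each recommender, predict
the held-out ratings — and scores every model with mean squared error
and mean absolute percentage error.  Accuracy is additionally reported
as 100 - MAPE, since a percentage-error metric is often quoted as its
complement.

Models compared:

``cf``      global user-based collaborative filtering (no pattern gating)
``cbf``     content-based: linear in user-to-pattern feature distance
``cf+cbf``  unweighted mean of the two baselines
``hybrid``  within-pattern CF with simulated feedback rounds and the
            feature-space k-NN cold-start fallback
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .clustering import SleepPatternClusterer
from .recommend import (
    CombinedRecommender,
    ContentRecommender,
    GlobalCFRecommender,
    PatternCFRecommender,
    run_feedback_loop,
)
from .synthetic import SyntheticConfig, generate_dataset, simulate_feedback

MODELS = ("cf", "cbf", "cf+cbf", "hybrid")


def mse(actual, predicted) -> float:
    """Mean squared error (1/n) * sum (d_i - dhat_i)^2."""
    a, p = _check_pair(actual, predicted)
    return float(np.mean((a - p) ** 2))


def mape(actual, predicted) -> float:
    """Mean absolute percentage error (100/n) * sum |d_i - dhat_i| / d_i.

    Undefined when any actual value is zero (the percentage denominator
    vanishes); ratings are >= 1 so this never triggers in normal use.
    """
    a, p = _check_pair(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE is undefined when an actual value is zero")
    return float(100.0 * np.mean(np.abs((a - p) / a)))


def _check_pair(actual, predicted):
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size == 0 or a.size != p.size:
        raise ValueError("actual and predicted must be nonempty and of equal length")
    return a, p


@dataclass(frozen=True)
class EvaluationReport:
    """Per-model held-out error summary."""

    model: str
    mse: float
    mape: float
    accuracy: float  # 100 - mape
    n_test: int
    seed: int
    config_digest: str

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mse": self.mse,
            "mape": self.mape,
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "seed": self.seed,
            "config_digest": self.config_digest,
        }


def config_digest(config: SyntheticConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def split_ratings(matrix, test_fraction: float = 0.2, rng=None):
    """Per-user 80/20 split of the observed ratings.

    Each user's observed entries are split independently (seeded); users
    with fewer than two ratings contribute to training only.  Returns
    ``(train_matrix, test_triples)`` with test triples (uid, smid, rating).
    """
    rng = np.random.default_rng(rng)
    train = matrix.copy()
    test = []
    for i, uid in enumerate(matrix.uids):
        observed = np.flatnonzero(matrix.mask[i])
        if observed.size < 2:
            continue
        n_test = min(max(1, int(round(test_fraction * observed.size))), observed.size - 1)
        chosen = rng.choice(observed, size=n_test, replace=False)
        for j in chosen:
            test.append((uid, matrix.smids[j], float(matrix.raw[i, j])))
            train.raw[i, j] = np.nan
    train.version += 1
    return train, test


def _fit_models(ds, train, clusterer, *, feedback_rounds, tau, k_nn, refit_every,
                rng_feedback, exclude):
    """Fit the four recommenders on the training fold."""
    cf = GlobalCFRecommender(tau=tau).fit(ds.features, train)
    cbf = ContentRecommender(clusterer=clusterer).fit(ds.features, train)
    combo = CombinedRecommender(cf=cf, cbf=cbf).fit(ds.features, train)
    hybrid = PatternCFRecommender(clusterer=clusterer, tau=tau, k_nn=k_nn).fit(
        ds.features, train
    )

    def feedback(uid, smid):
        j = train.smid_index(smid)
        i = train.uid_index(uid)
        return simulate_feedback(ds.Z[i], ds.centroids_norm[j], ds.config, rng_feedback)

    if feedback_rounds > 0:
        run_feedback_loop(hybrid, feedback, rounds=feedback_rounds,
                          refit_every=refit_every, exclude=exclude)
    return {"cf": cf, "cbf": cbf, "cf+cbf": combo, "hybrid": hybrid}


def _score(model, test):
    pairs = [(u, s) for u, s, _ in test]
    actual = np.array([r for _, _, r in test])
    predicted = model.predict(pairs)
    return mse(actual, predicted), mape(actual, predicted)


def run_experiment(config: SyntheticConfig, seed: int, *, feedback_rounds: int = 10,
                   k="auto", tau: float = 0.0, k_nn: int = 5,
                   test_fraction: float = 0.2, refit_every: int = 10,
                   ) -> list[EvaluationReport]:
    """End-to-end comparison of the four models on one synthetic cohort.

    Generates data under ``config`` with the given seed, splits the
    observed ratings 80/20 per user, fits the pattern model, runs
    ``feedback_rounds`` simulated feedback sweeps for the hybrid engine
    (never soliciting feedback on held-out pairs), and reports held-out
    MSE / MAPE for every model.
    """
    cfg = replace(config, seed=int(seed))
    ss = np.random.SeedSequence(int(seed))
    rng_data, rng_split, rng_feedback = (np.random.default_rng(s) for s in ss.spawn(3))
    ds = generate_dataset(cfg, rng=rng_data)
    if ds.ratings is None or ds.ratings.n_observed == 0:
        raise ValueError("configuration yields no observed ratings to evaluate")
    train, test = split_ratings(ds.ratings, test_fraction=test_fraction, rng=rng_split)
    if not test:
        raise ValueError("empty test fold; increase n_users or rating density")
    clusterer = SleepPatternClusterer(k=k, random_state=int(seed)).fit(ds.features)
    exclude = {}
    for uid, smid, _ in test:
        exclude.setdefault(uid, set()).add(smid)
    models = _fit_models(ds, train, clusterer, feedback_rounds=feedback_rounds,
                         tau=tau, k_nn=k_nn, refit_every=refit_every,
                         rng_feedback=rng_feedback, exclude=exclude)
    digest = config_digest(cfg)
    reports = []
    for name in MODELS:
        m, p = _score(models[name], test)
        reports.append(EvaluationReport(name, m, p, 100.0 - p, len(test), int(seed), digest))
    return reports


def feedback_mape_trajectory(config: SyntheticConfig, seed: int, rounds: int = 20, *,
                             k="auto", tau: float = 0.0, k_nn: int = 5,
                             test_fraction: float = 0.2) -> np.ndarray:
    """Held-out MAPE of the hybrid engine after each feedback round.

    Element 0 is the pre-feedback baseline; element r the MAPE after
    round r.  Used to check that accumulating feedback does not degrade
    recommendations.
    """
    cfg = replace(config, seed=int(seed))
    ss = np.random.SeedSequence(int(seed))
    rng_data, rng_split, rng_feedback = (np.random.default_rng(s) for s in ss.spawn(3))
    ds = generate_dataset(cfg, rng=rng_data)
    train, test = split_ratings(ds.ratings, test_fraction=test_fraction, rng=rng_split)
    clusterer = SleepPatternClusterer(k=k, random_state=int(seed)).fit(ds.features)
    hybrid = PatternCFRecommender(clusterer=clusterer, tau=tau, k_nn=k_nn).fit(ds.features, train)
    exclude = {}
    for uid, smid, _ in test:
        exclude.setdefault(uid, set()).add(smid)

    def feedback(uid, smid):
        return simulate_feedback(ds.Z[train.uid_index(uid)],
                                 ds.centroids_norm[train.smid_index(smid)],
                                 ds.config, rng_feedback)

    def score(model):
        return _score(model, test)[1]

    history = run_feedback_loop(hybrid, feedback, rounds=rounds, refit_every=0,
                                exclude=exclude, callback=score)
    return np.asarray(history)


def reports_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Pivot a report list into a metrics x models table."""
    frame = pd.DataFrame([r.to_dict() for r in reports])
    table = frame.pivot_table(index=None, values=["mse", "mape"], columns="model",
                              aggfunc="median")
    cols = [m for m in MODELS if m in table.columns]
    return table.loc[["mse", "mape"], cols]


def reports_to_json(reports: list[EvaluationReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"schema_version": 1, "reports": [r.to_dict() for r in reports]},
                  fh, indent=1)
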