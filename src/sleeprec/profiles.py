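"""User profiles built from nightly motion-bed records.

A profile summarises one sleeper as a five-dimensional feature vector —
the per-night means of sleep time (h), movement events, ambient sound (dB)
and snoring index, plus the body-mass index (kg/m^2) from intake data —
together with demographics and the ratings the user has given to
recommended sleep patterns.  Feedback updates touch the rating history
only; the sensor-derived feature vector is never altered by feedback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: order of the profile feature vector
FEATURE_NAMES = ("sleep_time", "moving", "sound", "snoring", "bmi")

#: columns a nightly sensor record must carry (BMI comes from demographics)
RECORD_COLUMNS = ("sleep_time", "moving", "sound", "snoring")

RATING_MIN = 1
RATING_MAX = 5


@dataclass
class UserProfile:
    """One user's aggregated sleep features, demographics and rating history."""

    uid: str
    bmi: float
    features: np.ndarray
    birth: int | None = None
    gender: str | None = None
    pattern_label: int | None = None
    ratings: dict[str, int] = field(default_factory=dict)
    feedback_round: int = 0

    def to_dict(self) -> dict:
        return {
            "uid": self.uid,
            "bmi": float(self.bmi),
            "birth": self.birth,
            "gender": self.gender,
            "features": [float(x) for x in self.features],
            "pattern_label": None if self.pattern_label is None else int(self.pattern_label),
            "ratings": {k: int(v) for k, v in self.ratings.items()},
            "feedback_round": int(self.feedback_round),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserProfile":
        return cls(
            uid=d["uid"],
            bmi=d["bmi"],
            features=np.asarray(d["features"], dtype=float),
            birth=d.get("birth"),
            gender=d.get("gender"),
            pattern_label=d.get("pattern_label"),
            ratings=dict(d.get("ratings", {})),
            feedback_round=int(d.get("feedback_round", 0)),
        )


def build_profile(records: pd.DataFrame, demographics) -> UserProfile:
    """Aggregate one user's nightly records into a profile.

    Parameters
    ----------
    records : DataFrame
        Nightly rows for a single user with columns ``uid`` and
        ``sleep_time, moving, sound, snoring``.
    demographics : mapping
        Must provide ``bmi``; ``birth`` / ``gender`` are optional.

    The feature vector is the arithmetic mean over nights of the four
    sensor measurements, with BMI appended as the fifth coordinate.
    """
    if len(records) == 0:
        raise ValueError("build_profile requires at least one sleep record")
    values = records.loc[:, list(RECORD_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("sleep records contain non-finite measurements")
    bmi = float(demographics["bmi"])
    if not np.isfinite(bmi):
        raise ValueError("BMI must be finite")
    uid = str(records["uid"].iloc[0]) if "uid" in records.columns else str(demographics.get("uid"))
    features = np.append(values.mean(axis=0), bmi)
    birth = demographics.get("birth") if hasattr(demographics, "get") else None
    gender = demographics.get("gender") if hasattr(demographics, "get") else None
    return UserProfile(
        uid=uid,
        bmi=bmi,
        features=features,
        birth=None if birth is None or (isinstance(birth, float) and np.isnan(birth)) else int(birth),
        gender=gender,
    )


def build_profiles(records: pd.DataFrame, demographics: pd.DataFrame):
    """Build profiles for every user in a nightly record table.

    Returns ``(profiles, feature_matrix, uids)`` with rows of the matrix
    aligned to the uid order of ``demographics``.
    """
    demo = demographics.set_index("uid", drop=False)
    profiles: list[UserProfile] = []
    grouped = dict(tuple(records.groupby("uid"))) if len(records) else {}
    for uid in demo.index:
        if uid not in grouped:
            raise ValueError(f"no sleep records for user {uid!r}")
        profiles.append(build_profile(grouped[uid], demo.loc[uid]))
    uids = [p.uid for p in profiles]
    X = np.vstack([p.features for p in profiles]) if profiles else np.empty((0, 5))
    return profiles, X, uids


class FeatureNormalizer(BaseEstimator, TransformerMixin):
    """Z-score feature normalization with population (ddof=0) scaling.

    Puts the heterogeneous sensor units (hours, events, dB, index, kg/m^2)
    on a common scale so Euclidean distances weight features comparably.
    A constant feature has no meaningful scale and is rejected by name.
    """

    def __init__(self, feature_names=None):
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("normalization requires a 2-D array with >= 2 rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        names = self.feature_names or FEATURE_NAMES
        for j, s in enumerate(self.scale_):
            if s <= 0:
                name = names[j] if j < len(names) else f"feature {j}"
                raise ValueError(f"degenerate constant feature: {name!r} has zero spread")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) / self.scale_

    def inverse_transform(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return Z * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        norm = cls()
        norm.mean_ = np.asarray(d["mean"], dtype=float)
        norm.scale_ = np.asarray(d["scale"], dtype=float)
        norm.n_features_in_ = norm.mean_.size
        return norm


def fit_normalization(profiles_or_X) -> FeatureNormalizer:
    """Fit z-score parameters on a population of profiles (or a matrix)."""
    X = _as_feature_matrix(profiles_or_X)
    return FeatureNormalizer().fit(X)


def apply_normalization(profile_or_x, params: FeatureNormalizer) -> np.ndarray:
    """Map one profile (or feature vector) into normalized space."""
    if isinstance(profile_or_x, UserProfile):
        x = profile_or_x.features
    else:
        x = np.asarray(profile_or_x, dtype=float)
    return params.transform(x)[0] if x.ndim == 1 else params.transform(x)


def _as_feature_matrix(profiles_or_X) -> np.ndarray:
    if isinstance(profiles_or_X, np.ndarray):
        return profiles_or_X
    first = profiles_or_X[0] if len(profiles_or_X) else None
    if isinstance(first, UserProfile):
        return np.vstack([p.features for p in profiles_or_X])
    return np.asarray(profiles_or_X, dtype=float)


def reconstruct_profile(profile: UserProfile, smid: str, rating: int) -> UserProfile:
    """Fold one feedback rating into a profile (latest rating wins).

    Sets ``ratings[smid]`` to the new value, bumps ``feedback_round`` and
    leaves the feature vector untouched.  The profile is updated in place
    and returned.
    """
    rating = int(rating)
    if not (RATING_MIN <= rating <= RATING_MAX):
        raise ValueError(f"rating must be in {{{RATING_MIN}..{RATING_MAX}}}, got {rating}")
    profile.ratings[str(smid)] = rating
    profile.feedback_round += 1
    return profile


def profiles_to_json(profiles, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1)


def profiles_from_json(path) -> list[UserProfile]:
    with open(path, encoding="utf-8") as fh:
        return [UserProfile.from_dict(d) for d in json.load(fh)]
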