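"""Synthetic motion-bed sleep datasets with known archetype structure.

Emulates a cohort of users whose nightly sensor measurements (sleep time,
movement events, ambient sound, snoring index) and BMI are drawn from a
small number of latent sleep-pattern archetypes, and whose 1-5 ratings of
recommended sleep patterns decrease with the distance between the user
and the pattern's centroid in normalized feature space:

    rating(u, j) = clip(round(5 - affinity_scale * dist(u, c_j) + eps), 1, 5)

with eps ~ N(0, rating_noise_sd) and each entry masked missing with
probability ``missing_rate``.  The affinity model is a modelling choice,
not an observed behaviour: it makes within-cluster collaborative
filtering informative by construction, which is exactly the premise a
pattern-restricted recommender rests on.

Ground truth (archetype labels, centroids) is retained so parameter
recovery and recommendation error can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .profiles import FEATURE_NAMES, FeatureNormalizer, build_profiles
from .ratings import RatingMatrix, default_smids

#: five sleep archetypes over (sleep_time h, moving events/night, sound dB,
#: snoring index, BMI kg/m^2): settled, short, heavy-snorer, restless, long
DEFAULT_ARCHETYPES = (
    (7.5, 8.0, 32.0, 0.5, 22.0),
    (4.5, 20.0, 38.0, 1.0, 24.0),
    (6.5, 15.0, 55.0, 6.0, 31.0),
    (6.5, 32.0, 46.0, 2.5, 28.0),
    (9.5, 4.0, 25.0, 0.2, 18.0),
)

#: per-feature nightly noise SDs (BMI noise is per user, not per night)
DEFAULT_FEATURE_NOISE = (0.5, 3.0, 3.0, 0.5, 1.5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a simulated cohort.

    Defaults mirror the study scale: 1000 users drawn from five latent
    sleep-pattern archetypes, a week of nights per user, and sparse
    integer ratings produced by the distance-affinity model.
    """

    n_users: int = 1000
    k_true: int = 5
    nights_per_user: int = 7
    archetype_means: tuple = DEFAULT_ARCHETYPES
    feature_noise_sd: tuple = DEFAULT_FEATURE_NOISE
    rating_noise_sd: float = 0.4
    affinity_scale: float = 1.0
    missing_rate: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_users < 0 or self.nights_per_user < 1 or self.k_true < 1:
            raise ValueError("counts must be positive (n_users may be 0)")
        arch = np.asarray(self.archetype_means, dtype=float)
        if arch.shape != (self.k_true, len(FEATURE_NAMES)):
            raise ValueError(
                f"archetype_means must be {self.k_true} x {len(FEATURE_NAMES)}, got {arch.shape}"
            )
        noise = np.asarray(self.feature_noise_sd, dtype=float)
        if noise.shape != (len(FEATURE_NAMES),) or np.any(noise < 0):
            raise ValueError("feature_noise_sd must be 5 nonnegative values")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be nonnegative")
        if self.affinity_scale <= 0:
            raise ValueError("affinity_scale must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    @property
    def archetype_array(self) -> np.ndarray:
        return np.asarray(self.archetype_means, dtype=float)

    @property
    def noise_array(self) -> np.ndarray:
        return np.asarray(self.feature_noise_sd, dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_users": self.n_users,
            "k_true": self.k_true,
            "nights_per_user": self.nights_per_user,
            "archetype_means": [list(map(float, row)) for row in self.archetype_means],
            "feature_noise_sd": list(map(float, self.feature_noise_sd)),
            "rating_noise_sd": self.rating_noise_sd,
            "affinity_scale": self.affinity_scale,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "archetype_means" in d:
            d["archetype_means"] = tuple(tuple(row) for row in d["archetype_means"])
        if "feature_noise_sd" in d:
            d["feature_noise_sd"] = tuple(d["feature_noise_sd"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def generate_users(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Draw users, their nightly records and demographics.

    Returns ``(records, demographics, true_labels)``: a long nightly-record
    table (uid, night_index, sleep_time, moving, sound, snoring), a
    per-user demographics table (uid, bmi, birth, gender), and the latent
    archetype label of each user.  Nightly sensor values are
    archetype mean + N(0, sd) truncated at 0.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, nights = config.n_users, config.nights_per_user
    record_cols = ["uid", "night_index", "sleep_time", "moving", "sound", "snoring"]
    demo_cols = ["uid", "bmi", "birth", "gender"]
    if n == 0:
        return (
            pd.DataFrame(columns=record_cols),
            pd.DataFrame(columns=demo_cols),
            np.empty(0, dtype=int),
        )
    labels = rng.integers(0, config.k_true, size=n)
    arch = config.archetype_array
    noise = config.noise_array
    sensor = arch[labels, :4][:, None, :] + rng.normal(0.0, noise[:4], size=(n, nights, 4))
    sensor = np.maximum(sensor, 0.0)
    bmi = np.maximum(arch[labels, 4] + rng.normal(0.0, noise[4], size=n), 0.0)
    birth = rng.integers(1950, 2006, size=n)
    gender = rng.choice(["F", "M"], size=n)
    uids = [f"U{i + 1:04d}" for i in range(n)]
    records = pd.DataFrame(
        {
            "uid": np.repeat(uids, nights),
            "night_index": np.tile(np.arange(nights), n),
            "sleep_time": sensor[:, :, 0].ravel(),
            "moving": sensor[:, :, 1].ravel(),
            "sound": sensor[:, :, 2].ravel(),
            "snoring": sensor[:, :, 3].ravel(),
        }
    )
    demographics = pd.DataFrame({"uid": uids, "bmi": bmi, "birth": birth, "gender": gender})
    return records, demographics, labels


def affinity_rating(dist, config: SyntheticConfig, eps=0.0):
    """The rating model: clip(round(5 - affinity_scale * dist + eps), 1, 5)."""
    raw = 5.0 - config.affinity_scale * np.asarray(dist, dtype=float) + eps
    return np.clip(np.rint(raw), 1, 5)


def simulate_ratings(uids, Z, centroids, config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> RatingMatrix:
    """Simulate the sparse user x pattern rating matrix.

    ``Z`` are user feature vectors and ``centroids`` the pattern centers,
    both in the same normalized space.  Each entry is independently
    missing with probability ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    dist = cdist(Z, centroids)
    eps = rng.normal(0.0, config.rating_noise_sd, size=dist.shape) if config.rating_noise_sd > 0 else 0.0
    raw = affinity_rating(dist, config, eps).astype(float)
    missing = rng.random(size=dist.shape) < config.missing_rate
    raw[missing] = np.nan
    return RatingMatrix(uids, default_smids(centroids.shape[0]), raw)


def simulate_feedback(z_user, centroid, config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> int:
    """One feedback rating for a recommended pattern, by the affinity model."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dist = float(np.linalg.norm(np.asarray(z_user, float) - np.asarray(centroid, float)))
    eps = rng.normal(0.0, config.rating_noise_sd) if config.rating_noise_sd > 0 else 0.0
    return int(affinity_rating(dist, config, eps))


@dataclass
class SyntheticDataset:
    """A generated cohort bundled with its ground truth."""

    config: SyntheticConfig
    records: pd.DataFrame
    demographics: pd.DataFrame
    true_labels: np.ndarray
    uids: list = field(default_factory=list)
    features: np.ndarray | None = None        # raw per-user 5-vectors
    normalizer: FeatureNormalizer | None = None
    Z: np.ndarray | None = None               # normalized features
    centroids_norm: np.ndarray | None = None  # archetype means, normalized
    ratings: RatingMatrix | None = None


def generate_dataset(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Full pipeline fixture: users, profiles, normalization, ratings."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    records, demographics, labels = generate_users(config, rng)
    _, X, uids = build_profiles(records, demographics)
    if config.n_users < 2:
        return SyntheticDataset(config, records, demographics, labels, uids, X)
    norm = FeatureNormalizer().fit(X)
    Z = norm.transform(X)
    centroids = norm.transform(config.archetype_array)
    matrix = simulate_ratings(uids, Z, centroids, config, rng)
    return SyntheticDataset(config, records, demographics, labels, uids, X, norm, Z, centroids, matrix)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the cohort as CSVs: records, users, ratings (triplets), truth."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.records.to_csv(out / "records.csv", index=False)
    ds.demographics.to_csv(out / "users.csv", index=False)
    if ds.ratings is not None:
        ds.ratings.to_triplets().to_csv(out / "ratings.csv", index=False)
    pd.DataFrame({"uid": ds.uids, "true_label": ds.true_labels}).to_csv(
        out / "truth.csv", index=False
    )
    ds.config.to_json(out / "config.json")


def read_dataset(indir) -> SyntheticDataset:
    """Reload a cohort written by :func:`write_dataset`."""
    from pathlib import Path

    ind = Path(indir)
    config = SyntheticConfig.from_json(ind / "config.json")
    records = pd.read_csv(ind / "records.csv")
    demographics = pd.read_csv(ind / "users.csv")
    truth = pd.read_csv(ind / "truth.csv")
    _, X, uids = build_profiles(records, demographics)
    ds = SyntheticDataset(config, records, demographics,
                          truth["true_label"].to_numpy(), uids, X)
    if len(uids) >= 2:
        ds.normalizer = FeatureNormalizer().fit(X)
        ds.Z = ds.normalizer.transform(X)
        ds.centroids_norm = ds.normalizer.transform(config.archetype_array)
        ratings_path = ind / "ratings.csv"
        if ratings_path.exists():
            triplets = pd.read_csv(ratings_path)
            ds.ratings = RatingMatrix.from_triplets(
                triplets, uids=uids, smids=default_smids(config.k_true)
            )
    return ds


def make_default_config(**overrides) -> SyntheticConfig:
    """The default benchmark conditions, optionally overridden."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()
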