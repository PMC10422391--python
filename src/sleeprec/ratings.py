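"""Sleep-pattern rating matrix and within-pattern user similarity.

Users rate recommended sleep patterns on a 1-5 scale.  For similarity
computation the ratings are mapped affinely onto [-1, 1] (1 -> -1,
3 -> 0, 5 -> +1) so that cosine similarity lands in [-1, 1] with 0 the
"indifferent" midpoint.  Similarity between two users is the cosine over
the patterns *both* have rated (pairwise-complete support); zero-filling
unrated entries would manufacture agreement on patterns neither has seen.

Note on the similarity choice: distances between user *feature vectors*
are Euclidean (see :mod:`sleeprec.clustering`), but user-user similarity
on the rating matrix is a cosine — only the cosine yields the documented
[-1, 1] similarity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import RATING_MAX, RATING_MIN


def default_smids(k: int) -> list[str]:
    return [f"SM{j + 1}" for j in range(k)]


class RatingMatrix:
    """Sparse users x sleep-pattern-labels matrix of 1-5 ratings.

    Stored densely as floats with NaN marking missing entries (the label
    catalogue is small, typically <= 8 patterns); observed entries must be
    integers in {1..5}.
    """

    def __init__(self, uids, smids, raw=None):
        self.uids = [str(u) for u in uids]
        self.smids = [str(s) for s in smids]
        if raw is None:
            raw = np.full((len(self.uids), len(self.smids)), np.nan)
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (len(self.uids), len(self.smids)):
            raise ValueError("raw matrix shape does not match uids x smids")
        _validate_raw(raw)
        self.raw = raw
        self._uid_index = {u: i for i, u in enumerate(self.uids)}
        self._smid_index = {s: j for j, s in enumerate(self.smids)}
        #: bumped on every write; lets callers cache derived quantities
        self.version = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def from_triplets(cls, triplets: pd.DataFrame, uids=None, smids=None) -> "RatingMatrix":
        """Build from a (uid, smid, rating) long table."""
        if uids is None:
            uids = sorted(triplets["uid"].astype(str).unique())
        if smids is None:
            smids = sorted(triplets["smid"].astype(str).unique())
        m = cls(uids, smids)
        for row in triplets.itertuples(index=False):
            m.set(str(row.uid), str(row.smid), row.rating)
        return m

    def to_triplets(self) -> pd.DataFrame:
        rows = [
            (u, s, int(self.raw[i, j]))
            for i, u in enumerate(self.uids)
            for j, s in enumerate(self.smids)
            if not np.isnan(self.raw[i, j])
        ]
        return pd.DataFrame(rows, columns=["uid", "smid", "rating"])

    def copy(self) -> "RatingMatrix":
        return RatingMatrix(self.uids, self.smids, self.raw.copy())

    # -- access -------------------------------------------------------------

    def uid_index(self, uid: str) -> int:
        try:
            return self._uid_index[str(uid)]
        except KeyError:
            raise KeyError(f"unknown uid {uid!r}") from None

    def smid_index(self, smid: str) -> int:
        try:
            return self._smid_index[str(smid)]
        except KeyError:
            raise KeyError(f"unknown smid {smid!r}") from None

    def get(self, uid, smid) -> float:
        return float(self.raw[self.uid_index(uid), self.smid_index(smid)])

    def set(self, uid, smid, rating) -> None:
        r = float(rating)
        if not (float(r).is_integer() and RATING_MIN <= r <= RATING_MAX):
            raise ValueError(f"rating must be an integer in {{1..5}}, got {rating!r}")
        self.raw[self.uid_index(uid), self.smid_index(smid)] = r
        self.version += 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean observed-entry indicator."""
        return ~np.isnan(self.raw)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def normalized(self, ternary: bool = False) -> np.ndarray:
        """The [-1, 1] view; ``ternary=True`` quantizes to sign {-1, 0, +1}."""
        norm = normalize_ratings(self.raw)
        return np.sign(norm) if ternary else norm

    def rated_smids(self, uid) -> list[str]:
        i = self.uid_index(uid)
        return [s for j, s in enumerate(self.smids) if not np.isnan(self.raw[i, j])]

    def unrated_smids(self, uid) -> list[str]:
        i = self.uid_index(uid)
        return [s for j, s in enumerate(self.smids) if np.isnan(self.raw[i, j])]


def _validate_raw(raw: np.ndarray) -> None:
    observed = raw[~np.isnan(raw)]
    if observed.size and not (
        np.all((observed >= RATING_MIN) & (observed <= RATING_MAX))
        and np.allclose(observed, np.rint(observed))
    ):
        raise ValueError("observed ratings must be integers in {1..5}")


def normalize_ratings(raw):
    """Affine map of 1-5 ratings onto [-1, 1]: r -> (r - 3) / 2.

    NaN (missing) entries pass through; out-of-range values raise.
    """
    arr = np.asarray(raw, dtype=float)
    _validate_raw(np.atleast_1d(arr))
    result = (arr - 3.0) / 2.0
    return float(result) if np.isscalar(raw) or arr.ndim == 0 else result


# ---------------------------------------------------------------------------
# similarity


@dataclass(frozen=True)
class SimilarityResult:
    """Cosine similarity between two users with its co-rating support."""

    uid_a: str
    uid_b: str
    sim: float
    n_corated: int


def sim_score(uid_a, uid_b, matrix: RatingMatrix, ternary: bool = False) -> SimilarityResult:
    """Cosine similarity over co-rated patterns on the normalized matrix.

    Returns sim = 0 (with the support recorded) when the users share no
    rated pattern or either co-rated sub-vector is all zero.
    """
    i = matrix.uid_index(uid_a)
    j = matrix.uid_index(uid_b)
    norm = matrix.normalized(ternary=ternary)
    a, b = norm[i], norm[j]
    both = ~np.isnan(a) & ~np.isnan(b)
    n_co = int(both.sum())
    sim = 0.0
    if n_co:
        av, bv = a[both], b[both]
        na, nb = np.sqrt(np.sum(av * av)), np.sqrt(np.sum(bv * bv))
        if na > 0 and nb > 0:
            sim = float(np.clip(np.dot(av, bv) / (na * nb), -1.0, 1.0))
    return SimilarityResult(str(uid_a), str(uid_b), sim, n_co)


def similarity_row(i: int, norm: np.ndarray):
    """Vectorized co-rated cosine of user row ``i`` against every user.

    Returns ``(sims, n_corated)`` arrays of length n_users.  Pairs with no
    co-rated pattern, or an all-zero co-rated sub-vector, get sim 0.
    """
    mask = ~np.isnan(norm)
    filled = np.nan_to_num(norm)
    a = filled[i]
    mask_a = mask[i]
    num = filled @ a
    # per-pair co-rated squared norms: restrict each user's energy to the
    # coordinates the *other* user rated
    den_a = mask @ (a * a)                    # ||a|| over j's support (a already 0 off-support)
    den_b = (filled * filled) @ mask_a.astype(float)  # ||b|| over a's support
    n_co = mask @ mask_a.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = num / np.sqrt(den_a * den_b)
    sims = np.where((den_a > 0) & (den_b > 0), sims, 0.0)
    return np.clip(sims, -1.0, 1.0), n_co


def neighbor_set(uid, matrix: RatingMatrix, labels, tau: float = 0.0,
                 max_neighbors: int | None = None, ternary: bool = False) -> list[SimilarityResult]:
    """Ranked same-pattern neighbors of ``uid``.

    Candidates are restricted to users sharing ``uid``'s pattern label;
    pairs with similarity below ``tau`` or with zero co-rating support are
    dropped; the rest are sorted by similarity descending (ties by uid)
    and truncated to ``max_neighbors``.  An empty list is a valid result
    (the cold-start path).
    """
    labels = np.asarray(labels)
    i = matrix.uid_index(uid)
    sims, n_co = similarity_row(i, matrix.normalized(ternary=ternary))
    keep = (labels == labels[i]) & (n_co > 0) & (sims >= tau)
    keep[i] = False
    candidates = [
        SimilarityResult(str(uid), matrix.uids[j], float(sims[j]), int(n_co[j]))
        for j in np.flatnonzero(keep)
    ]
    candidates.sort(key=lambda r: (-r.sim, r.uid_b))
    if max_neighbors is not None:
        candidates = candidates[:max_neighbors]
    return candidates
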