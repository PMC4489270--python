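"""Profile comparison: Pearson correlation and the species-shuffling null.

Two proteins co-evolve if their standardized conservation profiles rise
and fall together across the surveyed genomes, which is measured by the
Pearson correlation r of their Z-score profiles.  Because profile entries
are not independent draws (species are phylogenetically related and the
genome columns were jointly standardized), significance is estimated with
a naive empirical null: shuffle the species entries of one profile many
times, collect the resulting correlations, and report the observed r as a
Z-score against that null distribution.  The null mean is estimated
empirically rather than assumed zero — for profiles of length n it sits
near -1/(n-1), not at 0.

``exhaustive_permutation_z`` enumerates all n! permutations for short
vectors and is the exact reference the sampled estimator must converge
to; it exists so the Monte-Carlo machinery can be validated against a
closed, independent computation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateProfileError, MatrixError

logger = logging.getLogger(__name__)

DEFAULT_N_SHUFFLES = 1000


def _as_unit(v: np.ndarray) -> np.ndarray:
    """Center and scale to unit norm so correlations become dot products."""
    v = np.asarray(v, dtype=float)
    c = v - v.mean()
    norm = np.linalg.norm(c)
    if norm == 0:
        raise DegenerateProfileError("profile has zero variance")
    return c / norm


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    Raises :class:`DegenerateProfileError` if either profile is constant
    (the caller excludes such proteins) and :class:`ValueError` on length
    mismatch or length < 3.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("profiles must have length >= 3")
    r = float(_as_unit(a) @ _as_unit(b))
    return max(-1.0, min(1.0, r))


def _pair_rng(seed: int, query_id: str, subject_id: str) -> np.random.Generator:
    """Generator seeded per (query, subject) pair from the master seed.

    Results are then reproducible regardless of the order in which pairs
    are evaluated.  CRC32 keeps the derived entropy stable across runs
    and platforms (unlike the salted builtin ``hash``).
    """
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed, zlib.crc32(query_id.encode()), zlib.crc32(subject_id.encode())]
        )
    )


def _null_coefficients(
    a, b, n_shuffles: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    a_hat = _as_unit(a)
    b_hat = _as_unit(b)
    r_obs = float(a_hat @ b_hat)
    n = a_hat.size
    # Uniform random permutations with replacement; identity not excluded.
    idx = rng.permuted(np.tile(np.arange(n), (n_shuffles, 1)), axis=1)
    r_null = b_hat[idx] @ a_hat
    return r_obs, r_null


def permutation_z(
    a,
    b,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
) -> float:
    """Observed r standardized against the species-shuffling null.

    Draws ``n_shuffles`` uniform random permutations of ``b``, computes the
    correlation of ``a`` with each, and returns
    ``(r_obs - mean(r_null)) / sd(r_null)``.  Deterministic given a seed.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs, r_null = _null_coefficients(a, b, n_shuffles, rng)
    sd = r_null.std()
    if sd == 0:
        raise DegenerateProfileError("degenerate null: all shuffled r identical")
    return float((r_obs - r_null.mean()) / sd)


def exhaustive_permutation_z(a, b) -> float:
    """Exact permutation Z over all n! shuffles (n <= 7 only).

    Enumeration oracle for :func:`permutation_z`; the sampled estimate
    converges to this value at the usual 1/sqrt(n_shuffles) Monte-Carlo
    rate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size > 7:
        raise ValueError(f"exhaustive enumeration limited to length <= 7, got {a.size}")
    a_hat = _as_unit(a)
    b_hat = _as_unit(b)
    r_obs = float(a_hat @ b_hat)
    r_null = np.array([np.dot(a_hat, perm) for perm in permutations(b_hat)])
    assert len(r_null) == factorial(a.size)
    sd = r_null.std()
    if sd == 0:
        raise DegenerateProfileError("degenerate null: all permutations give same r")
    return float((r_obs - r_null.mean()) / sd)


@dataclass(frozen=True)
class SimilarityResult:
    """One row of the ranked output: a subject protein compared to the query.

    ``rank`` 0 is reserved for the query itself (the heatmap's top row,
    r = 1 by construction); hits start at rank 1.
    """

    query_protein_id: str
    subject_protein_id: str
    r: float
    z: float
    n_shuffles: int
    rank: int


def results_to_frame(results: list[SimilarityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "protein_id": s.subject_protein_id,
                "r": s.r,
                "z": s.z,
            }
            for s in results
        ]
    )


class ProfileSimilaritySearch(BaseEstimator):
    """Top-k co-evolution search over a fitted Z-score profile matrix.

    ``fit`` indexes a protein x genome Z-matrix (typically the output of
    :class:`~phyloprofile.profile_core.NPPNormalizer`); ``query`` returns
    the k proteins whose profiles correlate best with a named protein's
    profile, each with its permutation Z-score, in the spirit of
    :class:`sklearn.neighbors.NearestNeighbors` but with correlation
    similarity and an empirical significance estimate.

    Parameters
    ----------
    k : int, default 50
        Number of hits to return (the reference server offers 50, 100,
        150 or 200; any positive integer is accepted).
    n_shuffles : int, default 1000
        Shuffles per pair for the permutation null.
    seed : int, default 0
        Master seed; each (query, subject) pair derives its own stream.
    """

    def __init__(
        self, k: int = 50, n_shuffles: int = DEFAULT_N_SHUFFLES, seed: int = 0
    ):
        self.k = k
        self.n_shuffles = n_shuffles
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "ProfileSimilaritySearch":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a protein x genome DataFrame of Z-scores")
        if X.shape[1] < 3:
            raise MatrixError("need at least 3 genome columns")
        self.zmatrix_ = X
        self.protein_ids_ = list(X.index)
        self.genome_ids_ = list(X.columns)
        return self

    def _check_fitted(self):
        if not hasattr(self, "zmatrix_"):
            raise MatrixError("ProfileSimilaritySearch is not fitted")

    def _all_correlations(self, profile: np.ndarray) -> pd.Series:
        """Pearson r of one profile against every indexed protein.

        Zero-variance rows correlate as NaN and are excluded downstream.
        """
        Z = self.zmatrix_.to_numpy(dtype=float)
        q = np.asarray(profile, dtype=float)
        qc = q - q.mean()
        qn = np.linalg.norm(qc)
        if qn == 0:
            raise DegenerateProfileError("query profile has zero variance")
        Zc = Z - Z.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Zc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Zc @ (qc / qn)) / norms
        r[norms == 0] = np.nan
        return pd.Series(np.clip(r, -1.0, 1.0), index=self.zmatrix_.index)

    def query_profile(
        self, profile, label: str = "query", k: int | None = None,
        include_self_row: bool = True,
    ) -> list[SimilarityResult]:
        """Rank indexed proteins against an arbitrary Z-score profile.

        Hits are sorted by r descending, ties broken by protein id
        ascending.  When ``include_self_row`` is set, a rank-0 row for the
        query profile itself (r = 1) heads the list.
        """
        self._check_fitted()
        k = self.k if k is None else k
        if k < 1:
            raise ValueError("k must be >= 1")
        r_all = self._all_correlations(profile)
        dropped = r_all.index[r_all.isna()]
        if len(dropped):
            logger.warning(
                "skipping %d zero-variance profile(s): %s",
                len(dropped), ", ".join(map(str, dropped[:10])),
            )
        r_all = r_all.dropna()
        r_all = r_all.drop(index=label, errors="ignore")
        order = sorted(r_all.items(), key=lambda kv: (-kv[1], kv[0]))[:k]

        results: list[SimilarityResult] = []
        if include_self_row:
            z_self = permutation_z(
                profile, profile, self.n_shuffles, _pair_rng(self.seed, label, label)
            )
            results.append(
                SimilarityResult(label, label, 1.0, z_self, self.n_shuffles, 0)
            )
        for rank, (pid, r) in enumerate(order, start=1):
            z = permutation_z(
                profile,
                self.zmatrix_.loc[pid].to_numpy(dtype=float),
                self.n_shuffles,
                _pair_rng(self.seed, label, str(pid)),
            )
            results.append(
                SimilarityResult(label, str(pid), float(r), z, self.n_shuffles, rank)
            )
        return results

    def query(self, protein_id: str, k: int | None = None) -> list[SimilarityResult]:
        """Top-k co-evolving partners of a protein already in the matrix."""
        self._check_fitted()
        if protein_id not in self.zmatrix_.index:
            raise KeyError(f"protein {protein_id!r} not in Z-matrix")
        n_candidates = len(self.protein_ids_) - 1
        k = self.k if k is None else k
        if not 1 <= k <= n_candidates:
            raise ValueError(f"k must be in [1, {n_candidates}], got {k}")
        profile = self.zmatrix_.loc[protein_id].to_numpy(dtype=float)
        return self.query_profile(profile, label=protein_id, k=k)


def top_k_similar(
    query_id: str,
    zmatrix: pd.DataFrame,
    k: int,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> list[SimilarityResult]:
    """Functional wrapper over :class:`ProfileSimilaritySearch.query`."""
    search = ProfileSimilaritySearch(k=k, n_shuffles=n_shuffles, seed=seed)
    return search.fit(zmatrix).query(query_id)
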