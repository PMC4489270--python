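"""Self-score normalization and per-genome standardization of profiles.

The raw bit score of a protein against a distant genome is small even for
a perfectly conserved ortholog, simply because every alignment to that
genome scores low.  The normalized phylogenetic profile corrects for this
in two steps: (1) divide each protein's per-genome top bit score by its
self-score (the top bit score of the protein against its own genome), so
values land on a 0-1 conservation scale, and (2) standardize each genome
column against the distribution of normalized scores of *all* profiled
proteins in that genome, so a value expresses conservation relative to
what is typical at that evolutionary distance.

The per-genome means and standard deviations learned in step (2) are the
reusable "genome statistics": sequence-mode queries are standardized
against them without re-profiling the whole proteome, which is why the
transformer below separates ``fit`` (learn the statistics) from
``transform`` (apply them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .blast_io import (
    DEFAULT_MIN_FRACTION,
    DEFAULT_SCORE_THRESHOLD,
    GenomeManifest,
    filter_low_scores,
    filter_sparse_queries,
)
from .errors import DegenerateProfileError, MatrixError, NormalizationError


def normalize_by_self(
    matrix: pd.DataFrame, manifest: GenomeManifest, cap: bool = True
) -> pd.DataFrame:
    """Divide each protein's scores by its self-score; missing becomes 0.

    The self-score is the protein's top within-genome BLAST score (taken
    from the query-genome column, so a higher-scoring paralog can stand in
    for the protein itself).  The query-genome column therefore normalizes
    to exactly 1 for every retained protein.  With ``cap`` (default), the
    rare cross-genome score exceeding the self-score is clipped to 1 so
    all values live in [0, 1].

    Raises
    ------
    NormalizationError
        If any protein has a missing or non-positive self-score; the
        message lists the offending protein ids.
    """
    qcol = manifest.query_genome_id
    if qcol not in matrix.columns:
        raise MatrixError(f"query genome column {qcol!r} absent from matrix")
    self_scores = matrix[qcol]
    bad = matrix.index[self_scores.isna() | (self_scores <= 0)]
    if len(bad):
        raise NormalizationError(
            "cannot normalize proteins with missing or zero self-score: "
            + ", ".join(map(str, bad[:20]))
            + ("..." if len(bad) > 20 else "")
        )
    norm = matrix.div(self_scores, axis=0).fillna(0.0)
    if cap:
        norm = norm.clip(upper=1.0)
    return norm


def compute_genome_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-genome mean and population standard deviation of normalized scores.

    Zeros (absent orthologs) are part of the population: excluding them
    would bias the genome means upward.  Standard deviation divides by n,
    not n - 1.  Returns a DataFrame indexed by genome id with columns
    ``mean``, ``sd`` and ``n``.

    Raises
    ------
    DegenerateProfileError
        If any genome column has zero variance (its Z-scores would be
        undefined); the message names the genome.
    """
    if len(matrix) < 2:
        raise MatrixError("need at least 2 proteins to compute genome statistics")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        raise DegenerateProfileError(
            f"zero-variance genome column(s): {', '.join(map(str, flat))}"
        )
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "n": len(matrix)}
    ).rename_axis("genome_id")


def zscore_matrix(matrix: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Standardize each genome column with the given genome statistics."""
    missing = [g for g in matrix.columns if g not in stats.index]
    if missing:
        raise MatrixError(f"genomes absent from stats: {missing}")
    mean = stats["mean"].reindex(matrix.columns)
    sd = stats["sd"].reindex(matrix.columns)
    return (matrix - mean) / sd


def write_stats_tsv(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index_label="genome_id")


def read_stats_tsv(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", index_col=0)
    return stats[["mean", "sd", "n"]]


class NPPNormalizer(TransformerMixin, BaseEstimator):
    """Transformer from raw bit-score matrices to standardized profiles.

    Applies the whole-genome workflow: filter bit scores below
    ``score_threshold``, drop proteins with hits in fewer than
    ``min_fraction`` of genomes, normalize by self-score, and Z-score each
    genome column.  ``fit`` learns the per-genome means and standard
    deviations from the training matrix; ``transform`` standardizes a raw
    matrix against those learned statistics, so a fitted normalizer also
    serves sequence-mode queries (see :mod:`phyloprofile.sequence_query`).

    The query-genome column normalizes to exactly 1 for every protein, so
    it carries no information and has no defined Z-score; it is kept in
    ``normalized_`` but excluded from the genome statistics and the
    Z-matrix.

    Parameters
    ----------
    manifest : GenomeManifest
        Genome order and the identity of the query genome.
    score_threshold : float, default 50
        Bit scores strictly below this are treated as no hit.
    min_fraction : float, default 0.25
        Minimum fraction of genomes with a surviving hit.
    cap : bool, default True
        Clip normalized values at 1.

    Attributes
    ----------
    genome_stats_ : pandas.DataFrame
        Per-genome ``mean``, ``sd`` (population) and ``n``.
    normalized_ : pandas.DataFrame
        Normalized training matrix (values in [0, 1]).
    removed_proteins_ : list of str
        Proteins dropped by the sparsity filter.
    """

    def __init__(
        self,
        manifest: GenomeManifest,
        score_threshold: float = DEFAULT_SCORE_THRESHOLD,
        min_fraction: float = DEFAULT_MIN_FRACTION,
        cap: bool = True,
    ):
        self.manifest = manifest
        self.score_threshold = score_threshold
        self.min_fraction = min_fraction
        self.cap = cap

    def _normalize(self, X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        filtered = filter_low_scores(X, self.score_threshold)
        filtered, removed = filter_sparse_queries(filtered, self.min_fraction)
        return normalize_by_self(filtered, self.manifest, cap=self.cap), removed

    def fit(self, X: pd.DataFrame, y=None) -> "NPPNormalizer":
        """Learn per-genome statistics from a raw bit-score matrix."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a protein x genome DataFrame")
        norm, removed = self._normalize(X)
        self.normalized_ = norm
        self.removed_proteins_ = removed
        self.genome_stats_ = compute_genome_stats(
            norm.drop(columns=self.manifest.query_genome_id)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Standardize a raw bit-score matrix with the fitted statistics."""
        if not hasattr(self, "genome_stats_"):
            raise MatrixError("NPPNormalizer is not fitted")
        norm, _ = self._normalize(X)
        return zscore_matrix(
            norm.drop(columns=self.manifest.query_genome_id), self.genome_stats_
        )

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        self.fit(X)
        return zscore_matrix(
            self.normalized_.drop(columns=self.manifest.query_genome_id),
            self.genome_stats_,
        )
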