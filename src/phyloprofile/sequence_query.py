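"""Profiling a single submitted protein sequence against a built database.

A user-submitted sequence has no self-score: it is not a member of the
profiled proteome, so its within-genome top score is unavailable.  The
workflow is therefore modified: per-genome top bit scores are filtered as
usual, normalized by the *highest* score among the genome hits (the best
genome defines conservation 1), and standardized against the per-genome
means and standard deviations precomputed from the whole-proteome build.
The resulting Z-profile is then ranked against the precomputed Z-matrix
exactly as in whole-genome mode.

This module consumes BLAST tabular files (the single query searched
against each genome's protein set); running BLASTP itself is optional
convenience via :func:`run_blastp`.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .blast_io import DEFAULT_SCORE_THRESHOLD, read_blast_tab, select_top_hits
from .errors import MatrixError, NormalizationError
from .profile_core import zscore_matrix
from .similarity import DEFAULT_N_SHUFFLES, ProfileSimilaritySearch, SimilarityResult


@dataclass(frozen=True)
class SequenceQueryProfile:
    """Per-genome scores of one submitted sequence at each pipeline stage."""

    query_label: str
    raw_scores: pd.Series
    normalized: pd.Series
    zscores: pd.Series


def normalize_by_max(raw_scores: pd.Series) -> pd.Series:
    """Scale per-genome scores by the best one; missing genomes become 0.

    Expects low scores to be filtered already; the maximum surviving score
    maps to exactly 1, so sequence-mode values cannot exceed 1 by
    construction.
    """
    present = raw_scores.dropna()
    if present.empty or present.max() <= 0:
        raise NormalizationError("no homologs above threshold")
    return (raw_scores / present.max()).fillna(0.0)


def zscore_with_stats(normalized: pd.Series, stats: pd.DataFrame) -> pd.Series:
    """Standardize a per-genome profile with precomputed genome statistics."""
    missing = [g for g in normalized.index if g not in stats.index]
    if missing:
        raise MatrixError(f"genomes absent from stats: {missing}")
    frame = zscore_matrix(normalized.to_frame().T, stats)
    return frame.iloc[0]


def build_sequence_profile(
    raw_scores: pd.Series,
    stats: pd.DataFrame,
    label: str = "query",
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> SequenceQueryProfile:
    """Run the sequence-mode pipeline up to the Z-score profile."""
    filtered = raw_scores.where(raw_scores >= score_threshold)
    normalized = normalize_by_max(filtered)
    # Only genomes with precomputed statistics can be standardized; the
    # query genome itself has none (its normalized column is constant).
    covered = normalized[normalized.index.isin(stats.index)]
    zscores = zscore_with_stats(covered, stats)
    return SequenceQueryProfile(label, raw_scores, normalized, zscores)


def query_by_sequence(
    raw_scores: pd.Series,
    stats: pd.DataFrame,
    zmatrix: pd.DataFrame,
    k: int = 50,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    label: str = "query",
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> tuple[SequenceQueryProfile, list[SimilarityResult]]:
    """Rank database proteins against a submitted sequence's profile.

    Output schema matches whole-genome queries; the rank-0 row is the
    submitted sequence itself.  Note that a database protein re-submitted
    as a sequence does not score r = 1 against itself: max-hit
    normalization differs from self-score normalization.
    """
    profile = build_sequence_profile(raw_scores, stats, label, score_threshold)
    search = ProfileSimilaritySearch(k=k, n_shuffles=n_shuffles, seed=seed)
    search.fit(zmatrix)
    ordered = profile.zscores.reindex(zmatrix.columns)
    if ordered.isna().any():
        raise MatrixError("sequence profile does not cover all matrix genomes")
    results = search.query_profile(
        ordered.to_numpy(dtype=float), label=label, k=k
    )
    return profile, results


def profile_from_blast_files(
    paths: Mapping[str, str | Path], genome_ids: list[str]
) -> pd.Series:
    """Collect one query's per-genome top bit scores from tabular files.

    ``paths`` maps genome id to the BLAST tabular file of the single query
    against that genome; genomes without a file or without hits are
    missing (NaN).
    """
    scores = pd.Series(np.nan, index=pd.Index(genome_ids, name="genome_id"))
    for gid, path in paths.items():
        if gid not in scores.index:
            raise MatrixError(f"genome {gid!r} not in manifest")
        hits = read_blast_tab(path, gid)
        if not hits:
            continue
        top = select_top_hits(hits)
        best = max(h.bit_score for h in top.values())
        scores[gid] = best
    return scores


def run_blastp(
    query_fasta: str | Path, subject_fasta: str | Path, out_path: str | Path
) -> Path:
    """Optional convenience: shell out to a local ``blastp`` (outfmt 6).

    Requires the NCBI BLAST+ suite on PATH; no pipeline stage depends on
    it, since the readers consume pre-made tabular files.
    """
    if shutil.which("blastp") is None:
        raise RuntimeError("blastp not found on PATH")
    subprocess.run(
        [
            "blastp", "-query", str(query_fasta), "-subject", str(subject_fasta),
            "-outfmt", "6", "-out", str(out_path),
        ],
        check=True,
    )
    return Path(out_path)


def read_fasta_label(path: str | Path) -> str:
    """First record id of a FASTA file, used to label sequence queries."""
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                return line[1:].split()[0].strip() or "query"
    return "query"
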