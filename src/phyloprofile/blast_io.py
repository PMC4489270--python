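"""Reading BLAST tabular output and assembling raw bit-score matrices.

The whole-genome profiling workflow starts from one 12-column BLAST
tabular file (``-outfmt 6``) per subject genome, holding the hits of every
protein of the query genome against that genome's full protein set.  This
module parses those files, keeps the top-scoring hit per (protein, genome)
pair, assembles the protein x genome raw bit-score matrix, and applies the
two early filters: drop low bit scores and drop proteins with homologs in
too few genomes.

Matrices are plain :class:`pandas.DataFrame` objects (rows = proteins,
columns = genomes in manifest order) with ``NaN`` as the explicit missing
marker.  Missing stays distinct from zero until normalization, where
"no surviving hit" becomes conservation 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import BlastParseError, MatrixError

#: Default bit-score cutoff: hits scoring strictly below it are discarded.
DEFAULT_SCORE_THRESHOLD = 50.0

#: Default minimum fraction of genomes in which a protein must have a
#: surviving hit to be profiled at all.
DEFAULT_MIN_FRACTION = 0.25

MISSING = "NA"


@dataclass(frozen=True)
class BlastHit:
    """One BLAST alignment, reduced to the fields the pipeline consumes.

    ``genome_id`` identifies the subject genome and comes from the file's
    manifest entry, not from the hit line itself.  The e-value is carried
    for provenance only; all scoring uses the bit score.
    """

    query_id: str
    subject_id: str
    evalue: float
    bit_score: float
    genome_id: str

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score: {self.bit_score}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


@dataclass(frozen=True)
class ManifestEntry:
    genome_id: str
    species: str
    taxon: str
    subtaxon: str


@dataclass(frozen=True)
class GenomeManifest:
    """Ordered list of surveyed genomes with their taxonomic grouping.

    The entry order is authoritative: it defines the column order of every
    matrix and the left-to-right order of the rendered heatmap, where
    genomes are grouped into major taxa (animals, fungi, plants, protists)
    and subtaxa.  ``query_genome_id`` names the genome whose proteome is
    being profiled; its column carries the self-scores.
    """

    entries: tuple[ManifestEntry, ...]
    query_genome_id: str

    def __post_init__(self) -> None:
        ids = [e.genome_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise MatrixError(f"duplicate genome ids in manifest: {dupes}")
        if self.query_genome_id not in ids:
            raise MatrixError(
                f"query genome {self.query_genome_id!r} not in manifest"
            )

    @property
    def genome_ids(self) -> list[str]:
        return [e.genome_id for e in self.entries]

    @property
    def species_names(self) -> list[str]:
        return [e.species for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def taxon_boundaries(self) -> list[int]:
        """Column indices where a new major taxon starts (first excluded).

        A manifest spanning four taxa yields three internal boundaries,
        used by the renderer to draw vertical separators.
        """
        bounds = []
        for i in range(1, len(self.entries)):
            if self.entries[i].taxon != self.entries[i - 1].taxon:
                bounds.append(i)
        return bounds

    def subtaxon_blocks(self) -> list[tuple[str, str, int, int]]:
        """Contiguous (taxon, subtaxon, start, stop) column blocks."""
        blocks: list[tuple[str, str, int, int]] = []
        for i, e in enumerate(self.entries):
            if blocks and blocks[-1][0] == e.taxon and blocks[-1][1] == e.subtaxon:
                t, s, start, _ = blocks[-1]
                blocks[-1] = (t, s, start, i + 1)
            else:
                blocks.append((e.taxon, e.subtaxon, i, i + 1))
        return blocks

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#query_genome={self.query_genome_id}\n")
            fh.write("genome_id\tspecies\ttaxon\tsubtaxon\n")
            for e in self.entries:
                fh.write(f"{e.genome_id}\t{e.species}\t{e.taxon}\t{e.subtaxon}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, query_genome_id: str | None = None) -> "GenomeManifest":
        """Read a 4-column manifest TSV (header line required).

        The query genome may be stated in a ``#query_genome=`` comment or
        passed explicitly; an explicit argument wins.
        """
        entries = []
        header_seen = False
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#query_genome=") and query_genome_id is None:
                        query_genome_id = line.split("=", 1)[1].strip()
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise BlastParseError(
                        f"{path}: manifest line needs 4 columns: {line!r}"
                    )
                entries.append(ManifestEntry(*parts[:4]))
        if query_genome_id is None:
            raise MatrixError("query genome id not given and not in manifest file")
        return cls(tuple(entries), query_genome_id)


def read_blast_tab(path: str | Path, genome_id: str) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file into :class:`BlastHit` records.

    Column 11 is the e-value and column 12 the bit score.  Lines starting
    with ``#`` are skipped; input order is preserved.  An empty file (or
    one with only comments) yields an empty list.

    Raises
    ------
    BlastParseError
        If a data line has fewer than 12 fields or its e-value/bit score
        does not parse; the message names the offending line number.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bit_score = float(fields[11])
            except ValueError as exc:
                raise BlastParseError(f"{path}:{lineno}: {exc}") from None
            hits.append(BlastHit(fields[0], fields[1], evalue, bit_score, genome_id))
    return hits


def select_top_hits(hits: Iterable[BlastHit]) -> dict[tuple[str, str], BlastHit]:
    """Keep the highest-scoring hit per (query protein, subject genome).

    Ties are broken by input order (the first hit at the maximal score
    wins), so the retained subject id is deterministic across runs.
    """
    best: dict[tuple[str, str], BlastHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.genome_id)
        cur = best.get(key)
        if cur is None or hit.bit_score > cur.bit_score:
            best[key] = hit
    return best


def build_raw_matrix(
    top_hits: Mapping[tuple[str, str], BlastHit | float],
    protein_ids: Iterable[str],
    manifest: GenomeManifest,
) -> pd.DataFrame:
    """Assemble the protein x genome raw bit-score matrix.

    Rows follow ``protein_ids``, columns follow manifest order; pairs with
    no hit are ``NaN``.  Values may be :class:`BlastHit` objects or bare
    scores.
    """
    proteins = list(protein_ids)
    if not proteins:
        raise MatrixError("protein_ids is empty")
    if len(set(proteins)) != len(proteins):
        dupes = sorted({p for p in proteins if proteins.count(p) > 1})
        raise MatrixError(f"duplicate protein ids: {dupes}")
    genome_set = set(manifest.genome_ids)
    mat = pd.DataFrame(
        np.nan, index=pd.Index(proteins, name="protein_id"),
        columns=manifest.genome_ids, dtype=float,
    )
    for (q, g), val in top_hits.items():
        if g not in genome_set:
            raise MatrixError(f"genome {g!r} not in manifest")
        if q not in mat.index:
            continue
        mat.at[q, g] = val.bit_score if isinstance(val, BlastHit) else float(val)
    return mat


def read_blast_dir(
    hits_dir: str | Path,
    manifest: GenomeManifest,
    protein_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble the raw matrix from a directory of per-genome hit files.

    Expects one ``<genome_id>.tsv`` BLAST tabular file per manifest
    genome; genomes without a file contribute an all-missing column.
    When ``protein_ids`` is not given, proteins appear in order of first
    occurrence scanning genomes in manifest order.
    """
    hits_dir = Path(hits_dir)
    top: dict[tuple[str, str], BlastHit] = {}
    for g in manifest.genome_ids:
        path = hits_dir / f"{g}.tsv"
        if not path.exists():
            continue
        top.update(select_top_hits(read_blast_tab(path, g)))
    if protein_ids is None:
        seen: dict[str, None] = {}
        for q, _ in top:
            seen.setdefault(q, None)
        protein_ids = list(seen)
    return build_raw_matrix(top, protein_ids, manifest)


def filter_low_scores(
    matrix: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> pd.DataFrame:
    """Blank cells with bit score strictly below ``threshold``.

    A score exactly at the threshold survives.  No rows or columns are
    removed; idempotent, and raising the threshold never restores a cell.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return matrix.where(matrix >= threshold)


def filter_sparse_queries(
    matrix: pd.DataFrame, min_fraction: float = DEFAULT_MIN_FRACTION
) -> tuple[pd.DataFrame, list[str]]:
    """Drop proteins with surviving hits in too small a fraction of genomes.

    Returns the filtered matrix and the removed protein ids.  Removing
    every row is an error: the caller should lower ``min_fraction``.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = matrix.notna().mean(axis=1)
    keep = frac >= min_fraction
    removed = list(matrix.index[~keep])
    if not keep.any():
        raise MatrixError(
            "all proteins removed by sparsity filter; lower min_fraction "
            f"(currently {min_fraction})"
        )
    return matrix.loc[keep], removed


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialize a matrix as TSV with ``NA`` for missing cells."""
    matrix.to_csv(path, sep="\t", na_rep=MISSING, index_label="protein_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0,
        na_values=[MISSING], keep_default_na=False,
    )
    return df.astype(float)
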