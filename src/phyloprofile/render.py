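"""Output renderings: the taxa-grouped heatmap and the numerical table.

The heatmap shows the query's conservation profile as the top row and
the most similar profiles below it, one genome per column in manifest
order.  Similarity cells run from white (no detectable similarity) to
dark blue (conservation equal to the self-score); two leftmost columns
on a yellow-to-dark-red ramp show each row's Pearson r and permutation
Z against the query.  Vertical lines separate the major taxa, whose
names sit on top of the heatmap.  The numerical table carries the same
rows: protein id, gene name, description, r, Z, then the normalized
similarity value per genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .blast_io import GenomeManifest
from .errors import MatrixError
from .similarity import SimilarityResult

logger = logging.getLogger(__name__)

#: White (value 0, no similarity) to dark blue (value 1).
SIMILARITY_CMAP = LinearSegmentedColormap.from_list(
    "similarity", ["#ffffff", "#c6dbef", "#4292c6", "#08306b"]
)
#: Yellow (low) to dark red (high) for the r and Z side columns.
STAT_CMAP = LinearSegmentedColormap.from_list(
    "stat", ["#ffff66", "#fd8d3c", "#8b0000"]
)


@dataclass(frozen=True)
class HeatmapModel:
    """Everything the renderer needs, already ordered.

    ``values`` rows follow ``results`` (query at rank 0 on top), columns
    follow the manifest; cells are normalized similarities in [0, 1].
    """

    results: tuple[SimilarityResult, ...]
    values: pd.DataFrame
    manifest: GenomeManifest

    def __post_init__(self) -> None:
        if not self.results:
            raise MatrixError("heatmap model needs at least one row")
        if len(self.results) != len(self.values):
            raise MatrixError("results and value rows disagree")
        if list(self.values.columns) != self.manifest.genome_ids:
            raise MatrixError("value columns must follow manifest order")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise MatrixError("similarity values must lie in [0, 1]")
        if self.results[0].rank != 0:
            raise MatrixError("first row must be the query (rank 0)")


def build_heatmap_model(
    results: list[SimilarityResult],
    normalized_matrix: pd.DataFrame,
    manifest: GenomeManifest,
    query_values: pd.Series | None = None,
) -> HeatmapModel:
    """Join ranked results with their normalized profile rows.

    ``query_values`` supplies the top row for sequence-mode queries whose
    profile is not part of the matrix.
    """
    rows = []
    for res in results:
        pid = res.subject_protein_id
        if res.rank == 0 and query_values is not None:
            rows.append(query_values.reindex(manifest.genome_ids).fillna(0.0))
        else:
            rows.append(normalized_matrix.loc[pid].reindex(manifest.genome_ids))
    values = pd.DataFrame(
        rows, index=[r.subject_protein_id for r in results]
    )
    return HeatmapModel(tuple(results), values, manifest)


def render_heatmap(
    model: HeatmapModel, out_path: str | Path, dpi: int = 150
) -> Path:
    """Draw the taxa-grouped similarity heatmap to a PNG/SVG file."""
    n_rows = len(model.results)
    n_cols = len(model.manifest)
    fig_w = max(6.0, 0.14 * n_cols + 2.5)
    fig_h = max(2.5, 0.22 * n_rows + 2.0)
    fig, (ax_stat, ax_heat) = plt.subplots(
        1, 2, figsize=(fig_w, fig_h), sharey=True,
        gridspec_kw={"width_ratios": [2, n_cols], "wspace": 0.02},
    )

    # r and Z side columns, each min-max scaled onto the yellow-red ramp.
    r_vals = np.array([res.r for res in model.results])
    z_vals = np.array([res.z for res in model.results])

    def _scale(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.full_like(v, 0.5)

    stat = np.column_stack([_scale(r_vals), _scale(z_vals)])
    ax_stat.imshow(stat, cmap=STAT_CMAP, aspect="auto", vmin=0, vmax=1)
    ax_stat.set_xticks([0, 1], ["r", "Z"])
    ax_stat.xaxis.set_ticks_position("top")
    ax_stat.set_yticks(
        range(n_rows), [res.subject_protein_id for res in model.results],
        fontsize=7,
    )
    ax_stat.tick_params(length=0)

    ax_heat.imshow(
        model.values.to_numpy(dtype=float),
        cmap=SIMILARITY_CMAP, aspect="auto", vmin=0.0, vmax=1.0,
    )
    ax_heat.set_xticks(
        range(n_cols), model.manifest.species_names, rotation=90, fontsize=6
    )
    ax_heat.tick_params(length=0)
    for b in model.manifest.taxon_boundaries():
        ax_heat.axvline(b - 0.5, color="black", linewidth=1.2)

    # Major-taxon labels across the top of their column blocks.
    seen: dict[str, list[int]] = {}
    for i, e in enumerate(model.manifest.entries):
        seen.setdefault(e.taxon, []).append(i)
    for taxon, cols in seen.items():
        ax_heat.text(
            (min(cols) + max(cols)) / 2, -0.8, taxon,
            ha="center", va="bottom", fontsize=8, fontweight="bold",
        )

    query = model.results[0].query_protein_id
    fig.suptitle(f"Phylogenetic profile similarity: {query}", y=0.995)
    fig.savefig(out_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return Path(out_path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """3-column annotation TSV: protein_id, gene_name, description."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    df.columns = ["gene_name", "description"][: len(df.columns)]
    return df


def write_results_table(
    results: list[SimilarityResult],
    normalized_matrix: pd.DataFrame,
    annotations: pd.DataFrame | None,
    out_path: str | Path,
    manifest: GenomeManifest | None = None,
    query_values: pd.Series | None = None,
    xlsx_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the downloadable results table (TSV, optionally xlsx too).

    Columns: protein_id, gene_name, description, r, z, then one column of
    normalized similarity per genome; the query is the first data row.
    Proteins without an annotation get empty name/description fields.
    """
    if not results:
        raise MatrixError("no results to write")
    genome_order = (
        manifest.genome_ids if manifest is not None else list(normalized_matrix.columns)
    )
    records = []
    for res in results:
        pid = res.subject_protein_id
        if annotations is not None and pid in annotations.index:
            name = annotations.at[pid, "gene_name"]
            desc = annotations.at[pid, "description"]
        else:
            if annotations is not None:
                logger.warning("no annotation for protein %s", pid)
            name, desc = "", ""
        if res.rank == 0 and query_values is not None:
            profile = query_values.reindex(genome_order).fillna(0.0)
        else:
            profile = normalized_matrix.loc[pid].reindex(genome_order)
        rec = {
            "rank": res.rank,
            "protein_id": pid,
            "gene_name": name,
            "description": desc,
            "r": res.r,
            "z": res.z,
        }
        rec.update(profile.to_dict())
        records.append(rec)
    table = pd.DataFrame(records)
    table.to_csv(out_path, sep="\t", index=False, float_format="%.6f")
    if xlsx_path is not None:
        table.to_excel(xlsx_path, index=False)  # needs openpyxl
    return table


def plot_profiles(
    normalized_matrix: pd.DataFrame,
    protein_ids: list[str],
    manifest: GenomeManifest,
    out_path: str | Path,
) -> Path:
    """Line plot of selected conservation profiles across the genome panel."""
    if not protein_ids:
        raise MatrixError("no proteins selected")
    fig, ax = plt.subplots(figsize=(max(6.0, 0.12 * len(manifest)), 4.0))
    x = np.arange(len(manifest))
    for pid in protein_ids:
        ax.plot(x, normalized_matrix.loc[pid].reindex(manifest.genome_ids), label=pid)
    for b in model_boundaries(manifest):
        ax.axvline(b - 0.5, color="gray", linewidth=0.6, alpha=0.6)
    ax.set_xticks(x, manifest.species_names, rotation=90, fontsize=6)
    ax.set_ylabel("relative conservation")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(out_path)


def model_boundaries(manifest: GenomeManifest) -> list[int]:
    return manifest.taxon_boundaries()
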