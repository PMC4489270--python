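"""Synthetic inputs with the statistical structure the profiler assumes.

Real profiling needs BLAST runs of a whole proteome against dozens of
genomes.  For testing and calibration this module fabricates the same
artifacts at desk scale: a taxon-structured genome manifest, raw
bit-score matrices containing planted co-evolving modules, per-genome
BLAST tabular files that re-parse to a known matrix, and vector pairs
with a chosen true Pearson correlation.

The planted-module model mirrors the biology the method exploits: a
module shares a latent clade-level presence/loss pattern (a pathway
dropped by whole clades) plus per-species conservation noise, while
background proteins each follow an independent latent pattern.  Missing
orthologs are genuinely missing, so the fixtures exercise the pipeline's
missing-value handling, not just Gaussian noise.

All randomness flows from one master seed through named substreams, so
every generated artifact is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blast_io import GenomeManifest, ManifestEntry

# Subtaxon layout emulating a survey of 86 eukaryotic genomes grouped
# into four major taxa; counts are scaled for other genome panel sizes.
_TAXON_BLOCKS: list[tuple[str, str, int]] = [
    ("Animals", "Vertebrates", 20),
    ("Animals", "Insects", 10),
    ("Animals", "Nematodes", 6),
    ("Animals", "Other animals", 4),
    ("Fungi", "Ascomycetes", 12),
    ("Fungi", "Basidiomycetes", 6),
    ("Fungi", "Other fungi", 2),
    ("Plants", "Land plants", 8),
    ("Plants", "Green algae", 6),
    ("Protists", "Alveolates", 6),
    ("Protists", "Excavates", 6),
]


def synthetic_manifest(n_genomes: int = 86) -> GenomeManifest:
    """Taxon-grouped manifest of synthetic genomes; first genome is the query.

    For 86 genomes the subtaxon sizes follow the canonical survey layout;
    other sizes are allocated proportionally (largest remainder).
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    total = sum(c for _, _, c in _TAXON_BLOCKS)
    raw = [n_genomes * c / total for _, _, c in _TAXON_BLOCKS]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True
    )
    for i in remainders[: n_genomes - sum(counts)]:
        counts[i] += 1
    entries = []
    g = 0
    for (taxon, subtaxon, _), count in zip(_TAXON_BLOCKS, counts):
        for _ in range(count):
            g += 1
            entries.append(
                ManifestEntry(f"g{g:03d}", f"Synthetic species {g:03d}", taxon, subtaxon)
            )
    return GenomeManifest(tuple(entries), query_genome_id="g001")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-module score matrix.

    Defaults reproduce the standard recovery fixture: 100 proteins over
    86 genomes, one co-evolving module of 5 with within-module profile
    correlation 0.9, everything else background.
    """

    n_proteins: int = 100
    n_genomes: int = 86
    module_sizes: tuple[int, ...] = (5,)
    within_module_r: float = 0.9
    presence_prob: float = 0.85
    score_range: tuple[float, float] = (50.0, 1000.0)
    species_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("module sizes exceed n_proteins")
        if not 0 < self.within_module_r <= 1:
            raise ValueError("within_module_r must be in (0, 1]")
        if not 0 < self.presence_prob <= 1:
            raise ValueError("presence_prob must be in (0, 1]")
        if self.score_range[0] < 0 or self.score_range[1] <= self.score_range[0]:
            raise ValueError("score_range must be (min, max) with 0 <= min < max")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_correlated_pair(
    n: int, target_r: float, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two length-n vectors from a bivariate normal with correlation r.

    The sample correlation fluctuates around ``target_r`` with standard
    deviation about (1 - r^2)/sqrt(n).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, target_r * z1 + np.sqrt(1 - target_r**2) * z2


def _latent_pattern(
    rng: np.random.Generator,
    blocks: list[tuple[str, str, int, int]],
    n_genomes: int,
    presence_prob: float,
    noise_sd: float,
) -> np.ndarray:
    """One clade-structured conservation pattern in [0, 1]; NaN = lost.

    Each subtaxon clade is either retained (with a clade-level base
    conservation) or lost wholesale; retained species jitter around the
    clade base.
    """
    u = np.full(n_genomes, np.nan)
    for _, _, start, stop in blocks:
        if rng.random() < presence_prob:
            base = rng.uniform(0.15, 0.95)
            vals = base + noise_sd * rng.standard_normal(stop - start)
            u[start:stop] = np.clip(vals, 0.02, 1.0)
    return u


def generate_module_matrix(
    spec: FixtureSpec,
) -> tuple[pd.DataFrame, pd.Series, GenomeManifest]:
    """Raw score matrix with planted co-evolving modules.

    Module members share a latent clade presence/divergence pattern; the
    member-level noise is sized so that two members' conservation values
    correlate at roughly ``within_module_r`` (exactly identical profiles
    at r = 1).  Background proteins follow independent patterns.  Scores
    are the latent conservation times a per-protein self-score drawn from
    the upper part of ``score_range``; the query-genome column holds the
    self-score itself.

    Returns the matrix, a per-protein module label Series (-1 for
    background) and the manifest.
    """
    manifest = synthetic_manifest(spec.n_genomes)
    blocks = manifest.subtaxon_blocks()
    n_g = len(manifest)
    protein_ids = [f"P{i + 1:04d}" for i in range(spec.n_proteins)]
    labels = pd.Series(-1, index=pd.Index(protein_ids, name="protein_id"))

    rng_latent = _substream(spec.seed, 1)
    rng_member = _substream(spec.seed, 2)
    rng_scores = _substream(spec.seed, 3)

    smin, smax = spec.score_range
    conservation = np.empty((spec.n_proteins, n_g))
    row = 0
    for m, size in enumerate(spec.module_sizes):
        latent = _latent_pattern(
            rng_latent, blocks, n_g, spec.presence_prob, spec.species_noise_sd
        )
        present = ~np.isnan(latent)
        r = spec.within_module_r
        if r >= 1.0:
            member_sd = 0.0
        else:
            # v = latent + e with var(e) chosen so corr(v1, v2) = r.
            member_sd = float(np.nanstd(latent)) * np.sqrt((1 - r) / r)
        for _ in range(size):
            v = latent + member_sd * rng_member.standard_normal(n_g)
            v[present] = np.clip(v[present], 0.02, 1.0)
            conservation[row] = v
            labels.iloc[row] = m
            row += 1
    for _ in range(spec.n_proteins - row):
        conservation[row] = _latent_pattern(
            rng_latent, blocks, n_g, spec.presence_prob, spec.species_noise_sd
        )
        row += 1

    self_scores = rng_scores.uniform(0.4 * smax + 0.6 * smin, smax, spec.n_proteins)
    scores = conservation * self_scores[:, None]
    qcol = manifest.genome_ids.index(manifest.query_genome_id)
    scores[:, qcol] = self_scores  # self-score always present
    matrix = pd.DataFrame(
        scores, index=pd.Index(protein_ids, name="protein_id"),
        columns=manifest.genome_ids,
    )
    return matrix, labels, manifest


def write_toy_blast_files(
    matrix: pd.DataFrame,
    manifest: GenomeManifest,
    out_dir: str | Path,
    decoy_fraction: float = 0.3,
    seed: int = 0,
) -> list[Path]:
    """Write one 12-column BLAST tabular file per genome.

    Parsing the files back through top-hit selection reproduces
    ``matrix`` exactly (full-precision scores).  A fraction of cells also
    gets a decoy sub-optimal hit line at a strictly lower score, to
    exercise top-hit selection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _substream(seed, 99)
    paths = []
    for g in manifest.genome_ids:
        path = out_dir / f"{g}.tsv"
        with open(path, "w") as fh:
            fh.write("# synthetic BLASTP tabular output (outfmt 6)\n")
            col = matrix[g]
            for pid, score in col.items():
                if pd.isna(score):
                    continue
                lines = [(f"{g}_{pid}_best", float(score))]
                if score > 0 and rng.random() < decoy_fraction:
                    lines.append((f"{g}_{pid}_decoy", float(score) * 0.6))
                for sid, s in lines:
                    fh.write(
                        f"{pid}\t{sid}\t55.0\t100\t10\t1\t1\t100\t1\t100\t"
                        f"1e-20\t{s!r}\n"
                    )
        paths.append(path)
    return paths
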