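import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phyloprofile import (
    FixtureSpec,
    GenomeManifest,
    ManifestEntry,
    NPPNormalizer,
    generate_module_matrix,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_manifest() -> GenomeManifest:
    """Four genomes over two taxa; g1 is the query genome."""
    return GenomeManifest(
        (
            ManifestEntry("g1", "Species one", "Animals", "Vertebrates"),
            ManifestEntry("g2", "Species two", "Animals", "Insects"),
            ManifestEntry("g3", "Species three", "Fungi", "Ascomycetes"),
            ManifestEntry("g4", "Species four", "Fungi", "Basidiomycetes"),
        ),
        query_genome_id="g1",
    )


@pytest.fixture
def raw_small(tiny_manifest) -> pd.DataFrame:
    """3 proteins x 4 genomes with one missing cell; self-scores in g1."""
    return pd.DataFrame(
        {
            "g1": [200.0, 100.0, 400.0],
            "g2": [100.0, 80.0, np.nan],
            "g3": [60.0, 50.0, 300.0],
            "g4": [50.0, np.nan, 100.0],
        },
        index=pd.Index(["p1", "p2", "p3"], name="protein_id"),
    )


@pytest.fixture(scope="session")
def module_fixture():
    """The standard planted-module dataset: 5-protein module, 95 background.

    Returns (raw matrix, module labels, manifest, fitted normalizer,
    Z-matrix); shared across tests since it is deterministic.
    """
    spec = FixtureSpec(seed=0)
    matrix, labels, manifest = generate_module_matrix(spec)
    norm = NPPNormalizer(manifest)
    zmatrix = norm.fit_transform(matrix)
    return matrix, labels, manifest, norm, zmatrix
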