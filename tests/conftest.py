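import numpy as np
import pytest

from rotastoich.synthetic import (
    CountSpec,
    LatentSpec,
    SyntheticConfig,
    generate_count_matrix,
    generate_latent_dataset,
)


@pytest.fixture(scope="session")
def recovery_count_matrix():
    """40 taxa x 200 samples with one planted basis correlation of 0.9."""
    cov = np.eye(40)
    cov[0, 1] = cov[1, 0] = 0.9
    cfg = SyntheticConfig(
        seed=2024,
        treatments=("A",),
        count_spec=CountSpec(
            n_taxa=40, read_depth=2000, log_cov=cov, n_samples_per_treatment=200
        ),
    )
    return generate_count_matrix(cfg)


@pytest.fixture(scope="session")
def latent_recovery_dataset():
    """Two 3-indicator blocks, one true path of 0.8, loadings 0.9, n=500."""
    spec = LatentSpec(
        latents=["X", "Y"],
        blocks={"X": ["x1", "x2", "x3"], "Y": ["y1", "y2", "y3"]},
        loadings={k: 0.9 for k in ("x1", "x2", "x3", "y1", "y2", "y3")},
        paths={("Y", "X"): 0.8},
        n_samples=500,
    )
    return generate_latent_dataset(SyntheticConfig(seed=7, latent_spec=spec))
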