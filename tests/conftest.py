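import numpy as np
import pytest

from combfish.codebook import assign_dye_sequences
from combfish.crosstalk import CrosstalkMatrix
from combfish.genecall import build_gene_codes
from combfish.pipeline import TileImageSet, run_pipeline
from combfish.simulate import SimulationConfig, simulate_experiment


def bleed_matrix(n: int = 7, bleed: float = 0.2) -> np.ndarray:
    """Deterministic channel-dominant crosstalk with adjacent-channel leak."""
    C = np.eye(n)
    for d in range(n):
        for nb in (d - 1, d + 1):
            if 0 <= nb < n:
                C[nb, d] = bleed
    return C / np.linalg.norm(C, axis=0)


@pytest.fixture(scope="session")
def small_codebook():
    return assign_dye_sequences([f"g{i:02d}" for i in range(30)])


@pytest.fixture(scope="session")
def small_codes(small_codebook):
    return build_gene_codes(small_codebook, CrosstalkMatrix(bleed_matrix()))


@pytest.fixture(scope="session")
def default_experiment():
    """The default-condition synthetic experiment used by end-to-end tests."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_pipeline_run(default_experiment, tmp_path_factory):
    out = tmp_path_factory.mktemp("e2e")
    images = TileImageSet.from_simulation(default_experiment)
    result = run_pipeline(images, default_experiment.codebook, out_dir=out)
    return result
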