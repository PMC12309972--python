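import numpy as np
import pytest

from ssnetkit.io_formats import ExpressionMatrix
from ssnetkit.sweet import SampleNetwork
from ssnetkit.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with simple structure (no zero variance)."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],   # perfectly correlated with gene A
            [4.0, 3.0, 2.0, 1.0],   # perfectly anti-correlated
        ]
    )
    return ExpressionMatrix(["GA", "GB", "GC"], ["S1", "S2", "S3", "S4"], values)


@pytest.fixture
def random_expr() -> ExpressionMatrix:
    """10 samples x 50 genes with a planted co-expressed module, so the
    thresholded networks are non-empty (oracle-equivalence fixture)."""
    rng = np.random.default_rng(42)
    values = rng.standard_normal((50, 10))
    factor = rng.standard_normal(10)
    values[:10] = 0.8 * factor + 0.6 * rng.standard_normal((10, 10))
    return ExpressionMatrix(
        [f"G{i:02d}" for i in range(50)], [f"S{i}" for i in range(10)], values
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small strong-effect synthetic cohort shared across tests."""
    cfg = SyntheticConfig(
        n_samples=40, n_genes=120, n_blocks=1, block_size=25,
        planted_set_size=12, n_decoy_sets=5, seed=7,
    )
    return generate_cohort(cfg)


def make_network(edges: dict[tuple[str, str], tuple[float, float]], n_genes: int,
                 sample_id: str = "S") -> SampleNetwork:
    return SampleNetwork(sample_id=sample_id, edges=edges, n_genes=n_genes)
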