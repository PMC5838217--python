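import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_expression():
    from lprp.expression_io import ExpressionMatrix

    values = np.array([
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [10.0, 10.0, 10.0, 10.0, 10.0],
        [5.0, 4.0, 3.0, 2.0, 1.0],
    ])
    return ExpressionMatrix(["A", "B", "C"], ["s1", "s2", "s3", "s4", "s5"], values)


def random_discretized(rng, n_genes, n_samples, prefix="G"):
    from lprp.discretization import DiscretizedMatrix

    states = rng.integers(-1, 2, size=(n_genes, n_samples)).astype(np.int8)
    return DiscretizedMatrix([f"{prefix}{i:03d}" for i in range(n_genes)],
                             [f"S{j:03d}" for j in range(n_samples)], states)
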