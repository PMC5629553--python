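import numpy as np
import pytest

from modscan import ExpressionMatrix, ScreenConfig, run_screen
from modscan.synthdata import SyntheticSpec, benchmark_spec, generate


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 16 samples, deterministic values."""
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        ["gA", "gB", "gC"],
        [f"s{i}" for i in range(16)],
        rng.standard_normal((3, 16)),
    )


@pytest.fixture(scope="session")
def indep_matrix() -> ExpressionMatrix:
    """25 independent Gaussian genes over 60 samples (no planted structure)."""
    E, _, _ = generate(SyntheticSpec(n_genes=25, n_samples=60, seed=5))
    return E


@pytest.fixture(scope="session")
def benchmark_data():
    """The standard recovery benchmark matrix plus its ground truth."""
    spec = benchmark_spec(seed=42)
    E, manifest, strata = generate(spec)
    return E, manifest, strata


@pytest.fixture(scope="session")
def benchmark_config() -> ScreenConfig:
    # 1e-3 at 1000 permutations <=> "observed exceeds every null value",
    # the analogue of 1e-4 at 10,000 permutations under the add-one rule.
    return ScreenConfig(n_perm=1000, seed=7, empirical_cutoff=1e-3)


@pytest.fixture(scope="session")
def benchmark_screen(benchmark_data, benchmark_config):
    E, _, _ = benchmark_data
    return run_screen(E, benchmark_config)
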