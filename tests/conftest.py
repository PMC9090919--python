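import numpy as np
import pandas as pd
import pytest

from mutexome import ExpressionMatrix, SynthConfig, gen_expression, gen_genotypes


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(n_samples_per_cohort=400, n_genes=300, seed=11)


@pytest.fixture(scope="session")
def genotypes(small_cfg):
    return gen_genotypes(small_cfg)


@pytest.fixture(scope="session")
def expression_with_planted(small_cfg, genotypes):
    return gen_expression(small_cfg, genotypes)


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    """50 genes x 12 samples of seeded Gaussian log-intensities."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.normal(6, 1, size=(50, 12)),
        index=[f"g{i:02d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
    return ExpressionMatrix(data, "log_intensity")
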