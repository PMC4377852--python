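import numpy as np
import pandas as pd
import pytest

from immunoscape.matrix import ExpressionMatrix
from immunoscape.synthetic import SyntheticConfig, generate_reference_profiles


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def reference(default_config):
    expr, gt = generate_reference_profiles(default_config)
    return expr, gt


@pytest.fixture
def tiny_labeled_matrix() -> ExpressionMatrix:
    """3 cell types x 4 replicates, 6 genes, deterministic values."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"{t}_r{j}" for t in "ABC" for j in range(4)]
    labels = {s: s[0] for s in samples}
    vals = rng.uniform(1, 5, size=(6, 12))
    vals[0, :4] += 20  # g0 is an A marker
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=samples), labels, "linear"
    )
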