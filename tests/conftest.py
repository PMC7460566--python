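import numpy as np
import pytest

from profilex import ExpressionDataset, SampleLabels, SynthConfig, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 samples x 5 genes with deliberately varied gene profiles."""
    values = np.array(
        [
            [1.0, 2.0, 5.0, 0.1, 3.0],
            [2.0, 1.5, 5.0, 0.2, 6.0],
            [3.0, 1.0, 5.0, 0.1, 2.0],
            [4.0, 0.5, 5.0, 0.2, 7.0],
        ]
    )
    return ExpressionDataset(
        values, [f"s{i}" for i in range(4)], [f"g{j}" for j in range(5)]
    )


@pytest.fixture
def tiny_labels(tiny_dataset) -> SampleLabels:
    return SampleLabels({"s0": 0, "s1": 1, "s2": 0, "s3": 1})


@pytest.fixture(scope="session")
def default_synth():
    """One draw of the default generator, shared across tests."""
    return generate(SynthConfig(seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
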