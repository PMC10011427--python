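import numpy as np
import pytest

from dricluster.dataset import FeatureTable, VariableSpec


@pytest.fixture(scope="session")
def env_table():
    from dricluster.dataset import environment_fixture

    return environment_fixture()


def make_numeric_table(values: np.ndarray) -> FeatureTable:
    values = np.asarray(values, dtype=float)
    schema = [VariableSpec(name=f"x{j}", kind="numeric") for j in range(values.shape[1])]
    return FeatureTable(
        objects=tuple(str(i + 1) for i in range(values.shape[0])),
        values=values,
        schema=tuple(schema),
    )


def random_numeric_table(rng: np.random.Generator, n: int, p: int) -> FeatureTable:
    return make_numeric_table(rng.random((n, p)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
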