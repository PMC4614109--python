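import numpy as np
import pytest

from elmqsar import (
    LabeledDataset,
    SyntheticConfig,
    generate,
    generate_worked_example,
    standardize,
)


@pytest.fixture(scope="session")
def worked_example():
    """Tiny constant dataset (n=12, p=4) with hand-computable slopes."""
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_synth():
    """Default-condition synthetic dataset, seed 1."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_synth_standardized(small_synth):
    dataset, truth = small_synth
    zmat, stats = standardize(dataset.matrix)
    return LabeledDataset(zmat, dataset.labels.copy()), truth


@pytest.fixture()
def class_csv(tmp_path):
    """A 3-row CSV with string labels."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "COMPOUND,CLASS,D1,D2\n"
        "c1,active,0.5,1.0\n"
        "c2,inactive,1.5,2.0\n"
        "c3,active,-0.5,0.0\n"
    )
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
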