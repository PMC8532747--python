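import pandas as pd
import pytest

from broilerenv import (
    default_generator_config,
    generate_records,
    label_dataset,
    load_weight_config,
)


@pytest.fixture(scope="session")
def cfg():
    """Canonicalized default weight tables."""
    return load_weight_config()


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shape synthetic dataset (2496 rows), fixed seed."""
    return generate_records(default_generator_config(seed=11))


@pytest.fixture(scope="session")
def labeled_default(cfg, default_dataset) -> pd.DataFrame:
    """Default dataset scored end to end."""
    return label_dataset(cfg, default_dataset.records)
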