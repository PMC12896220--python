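import numpy as np
import pandas as pd
import pytest

from glnet.encoding import (
    apply_standardizer,
    encode_dataset,
    fit_standardizer,
    split_dataset,
)
from glnet.model import GLNetConfig, init_model
from glnet.schema import Factor, FactorSchema
from glnet.synthetic import default_sdd_like_spec, generate


@pytest.fixture(scope="session")
def toy_schema() -> FactorSchema:
    """Two numeric, one ordinal, one binary, two categorical factors."""
    return FactorSchema((
        Factor("age", "numeric"),
        Factor("cgpa", "numeric"),
        Factor("pressure", "ordinal"),
        Factor("suicidal", "binary", ("No", "Yes")),
        Factor("city", "categorical", ("A", "B", "C", "D")),
        Factor("diet", "categorical", ("Healthy", "Junk", "Mixed", "Poor", "Vegan")),
    ))


@pytest.fixture(scope="session")
def toy_records(toy_schema) -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 40
    df = pd.DataFrame({
        "age": rng.integers(18, 30, n).astype(float),
        "cgpa": np.round(rng.uniform(5, 10, n), 2),
        "pressure": rng.integers(1, 6, n).astype(float),
        "suicidal": rng.choice(["No", "Yes"], n),
        "city": rng.choice(list("ABCD"), n),
        "diet": rng.choice(["Healthy", "Junk", "Mixed", "Poor", "Vegan"], n),
    })
    df["depression"] = rng.integers(0, 2, n)
    return df


@pytest.fixture(scope="session")
def tiny_model():
    """A small seeded model for shape/determinism tests."""
    cfg = GLNetConfig(input_dim=12, embed_dim=16, ssm_state_dim=4, seed=3)
    return init_model(cfg)


@pytest.fixture(scope="session")
def sdd_spec():
    return default_sdd_like_spec()


@pytest.fixture(scope="session")
def synthetic_run(sdd_spec):
    """A small standardized synthetic dataset with its split (no training)."""
    df, truth = generate(sdd_spec, 1200, seed=11)
    ds = encode_dataset(df, sdd_spec.schema)
    split = split_dataset(ds, seed=5)
    std = fit_standardizer(ds, split.train)
    return df, truth, apply_standardizer(ds, std), split, std
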