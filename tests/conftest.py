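import numpy as np
import pandas as pd
import pytest

from gainimpute import (
    IncompleteTable,
    TableSchema,
    VariableSchema,
    ampute,
    demo_correlated_spec,
    draw_mechanism,
    generate,
)


@pytest.fixture
def tiny_schema() -> TableSchema:
    return TableSchema(
        [
            VariableSchema("sbp", "continuous"),
            VariableSchema("glucose", "continuous"),
            VariableSchema("smoker", "categorical", categories=("no", "yes")),
            VariableSchema(
                "death", "categorical", categories=("no", "yes"), role="dependent"
            ),
        ]
    )


@pytest.fixture
def tiny_complete(tiny_schema) -> IncompleteTable:
    df = pd.DataFrame(
        {
            "sbp": [100.0, 140.0, 180.0, 120.0, 160.0],
            "glucose": [4.0, 5.5, 7.0, 6.25, 4.75],
            "smoker": ["no", "yes", "no", "no", "yes"],
            "death": ["no", "no", "yes", "no", "yes"],
        }
    )
    return IncompleteTable.complete(df, tiny_schema)


@pytest.fixture
def tiny_incomplete(tiny_complete) -> IncompleteTable:
    mask = tiny_complete.mask.copy()
    mask[1, 0] = False  # sbp row 1
    mask[4, 1] = False  # glucose row 4
    mask[2, 2] = False  # smoker row 2
    return tiny_complete.with_mask(mask)


def random_incomplete(seed: int, n: int = 40, miss: float = 0.25) -> IncompleteTable:
    """Random small mixed-type table with MCAR holes in independent columns."""
    rng = np.random.default_rng(seed)
    n_cont = int(rng.integers(1, 4))
    n_cat = int(rng.integers(1, 3))
    variables = []
    df = pd.DataFrame(index=range(n))
    for i in range(n_cont):
        name = f"x{i}"
        variables.append(VariableSchema(name, "continuous"))
        df[name] = rng.normal(rng.uniform(-50, 50), rng.uniform(0.5, 20), size=n)
    for i in range(n_cat):
        name = f"c{i}"
        k = int(rng.integers(2, 5))
        cats = tuple(f"lvl{j}" for j in range(k))
        variables.append(VariableSchema(name, "categorical", categories=cats))
        df[name] = rng.choice(np.asarray(cats, object), size=n)
    variables.append(
        VariableSchema("outcome", "categorical", categories=("no", "yes"),
                       role="dependent")
    )
    df["outcome"] = rng.choice(np.asarray(("no", "yes"), object), size=n)
    table = IncompleteTable.complete(df, TableSchema(variables))
    mask = np.ones((n, len(variables)), dtype=bool)
    mask[:, : n_cont + n_cat] = rng.random((n, n_cont + n_cat)) >= miss
    # keep every column scorable/encodable: >= 3 observed values
    for j in range(n_cont + n_cat):
        obs = np.flatnonzero(mask[:, j])
        if len(obs) < 3:
            mask[rng.choice(n, size=3, replace=False), j] = True
    return table.with_mask(mask)


@pytest.fixture(scope="session")
def demo_table() -> IncompleteTable:
    """Strongly equicorrelated complete table (n=500) for training tests."""
    return generate(demo_correlated_spec(n=500, seed=7))


@pytest.fixture(scope="session")
def demo_incomplete(demo_table) -> IncompleteTable:
    mech = draw_mechanism(demo_table, 0.2, rng_seed=11)
    return ampute(demo_table, mech, rng_seed=12)
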