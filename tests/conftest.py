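import numpy as np
import pandas as pd
import pytest

from ebca.data import MixedTable, VariableSpec
from ebca.rules import parse_rules

CASE_META = {
    "GAFCLA": "numeric",
    "GAFSOCIAL": "numeric",
    "MAXECFOS_A": "numeric",
    "MAXECFOS_B": "categorical",
    "INGRESE": "categorical",
}

R1 = ("r1: if ((GAFCLA < 40) or (GAFSOCIAL < 40)) "
      "and ((MAXECFOS_A > 15) and (MAXECFOS_B = Every_Day)) then severely-ill")
R2 = ("r2: if (INGRESE = WORK) and ((GAFCLA > 70) or (GAFSOCIAL > 70)) "
      "then good-condition")


@pytest.fixture
def case_meta():
    return dict(CASE_META)


@pytest.fixture
def case_kb(case_meta):
    return parse_rules(f"{R1}\n{R2}\n", case_meta)


@pytest.fixture
def patient_specs():
    return [
        VariableSpec("GAFCLA", "numeric"),
        VariableSpec("GAFSOCIAL", "numeric"),
        VariableSpec("MAXECFOS_A", "numeric"),
        VariableSpec("MAXECFOS_B", "categorical",
                     categories=["Every_Day", "Sometimes", "Never"]),
        VariableSpec("INGRESE", "categorical",
                     categories=["WORK", "PENSION", "NONE"]),
    ]


def make_numeric_table(values: dict, ids=None) -> MixedTable:
    """Build a numeric-only MixedTable from {name: list} columns."""
    n = len(next(iter(values.values())))
    ids = ids or [f"u{i}" for i in range(n)]
    specs = [VariableSpec(name, "numeric") for name in values]
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()},
                      index=pd.Index(ids, name="id"))
    return MixedTable(df, specs)


@pytest.fixture
def numeric_table_factory():
    return make_numeric_table


def random_mixed_table(rng, n, n_num=2, n_cat=1, missing_rate=0.0) -> MixedTable:
    """Small random mixed table for property tests."""
    specs = [VariableSpec(f"x{i}", "numeric") for i in range(n_num)]
    cats = ["a", "b", "c"]
    specs += [VariableSpec(f"c{i}", "categorical", categories=cats)
              for i in range(n_cat)]
    data = {}
    for i in range(n_num):
        col = rng.normal(size=n) * (1 + i)
        if missing_rate:
            col[rng.random(n) < missing_rate] = np.nan
        data[f"x{i}"] = col
    for i in range(n_cat):
        col = rng.choice(cats, size=n).astype(object)
        if missing_rate:
            col[rng.random(n) < missing_rate] = None
        data[f"c{i}"] = col
    df = pd.DataFrame(data, index=pd.Index([f"r{j}" for j in range(n)], name="id"))
    return MixedTable(df, specs)


@pytest.fixture
def mixed_table_factory():
    return random_mixed_table
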