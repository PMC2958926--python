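"""Mixed-type tabular data model and readers.

Tables are CSV (comma separated, UTF-8, '.' decimal, ``NA``/empty = missing)
with the unit id in the first column.  A metadata sidecar (YAML or JSON)
declares each variable's kind, role, units, weight and — for categoricals —
the admissible category set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "MixedTable",
    "Distribution",
    "StochasticSpec",
    "read_metadata",
    "read_table",
    "summarize",
    "correlation_report",
    "read_stochastic_spec",
]

MISSING_TOKENS = {"", "NA"}

VALID_KINDS = ("numeric", "categorical")
VALID_ROLES = ("dea-input", "dea-output", "descriptive")


@dataclass
class VariableSpec:
    name: str
    kind: str
    role: str = "descriptive"
    units: str = ""
    weight: float = 1.0
    categories: Optional[list[str]] = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"{self.name}: kind must be one of {VALID_KINDS}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"{self.name}: role must be one of {VALID_ROLES}")
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"{self.name}: categorical variable needs categories")
        if self.kind == "numeric" and self.categories:
            raise ValueError(f"{self.name}: numeric variable cannot list categories")

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "role": self.role}
        if self.units:
            d["units"] = self.units
        if self.weight != 1.0:
            d["weight"] = self.weight
        if self.categories:
            d["categories"] = list(self.categories)
        return d


class MixedTable:
    """Rectangular units x variables table with explicit missing markers.

    Numeric cells are floats (NaN = missing); categorical cells are strings
    (None = missing).  Backed by a pandas DataFrame indexed by unit id.
    """

    def __init__(self, df: pd.DataFrame, variables: Sequence[VariableSpec]):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if list(df.columns) != names:
            raise ValueError("dataframe columns must match variable specs in order")
        if df.index.has_duplicates:
            raise ValueError("unit ids must be unique")
        self.df = df
        self.variables = list(variables)
        self.specs = {v.name: v for v in variables}
        for spec in self.variables:
            col = df[spec.name]
            if spec.kind == "numeric":
                values = col.to_numpy(dtype=float)
                if np.isinf(values).any():
                    raise ValueError(f"{spec.name}: non-finite numeric cell")
            else:
                bad = sorted(
                    {v for v in col.dropna() if v not in spec.categories}
                )
                if bad:
                    raise ValueError(
                        f"{spec.name}: undeclared categories {bad}; "
                        f"declared: {spec.categories}"
                    )

    # -- basic accessors ---------------------------------------------------

    @property
    def unit_ids(self) -> list:
        return list(self.df.index)

    @property
    def n_units(self) -> int:
        return len(self.df)

    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "numeric"]

    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "categorical"]

    def column(self, name: str) -> pd.Series:
        return self.df[name]

    def records(self) -> Iterator[tuple[object, dict]]:
        """Yield (unit id, {variable: value}) with missing cells as None/NaN."""
        for uid, row in self.df.iterrows():
            yield uid, row.to_dict()

    def subset(self, ids: Iterable) -> "MixedTable":
        return MixedTable(self.df.loc[list(ids)], self.variables)

    def select(self, names: Sequence[str]) -> "MixedTable":
        specs = [self.specs[n] for n in names]
        return MixedTable(self.df[list(names)], specs)

    # -- io ----------------------------------------------------------------

    def to_csv(self, path: Union[str, Path], id_column: str = "id") -> None:
        out = self.df.copy()
        out.index.name = id_column
        out.to_csv(path, na_rep="NA")

    def metadata_dict(self) -> list[dict]:
        return [v.to_dict() for v in self.variables]

    def write_metadata(self, path: Union[str, Path]) -> None:
        path = Path(path)
        payload = {"variables": self.metadata_dict()}
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_metadata(source: Union[str, Path, Mapping, Sequence]) -> list[VariableSpec]:
    """Load variable declarations from YAML/JSON path, mapping or list."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        data = yaml.safe_load(text)
    else:
        data = source
    if isinstance(data, Mapping):
        data = data.get("variables", data)
    specs = []
    for entry in data:
        if isinstance(entry, VariableSpec):
            specs.append(entry)
        else:
            specs.append(VariableSpec(**entry))
    return specs


def read_table(path: Union[str, Path],
               metadata: Union[str, Path, Sequence, Mapping]) -> MixedTable:
    """Read a CSV table against declared variable metadata.

    The first CSV column is the unit id.  Empty cells and ``NA`` are missing.
    Unparseable numeric cells and undeclared columns are errors that name the
    offending cell.
    """
    specs = read_metadata(metadata)
    by_name = {s.name: s for s in specs}
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError("table needs an id column plus at least one variable")
    id_col = raw.columns[0]
    undeclared = [c for c in raw.columns[1:] if c not in by_name]
    if undeclared:
        raise ValueError(f"undeclared columns in {path}: {undeclared}")
    missing_cols = [s.name for s in specs if s.name not in raw.columns]
    if missing_cols:
        raise ValueError(f"declared variables absent from {path}: {missing_cols}")
    raw = raw.set_index(id_col)
    columns = {}
    for spec in specs:
        col = raw[spec.name]
        if spec.kind == "numeric":
            parsed = []
            for uid, cell in col.items():
                cell = cell.strip()
                if cell in MISSING_TOKENS:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"unparseable numeric cell at row {uid!r}, "
                        f"column {spec.name!r}: {cell!r}"
                    ) from None
            columns[spec.name] = pd.Series(parsed, index=raw.index, dtype=float)
        else:
            cleaned = col.str.strip().where(~col.str.strip().isin(MISSING_TOKENS), None)
            columns[spec.name] = cleaned
    df = pd.DataFrame(columns, index=raw.index)[[s.name for s in specs]]
    return MixedTable(df, specs)


# ---------------------------------------------------------------------------
# descriptive statistics


def summarize(table: MixedTable, outlier_fence: float = 1.5) -> dict:
    """Descriptive report: per-numeric stats with Tukey-fence outlier flags,
    per-categorical frequency tables.  Flags only; nothing is removed."""
    report: dict = {"numeric": {}, "categorical": {}, "warnings": []}
    for spec in table.variables:
        col = table.df[spec.name]
        if spec.kind == "numeric":
            values = col.to_numpy(dtype=float)
            present = values[~np.isnan(values)]
            entry: dict = {"n": int(present.size),
                           "missing": int(np.isnan(values).sum())}
            if present.size == 0:
                report["warnings"].append(f"{spec.name}: all values missing")
                report["numeric"][spec.name] = entry
                continue
            q1, q2, q3 = np.percentile(present, [25, 50, 75])
            iqr = q3 - q1
            lo_fence = q1 - outlier_fence * iqr
            hi_fence = q3 + outlier_fence * iqr
            outlier_ids = [
                uid for uid, v in col.items()
                if not np.isnan(v) and (v < lo_fence or v > hi_fence)
            ]
            entry.update(
                mean=float(present.mean()),
                sd=float(present.std(ddof=1)) if present.size > 1 else 0.0,
                min=float(present.min()),
                q1=float(q1), median=float(q2), q3=float(q3),
                max=float(present.max()),
                outliers=outlier_ids,
            )
            report["numeric"][spec.name] = entry
        else:
            counts = col.value_counts(dropna=True).to_dict()
            report["categorical"][spec.name] = {
                "n": int(col.notna().sum()),
                "missing": int(col.isna().sum()),
                "frequencies": {str(k): int(v) for k, v in counts.items()},
            }
    return report


def correlation_report(table: MixedTable, threshold: float = 0.9) -> pd.DataFrame:
    """Pairwise Pearson correlations of numeric variables with a redundancy
    flag at ``|r| >= threshold``; feeds scenario pruning, never deletes."""
    names = table.numeric_names()
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x = table.df[a].to_numpy(dtype=float)
            y = table.df[b].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"var_a": a, "var_b": b, "pearson": r,
                         "redundant": bool(abs(r) >= threshold) if not np.isnan(r) else False})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "pearson", "redundant"])


# ---------------------------------------------------------------------------
# stochastic specification


@dataclass(frozen=True)
class Distribution:
    """Sampling model for one cell: uniform[a,b], triangular[a,m,b] or
    point-mass[v]."""

    family: str
    params: tuple

    def __post_init__(self):
        if self.family == "uniform":
            a, b = self.params
            if b < a:
                raise ValueError(f"uniform bounds out of order: [{a}, {b}]")
        elif self.family == "triangular":
            a, m, b = self.params
            if not (a <= m <= b):
                raise ValueError(f"triangular params out of order: [{a}, {m}, {b}]")
        elif self.family == "point-mass":
            if len(self.params) != 1:
                raise ValueError("point-mass takes a single value")
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "uniform":
            a, b = self.params
            if a == b:
                return np.full(size, a) if size else a
            return rng.uniform(a, b, size=size)
        if self.family == "triangular":
            a, m, b = self.params
            if a == b:
                return np.full(size, a) if size else a
            return rng.triangular(a, m, b, size=size)
        v = self.params[0]
        return np.full(size, v) if size else v

    @classmethod
    def parse(cls, obj) -> "Distribution":
        """Accept {'uniform': [a,b]}, {'family': 'uniform', 'params': [a,b]},
        or a bare number (point mass)."""
        if isinstance(obj, Distribution):
            return obj
        if isinstance(obj, (int, float)):
            return cls("point-mass", (float(obj),))
        if isinstance(obj, Mapping):
            if "family" in obj:
                return cls(obj["family"], tuple(float(p) for p in obj["params"]))
            if len(obj) == 1:
                family, params = next(iter(obj.items()))
                if isinstance(params, (int, float)):
                    params = [params]
                return cls(family, tuple(float(p) for p in params))
        raise ValueError(f"cannot interpret distribution spec {obj!r}")


@dataclass
class StochasticSpec:
    """(unit, variable) -> Distribution, covering every DEA-role variable."""

    entries: dict = field(default_factory=dict)

    def distribution(self, unit, variable) -> Distribution:
        return self.entries[(unit, variable)]

    def sample_matrix(self, units: Sequence, variables: Sequence[str],
                      rng: np.random.Generator) -> np.ndarray:
        out = np.empty((len(units), len(variables)))
        for i, u in enumerate(units):
            for j, v in enumerate(variables):
                out[i, j] = self.entries[(u, v)].sample(rng)
        return out

    def validate_coverage(self, units: Sequence, variables: Sequence[str]) -> None:
        missing = [(u, v) for u in units for v in variables
                   if (u, v) not in self.entries]
        if missing:
            raise ValueError(f"stochastic spec misses entries for: {missing[:10]}")


def read_stochastic_spec(source: Union[str, Path, Mapping],
                         table: MixedTable) -> StochasticSpec:
    """Build a StochasticSpec from YAML/JSON.

    Layout: ``defaults: {VAR: dist}`` applied to all units, overridable by
    ``units: {UNIT: {VAR: dist}}``.  Every DEA-role variable of every unit
    must end up covered.
    """
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = source
    defaults = {k: Distribution.parse(v) for k, v in (data.get("defaults") or {}).items()}
    per_unit = data.get("units") or {}
    entries = {}
    for unit in table.unit_ids:
        for var, dist in defaults.items():
            entries[(unit, var)] = dist
    for unit, overrides in per_unit.items():
        if unit not in table.df.index:
            raise ValueError(f"stochastic spec names unknown unit {unit!r}")
        for var, dist in overrides.items():
            entries[(unit, var)] = Distribution.parse(dist)
    spec = StochasticSpec(entries)
    dea_vars = [v.name for v in table.variables if v.role != "descriptive"]
    spec.validate_coverage(table.unit_ids, dea_vars)
    return spec
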