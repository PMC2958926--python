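"""Synthetic data generators: small-health-area I/O tables with a stochastic
structure, patient tables with planted mixed-type clusters, and noisy expert
rating matrices.  All generators are pure functions of (config, seed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import Distribution, MixedTable, StochasticSpec, VariableSpec
from .rules import IOAnnotation

__all__ = [
    "SHAGeneratorConfig",
    "PatientGeneratorConfig",
    "load_bmhcc_model",
    "generate_sha",
    "generate_patients",
    "generate_expert_ratings",
    "default_patient_config",
]


def load_bmhcc_model() -> tuple[dict, dict]:
    """Shipped care-model fixture: variable -> (bounds, IOAnnotation)."""
    text = resources.files("ebca.fixtures").joinpath("bmhcc.yaml").read_text()
    data = yaml.safe_load(text)
    bounds = {}
    annotations = {}
    for entry in data["variables"]:
        bounds[entry["name"]] = tuple(entry["bounds"])
        annotations[entry["name"]] = IOAnnotation(
            variable=entry["name"],
            role="input" if entry["role"] == "dea-input" else "output",
            orientation=entry["orientation"],
        )
    return bounds, annotations


@dataclass
class SHAGeneratorConfig:
    """Small-health-area generator: uniform bounds per variable, optional
    input-scaling plan marking units as planted-inefficient."""

    n_units: int = 12
    bounds: Optional[Mapping[str, tuple]] = None  # default: shipped care model
    roles: Optional[Mapping[str, str]] = None  # variable -> dea-input/dea-output
    inefficiency_plan: Mapping[str, float] = field(default_factory=dict)
    spec_half_width: float = 0.05  # relative half-width of the uniform spec

    def __post_init__(self):
        if self.bounds is None:
            fixture_bounds, annotations = load_bmhcc_model()
            self.bounds = fixture_bounds
            if self.roles is None:
                self.roles = {
                    v: ("dea-input" if a.role == "input" else "dea-output")
                    for v, a in annotations.items()
                }
        for name, (a, b) in self.bounds.items():
            if b < a:
                raise ValueError(f"{name}: bounds out of order [{a}, {b}]")
        for unit, factor in self.inefficiency_plan.items():
            if factor < 1:
                raise ValueError(f"scaling factor for {unit} must be >= 1")
        if not (0 <= self.spec_half_width < 1):
            raise ValueError("spec_half_width must lie in [0, 1)")


def generate_sha(config: SHAGeneratorConfig, seed: int
                 ) -> tuple[MixedTable, StochasticSpec, dict]:
    """Generate (table, stochastic spec, planted inefficiency labels).

    Central values are drawn uniformly within each variable's bounds; units
    in the inefficiency plan have all their input variables multiplied by
    the planned factor.  The stochastic spec puts a uniform distribution of
    the configured relative half-width around every central value.
    """
    rng = np.random.default_rng(seed)
    unit_ids = [f"SHA{i + 1:02d}" for i in range(config.n_units)]
    names = list(config.bounds)
    roles = config.roles or {}
    centre = np.empty((config.n_units, len(names)))
    for j, name in enumerate(names):
        a, b = config.bounds[name]
        centre[:, j] = rng.uniform(a, b, size=config.n_units) if b > a else a
    for unit, factor in config.inefficiency_plan.items():
        i = unit_ids.index(unit)
        for j, name in enumerate(names):
            if roles.get(name, "dea-input") == "dea-input":
                centre[i, j] *= factor
    if (centre <= 0).any():
        raise ValueError("generated non-positive central value")
    specs = [
        VariableSpec(name, "numeric", role=roles.get(name, "descriptive"))
        for name in names
    ]
    df = pd.DataFrame(centre, index=pd.Index(unit_ids, name="id"), columns=names)
    table = MixedTable(df, specs)
    entries = {}
    hw = config.spec_half_width
    for i, unit in enumerate(unit_ids):
        for j, name in enumerate(names):
            c = centre[i, j]
            if hw == 0:
                entries[(unit, name)] = Distribution("point-mass", (c,))
            else:
                entries[(unit, name)] = Distribution(
                    "uniform", (c * (1 - hw), c * (1 + hw)))
    labels = {u: u in config.inefficiency_plan for u in unit_ids}
    return table, StochasticSpec(entries), labels


# ---------------------------------------------------------------------------
# patients


@dataclass
class PatientGeneratorConfig:
    """Mixture generator for patient tables with planted clusters.

    ``numeric`` maps variable -> per-cluster (mean, sd) pairs; ``categorical``
    maps variable -> (categories, per-cluster probability rows).  Missing
    cells are masked completely at random at ``missing_rate``.
    """

    n: int
    numeric: Mapping[str, Sequence[tuple]]
    categorical: Mapping[str, tuple]
    proportions: Sequence[float]
    missing_rate: float = 0.0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("mixing proportions must sum to 1")
        k = len(self.proportions)
        for name, rows in self.numeric.items():
            if len(rows) != k:
                raise ValueError(f"{name}: need one (mean, sd) per cluster")
        for name, (cats, probs) in self.categorical.items():
            if len(probs) != k:
                raise ValueError(f"{name}: need one probability row per cluster")
            for row in probs:
                if len(row) != len(cats) or not np.isclose(sum(row), 1.0):
                    raise ValueError(f"{name}: probability rows must normalise")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def k(self) -> int:
        return len(self.proportions)


def default_patient_config(n: int = 300, missing_rate: float = 0.0,
                           separation: float = 6.0) -> PatientGeneratorConfig:
    """Three planted profiles over the case-study variables, with numeric
    means ``separation`` standard deviations apart so the rules r1/r2 of the
    shipped examples fire on distinct clusters."""
    s = separation
    return PatientGeneratorConfig(
        n=n,
        numeric={
            # cluster order: severely-ill, intermediate, good-condition
            "GAFCLA": [(30.0, 5.0), (30.0 + s * 5, 5.0), (30.0 + 2 * s * 5, 5.0)],
            "GAFSOCIAL": [(32.0, 5.0), (32.0 + s * 5, 5.0), (32.0 + 2 * s * 5, 5.0)],
            "MAXECFOS_A": [(25.0, 3.0), (25.0 - s * 3, 3.0), (25.0 - 2 * s * 3, 3.0)],
        },
        categorical={
            "MAXECFOS_B": (
                ["Every_Day", "Sometimes", "Never"],
                [[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]],
            ),
            "INGRESE": (
                ["WORK", "PENSION", "NONE"],
                [[0.05, 0.8, 0.15], [0.3, 0.5, 0.2], [0.9, 0.05, 0.05]],
            ),
        },
        proportions=[1 / 3, 1 / 3, 1 / 3],
        missing_rate=missing_rate,
    )


def generate_patients(config: PatientGeneratorConfig, seed: int
                      ) -> tuple[MixedTable, dict]:
    """Draw a patient table from the planted mixture; returns (table, truth)."""
    rng = np.random.default_rng(seed)
    assignments = rng.choice(config.k, size=config.n, p=config.proportions)
    ids = [f"P{i + 1:04d}" for i in range(config.n)]
    columns: dict = {}
    specs: list[VariableSpec] = []
    for name, rows in config.numeric.items():
        means = np.array([rows[c][0] for c in assignments])
        sds = np.array([rows[c][1] for c in assignments])
        columns[name] = means + rng.standard_normal(config.n) * sds
        specs.append(VariableSpec(name, "numeric"))
    for name, (cats, probs) in config.categorical.items():
        probs = np.asarray(probs, dtype=float)
        draws = [cats[rng.choice(len(cats), p=probs[c])] for c in assignments]
        columns[name] = draws
        specs.append(VariableSpec(name, "categorical", categories=list(cats)))
    df = pd.DataFrame(columns, index=pd.Index(ids, name="id"))
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        for j, spec in enumerate(specs):
            col = df[spec.name].to_numpy(dtype=object)
            col[mask[:, j]] = np.nan if spec.kind == "numeric" else None
            if spec.kind == "numeric":
                df[spec.name] = pd.array(col, dtype=object).astype(float)
            else:
                df[spec.name] = col
    table = MixedTable(df, specs)
    truth = {pid: int(c) for pid, c in zip(ids, assignments)}
    return table, truth


def generate_expert_ratings(true_scores: Sequence[float], noise_sd: float,
                            n_raters: int, seed: int) -> np.ndarray:
    """Units x raters matrix: each rater = true score + independent noise."""
    true_scores = np.asarray(true_scores, dtype=float)
    if true_scores.size < 2:
        raise ValueError("need at least 2 units")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((true_scores.size, n_raters)) * noise_sd
    return true_scores[:, None] + noise
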