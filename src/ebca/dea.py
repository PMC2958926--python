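"""Monte-Carlo data envelopment analysis.

Per-run pipeline: sample every (unit, variable) cell from its declared
distribution, apply the monotone-decreasing transform to non-standard
columns, then score every decision-making unit (DMU) with the envelopment
linear program.  Scores are pooled across runs until block means stabilise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .data import StochasticSpec
from .rules import IOAnnotation

__all__ = [
    "DEAInstance",
    "DEAModelConfig",
    "Scenario",
    "ConvergenceSettings",
    "EfficiencyPool",
    "TierThresholds",
    "TierClassification",
    "transform_nonstandard",
    "solve_dea",
    "run_monte_carlo",
    "classify_tiers",
    "enumerate_scenarios",
]

_SCORE_FLOOR = np.finfo(float).tiny
_POSITIVE_FLOOR = 1e-6  # floor for degenerate (zero-range) transforms


@dataclass
class DEAInstance:
    units: list
    inputs: np.ndarray  # n_units x n_inputs, strictly positive
    outputs: np.ndarray  # n_units x n_outputs, strictly positive

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        n = len(self.units)
        if n < 2:
            raise ValueError("DEA needs at least 2 units")
        if self.inputs.shape[0] != n or self.outputs.shape[0] != n:
            raise ValueError("input/output row counts must match unit count")
        if self.inputs.shape[1] < 1 or self.outputs.shape[1] < 1:
            raise ValueError("need at least one input and one output")
        if (self.inputs <= 0).any() or (self.outputs <= 0).any():
            raise ValueError("all DEA cells must be strictly positive")


@dataclass
class DEAModelConfig:
    orientation: str = "input"  # "input" | "output"
    returns_to_scale: str = "constant"  # "constant" | "variable"
    epsilon: float = 0.01  # efficiency tolerance for "scored efficient"

    def __post_init__(self):
        if self.orientation not in ("input", "output"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.returns_to_scale not in ("constant", "variable"):
            raise ValueError(f"bad returns-to-scale {self.returns_to_scale!r}")
        if not (0 < self.epsilon <= 0.05):
            raise ValueError("epsilon must lie in (0, 0.05]")


@dataclass
class Scenario:
    id: str
    inputs: list[str]
    outputs: list[str]
    provenance: str = "expert"  # "expert" | "automatic"

    def __post_init__(self):
        if not self.inputs or not self.outputs:
            raise ValueError(f"scenario {self.id}: I/O subsets must be non-empty")
        if set(self.inputs) & set(self.outputs):
            raise ValueError(f"scenario {self.id}: input/output subsets overlap")


def transform_nonstandard(column: np.ndarray,
                          annotation: IOAnnotation) -> np.ndarray:
    """Monotone decreasing linear transform for non-standard variables.

    x' = (max(x) + margin) - x with margin = margin_fraction * range(x);
    a zero-range column maps to a small positive constant floor.
    """
    if annotation.orientation != "non-standard":
        raise ValueError("transform applies to non-standard variables only")
    x = np.asarray(column, dtype=float)
    if (x <= 0).any():
        raise ValueError("non-standard transform requires positive values")
    rng = x.max() - x.min()
    if rng == 0:
        return np.full_like(x, _POSITIVE_FLOOR)
    margin = annotation.margin_fraction * rng
    return (x.max() + margin) - x


def solve_dea(instance: DEAInstance, config: DEAModelConfig, target) -> float:
    """Envelopment-form efficiency of one DMU, always reported in (0, 1].

    Input orientation: min theta s.t. X'lam <= theta*x_t, Y'lam >= y_t.
    Output orientation solves max phi analogously and reports 1/phi.
    Variable returns-to-scale adds sum(lam) = 1.
    """
    units = list(instance.units)
    t = units.index(target) if target in units else int(target)
    X = instance.inputs
    Y = instance.outputs
    n, p = X.shape
    q = Y.shape[1]
    vrs = config.returns_to_scale == "variable"

    if config.orientation == "input":
        # variables: lam (n), theta
        c = np.concatenate([np.zeros(n), [1.0]])
        a_in = np.hstack([X.T, -X[t].reshape(p, 1)])        # X'lam - theta x_t <= 0
        a_out = np.hstack([-Y.T, np.zeros((q, 1))])          # -Y'lam <= -y_t
        A_ub = np.vstack([a_in, a_out])
        b_ub = np.concatenate([np.zeros(p), -Y[t]])
        bounds = [(0, None)] * n + [(None, None)]
    else:
        # variables: lam (n), phi ; maximise phi
        c = np.concatenate([np.zeros(n), [-1.0]])
        a_in = np.hstack([X.T, np.zeros((p, 1))])            # X'lam <= x_t
        a_out = np.hstack([-Y.T, Y[t].reshape(q, 1)])        # phi y_t - Y'lam <= 0
        A_ub = np.vstack([a_in, a_out])
        b_ub = np.concatenate([X[t], np.zeros(q)])
        bounds = [(0, None)] * n + [(None, None)]

    A_eq = b_eq = None
    if vrs:
        A_eq = np.concatenate([np.ones(n), [0.0]]).reshape(1, -1)
        b_eq = [1.0]

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if not res.success:
        raise RuntimeError(f"DEA LP failed for unit {target!r}: {res.message}")
    value = res.x[-1]
    score = value if config.orientation == "input" else 1.0 / value
    return float(np.clip(score, _SCORE_FLOOR, 1.0))


def solve_all(instance: DEAInstance, config: DEAModelConfig) -> np.ndarray:
    return np.array([solve_dea(instance, config, u) for u in instance.units])


# ---------------------------------------------------------------------------
# Monte-Carlo pooling


@dataclass
class ConvergenceSettings:
    block_size: int = 500
    tolerance: float = 0.005
    max_runs: int = 20000

    def __post_init__(self):
        if self.block_size < 1 or self.max_runs < 2 * self.block_size:
            raise ValueError("need max_runs >= 2 * block_size >= 2")


@dataclass
class EfficiencyPool:
    units: list
    scores: np.ndarray  # runs x units
    seed: int
    converged: bool
    block_means: np.ndarray  # blocks x units
    epsilon: float
    resample_warnings: int = 0

    @property
    def n_runs(self) -> int:
        return self.scores.shape[0]

    def summary(self) -> pd.DataFrame:
        mean = self.scores.mean(axis=0)
        sd = self.scores.std(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(len(self.units))
        frac_eff = (self.scores >= 1.0 - self.epsilon).mean(axis=0)
        return pd.DataFrame(
            {"mean": mean, "sd": sd, "fraction_efficient": frac_eff},
            index=pd.Index(self.units, name="unit"),
        )

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.units)

    def convergence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.block_means, columns=self.units)


def run_monte_carlo(spec: StochasticSpec,
                    annotations: Mapping[str, IOAnnotation],
                    config: DEAModelConfig,
                    scenario: Scenario,
                    units: Sequence,
                    seed: int,
                    convergence: Optional[ConvergenceSettings] = None,
                    max_resample: int = 1000) -> EfficiencyPool:
    """Pool envelopment scores over Monte-Carlo draws of the I/O matrix.

    Stops when the largest per-DMU change between consecutive block means
    drops below the tolerance, or at the run cap.  Fully reproducible from
    ``seed``.  Non-positive draws are rejection-resampled (counted).
    """
    convergence = convergence or ConvergenceSettings()
    variables = scenario.inputs + scenario.outputs
    for v in variables:
        if v not in annotations:
            raise ValueError(f"no I/O annotation for scenario variable {v!r}")
    spec.validate_coverage(units, variables)
    rng = np.random.default_rng(seed)
    n_in = len(scenario.inputs)

    all_scores: list[np.ndarray] = []
    block_means: list[np.ndarray] = []
    converged = False
    warnings = 0

    while len(all_scores) < convergence.max_runs:
        for _ in range(convergence.block_size):
            matrix = spec.sample_matrix(units, variables, rng)
            retries = 0
            while (matrix <= 0).any():
                retries += 1
                if retries > max_resample:
                    raise RuntimeError("could not sample a positive I/O matrix")
                matrix = spec.sample_matrix(units, variables, rng)
            warnings += retries
            for j, var in enumerate(variables):
                ann = annotations[var]
                if ann.orientation == "non-standard":
                    matrix[:, j] = transform_nonstandard(matrix[:, j], ann)
            instance = DEAInstance(list(units), matrix[:, :n_in], matrix[:, n_in:])
            all_scores.append(solve_all(instance, config))
        block = np.array(all_scores[-convergence.block_size:])
        block_means.append(block.mean(axis=0))
        if len(block_means) >= 2:
            delta = np.abs(block_means[-1] - block_means[-2]).max()
            if delta < convergence.tolerance:
                converged = True
                break

    return EfficiencyPool(
        units=list(units),
        scores=np.array(all_scores),
        seed=seed,
        converged=converged,
        block_means=np.array(block_means),
        epsilon=config.epsilon,
        resample_warnings=warnings,
    )


# ---------------------------------------------------------------------------
# tier classification


@dataclass
class TierThresholds:
    efficient_mean: float = 0.95
    efficient_fraction: float = 0.5
    nearly_efficient_mean: float = 0.90
    uncertain_mean: float = 0.75


EFFICIENT_TIERS = ("efficient", "nearly-efficient")


@dataclass
class TierClassification:
    tiers: dict  # unit -> tier
    thresholds: TierThresholds
    converged: bool

    @property
    def binary(self) -> dict:
        return {
            u: "efficient-group" if t in EFFICIENT_TIERS else "inefficient-group"
            for u, t in self.tiers.items()
        }

    def to_frame(self) -> pd.DataFrame:
        binary = self.binary
        return pd.DataFrame(
            {"tier": self.tiers, "group": binary},
        ).rename_axis("unit")


def classify_tiers(pool: EfficiencyPool,
                   thresholds: Optional[TierThresholds] = None) -> TierClassification:
    """Four-tier classification on (mean score, fraction scored efficient),
    collapsed to the binary efficient/inefficient grouping."""
    if pool.n_runs == 0:
        raise ValueError("empty efficiency pool")
    thresholds = thresholds or TierThresholds()
    summary = pool.summary()
    tiers = {}
    for unit, row in summary.iterrows():
        if (row["mean"] >= thresholds.efficient_mean
                and row["fraction_efficient"] >= thresholds.efficient_fraction):
            tiers[unit] = "efficient"
        elif row["mean"] >= thresholds.nearly_efficient_mean:
            tiers[unit] = "nearly-efficient"
        elif row["mean"] >= thresholds.uncertain_mean:
            tiers[unit] = "uncertain"
        else:
            tiers[unit] = "inefficient"
    return TierClassification(tiers, thresholds, pool.converged)


# ---------------------------------------------------------------------------
# scenario enumeration


def enumerate_scenarios(input_vars: Sequence[str],
                        output_vars: Sequence[str],
                        mode: str = "automatic",
                        expert_list: Optional[Sequence[tuple]] = None,
                        correlations: Optional[pd.DataFrame] = None,
                        threshold: float = 0.9,
                        max_inputs: Optional[int] = None,
                        max_outputs: Optional[int] = None) -> list[Scenario]:
    """Enumerate I/O variable combinations.

    Expert mode returns the user-listed (inputs, outputs) combinations
    verbatim.  Automatic mode enumerates all non-empty subsets up to the size
    limits, pruning any scenario whose input set or output set contains a
    variable pair flagged redundant (|r| >= threshold) in ``correlations``.
    """
    if not input_vars or not output_vars:
        raise ValueError("need at least one candidate input and output")
    if mode == "expert":
        if not expert_list:
            raise ValueError("expert mode needs an explicit scenario list")
        return [
            Scenario(f"S{i + 1}", list(ins), list(outs), provenance="expert")
            for i, (ins, outs) in enumerate(expert_list)
        ]

    redundant: set[frozenset] = set()
    if correlations is not None:
        for _, row in correlations.iterrows():
            r = row["pearson"]
            if not pd.isna(r) and abs(r) >= threshold:
                redundant.add(frozenset((row["var_a"], row["var_b"])))

    def subsets(pool, cap):
        cap = cap or len(pool)
        for size in range(1, cap + 1):
            yield from itertools.combinations(pool, size)

    def clean(subset):
        return not any(
            frozenset(pair) in redundant
            for pair in itertools.combinations(subset, 2)
        )

    scenarios = []
    idx = 1
    for ins in subsets(list(input_vars), max_inputs):
        if not clean(ins):
            continue
        for outs in subsets(list(output_vars), max_outputs):
            if not clean(outs):
                continue
            scenarios.append(Scenario(f"S{idx}", list(ins), list(outs),
                                      provenance="automatic"))
            idx += 1
    if not scenarios:
        raise ValueError(
            "scenario enumeration pruned everything; raise the redundancy threshold"
        )
    return scenarios
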