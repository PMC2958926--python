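"""Class interpretation support: significance screening, class panel graphs,
characteristic-cell marking and inconsistency detection.

These tools summarise how each variable behaves across the classes of a
partition so a domain expert can label classes and spot anomalies that call
for new rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import MixedTable

__all__ = [
    "VariableSignificance",
    "ClassPanelGraph",
    "InconsistencyReport",
    "test_variables",
    "build_cpg",
    "mark_cells",
    "detect_inconsistencies",
]


@dataclass
class VariableSignificance:
    variable: str
    test: str  # "anova" | "kruskal-wallis" | "chi2-independence"
    statistic: float
    p_value: float
    adjusted_p: float = float("nan")
    note: str = ""


def _class_groups(labels: Mapping) -> dict:
    groups: dict = {}
    for rid, lab in labels.items():
        groups.setdefault(lab, []).append(rid)
    return groups


def _normality_ok(samples: Sequence[np.ndarray], alpha: float = 0.05,
                  min_n: int = 8) -> bool:
    """Shapiro-Wilk screen: parametric only when every class sample has
    n >= min_n and none rejects normality."""
    for s in samples:
        if s.size < min_n:
            return False
        if np.ptp(s) == 0:
            return False
        if stats.shapiro(s).pvalue < alpha:
            return False
    return True


def _pool_rare_categories(counts: np.ndarray, min_expected: float = 5.0
                          ) -> np.ndarray:
    """Merge the rarest columns until all expected counts pass the guard or
    only two columns remain."""
    counts = counts.copy()
    while counts.shape[1] > 2:
        total = counts.sum()
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
        if expected.min() >= min_expected:
            break
        order = np.argsort(counts.sum(axis=0))
        a, b = order[0], order[1]
        counts[:, b] += counts[:, a]
        counts = np.delete(counts, a, axis=1)
    return counts


def test_variables(table: MixedTable, labels: Mapping,
                   alpha: float = 0.05) -> list[VariableSignificance]:
    """Per-variable across-class significance with BH adjustment.

    Numeric: one-way ANOVA when all class samples pass a Shapiro-Wilk screen,
    Kruskal-Wallis otherwise.  Categorical: chi-square independence on the
    class x category contingency, pooling rare categories to satisfy the
    expected-count guard.  Results are sorted by adjusted p.
    """
    groups = _class_groups(labels)
    if len(groups) < 2:
        raise ValueError("need at least two classes")
    results: list[VariableSignificance] = []
    skipped: list[VariableSignificance] = []
    for spec in table.variables:
        col = table.df[spec.name]
        if spec.kind == "numeric":
            samples = []
            for members in groups.values():
                vals = col.loc[members].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    samples.append(vals)
            pooled = np.concatenate(samples) if samples else np.array([])
            if pooled.size == 0 or np.ptp(pooled) == 0:
                skipped.append(VariableSignificance(
                    spec.name, "skipped", float("nan"), float("nan"),
                    note="constant or empty variable"))
                continue
            if len(samples) < 2:
                skipped.append(VariableSignificance(
                    spec.name, "skipped", float("nan"), float("nan"),
                    note="fewer than two non-empty classes"))
                continue
            if _normality_ok(samples):
                stat, p = stats.f_oneway(*samples)
                test = "anova"
            else:
                stat, p = stats.kruskal(*samples)
                test = "kruskal-wallis"
            results.append(VariableSignificance(spec.name, test, float(stat), float(p)))
        else:
            cats = spec.categories
            counts = np.zeros((len(groups), len(cats)))
            for gi, members in enumerate(groups.values()):
                sub = col.loc[members].dropna()
                for ci, cat in enumerate(cats):
                    counts[gi, ci] = (sub == cat).sum()
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2 or counts.sum() == 0:
                skipped.append(VariableSignificance(
                    spec.name, "skipped", float("nan"), float("nan"),
                    note="fewer than two observed categories"))
                continue
            counts = _pool_rare_categories(counts)
            counts = counts[counts.sum(axis=1) > 0]
            if counts.shape[0] < 2:
                skipped.append(VariableSignificance(
                    spec.name, "skipped", float("nan"), float("nan"),
                    note="fewer than two non-empty classes"))
                continue
            stat, p, _, _ = stats.chi2_contingency(counts)
            results.append(VariableSignificance(
                spec.name, "chi2-independence", float(stat), float(p)))
    if results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, ap in zip(results, adjusted):
            r.adjusted_p = float(ap)
    results.sort(key=lambda r: (r.adjusted_p, r.variable))
    return results + skipped


# ---------------------------------------------------------------------------
# class panel graph


@dataclass
class ClassPanelGraph:
    """class x variable grid of conditional distributions.

    ``cells[(class, variable)]`` maps bin label -> conditional frequency;
    bins are shared across classes within a variable.  ``marks`` holds the
    (class, variable, bin) triples flagged characteristic.
    """

    classes: list
    variables: list[str]
    bins: dict  # variable -> list of bin labels
    cells: dict  # (class, variable) -> {bin: freq}
    counts: dict  # (class, variable) -> {bin: count}
    empty_cells: set = field(default_factory=set)
    marks: set = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            for var in self.variables:
                for b in self.bins[var]:
                    rows.append({
                        "class": cls, "variable": var, "bin": b,
                        "frequency": self.cells[(cls, var)].get(b, 0.0),
                        "count": self.counts[(cls, var)].get(b, 0),
                        "marked": (cls, var, b) in self.marks,
                    })
        return pd.DataFrame(rows)


def _sturges(n: int) -> int:
    return max(1, int(math.ceil(math.log2(n) + 1))) if n > 0 else 1


def build_cpg(table: MixedTable, labels: Mapping,
              n_bins: Optional[int] = None) -> ClassPanelGraph:
    """Class panel graph: per-class conditional distributions on shared bins.

    Numeric variables get equal-width bins over the pooled range (Sturges
    count by default); categoricals use their declared categories.
    """
    groups = _class_groups(labels)
    classes = sorted(groups)
    bins: dict = {}
    cells: dict = {}
    counts: dict = {}
    empty = set()
    for spec in table.variables:
        col = table.df[spec.name]
        if spec.kind == "numeric":
            pooled = col.loc[list(labels)].to_numpy(dtype=float)
            pooled = pooled[~np.isnan(pooled)]
            k = n_bins or _sturges(pooled.size)
            if pooled.size == 0:
                edges = np.array([0.0, 1.0])
            elif np.ptp(pooled) == 0:
                v = pooled[0]
                edges = np.array([v - 0.5, v + 0.5])
            else:
                edges = np.linspace(pooled.min(), pooled.max(), k + 1)
            labels_for_bins = [
                f"[{edges[i]:g}, {edges[i + 1]:g}{']' if i == len(edges) - 2 else ')'}"
                for i in range(len(edges) - 1)
            ]
            bins[spec.name] = labels_for_bins
            for cls in classes:
                vals = col.loc[groups[cls]].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                hist, _ = np.histogram(vals, bins=edges)
                total = hist.sum()
                if total == 0:
                    empty.add((cls, spec.name))
                    cells[(cls, spec.name)] = {b: 0.0 for b in labels_for_bins}
                else:
                    cells[(cls, spec.name)] = {
                        b: h / total for b, h in zip(labels_for_bins, hist)
                    }
                counts[(cls, spec.name)] = dict(zip(labels_for_bins, hist.tolist()))
        else:
            bins[spec.name] = list(spec.categories)
            for cls in classes:
                sub = col.loc[groups[cls]].dropna()
                total = len(sub)
                raw = {c: int((sub == c).sum()) for c in spec.categories}
                counts[(cls, spec.name)] = raw
                if total == 0:
                    empty.add((cls, spec.name))
                    cells[(cls, spec.name)] = {c: 0.0 for c in spec.categories}
                else:
                    cells[(cls, spec.name)] = {c: n / total for c, n in raw.items()}
    return ClassPanelGraph(classes, [v.name for v in table.variables],
                           bins, cells, counts, empty)


def mark_cells(cpg: ClassPanelGraph, threshold: float = 2.0) -> ClassPanelGraph:
    """Flag characteristic cells by adjusted standardized residuals.

    For each variable's class x bin count table, a cell is marked when
    |obs - exp| / sqrt(exp (1 - row_prop)(1 - col_prop)) > threshold under
    class/bin independence.
    """
    cpg.marks = set()
    for var in cpg.variables:
        matrix = np.array([
            [cpg.counts[(cls, var)].get(b, 0) for b in cpg.bins[var]]
            for cls in cpg.classes
        ], dtype=float)
        total = matrix.sum()
        if total == 0:
            continue
        row_p = matrix.sum(axis=1) / total
        col_p = matrix.sum(axis=0) / total
        expected = np.outer(matrix.sum(axis=1), matrix.sum(axis=0)) / total
        denom = np.sqrt(expected * (1 - row_p)[:, None] * (1 - col_p)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            residual = np.where(denom > 0, (matrix - expected) / denom, 0.0)
        for ci, cls in enumerate(cpg.classes):
            for bi, b in enumerate(cpg.bins[var]):
                if abs(residual[ci, bi]) > threshold:
                    cpg.marks.add((cls, var, b))
    return cpg


# ---------------------------------------------------------------------------
# inconsistency detection


@dataclass
class Inconsistency:
    class_label: object
    variable: str
    kind: str  # "bimodality" | "variance-inflation"
    evidence: float


@dataclass
class InconsistencyReport:
    items: list[Inconsistency]

    def to_rows(self) -> list[dict]:
        return [
            {"class": i.class_label, "variable": i.variable,
             "kind": i.kind, "evidence": i.evidence}
            for i in self.items
        ]

    def __len__(self) -> int:
        return len(self.items)


def detect_inconsistencies(table: MixedTable, labels: Mapping,
                           trough_threshold: float = 0.3,
                           peak_ratio: float = 0.5,
                           variance_factor: float = 1.5,
                           min_class_n: int = 10) -> InconsistencyReport:
    """Flag per-(class, numeric variable) anomalies that hint at a merged or
    ill-formed class: bimodal histograms (trough between the two tallest
    modes below ``trough_threshold`` of the smaller mode) and variance
    inflation relative to the pooled within-class variance."""
    groups = _class_groups(labels)
    items: list[Inconsistency] = []
    for spec in table.variables:
        if spec.kind != "numeric":
            continue
        col = table.df[spec.name]
        class_vals = {}
        for cls, members in groups.items():
            vals = col.loc[members].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size >= 2 and np.ptp(vals) > 0:
                class_vals[cls] = vals
        if len(class_vals) < 1:
            continue
        pooled_var = np.mean([v.var(ddof=1) for v in class_vals.values()])
        for cls, vals in class_vals.items():
            if vals.size < min_class_n:
                continue
            # bimodality: trough between the two tallest separated modes
            hist, _ = np.histogram(vals, bins=_sturges(vals.size))
            peaks = [
                i for i in range(len(hist))
                if hist[i] > 0
                and (i == 0 or hist[i] >= hist[i - 1])
                and (i == len(hist) - 1 or hist[i] >= hist[i + 1])
            ]
            if len(peaks) >= 2:
                peaks.sort(key=lambda i: -hist[i])
                a, b = sorted(peaks[:2])
                # modes must be separated and of comparable height
                if b - a >= 2 and min(hist[a], hist[b]) >= peak_ratio * max(hist[a], hist[b]):
                    trough = hist[a + 1:b].min()
                    smaller = min(hist[a], hist[b])
                    ratio = trough / smaller if smaller > 0 else 1.0
                    if ratio < trough_threshold:
                        items.append(Inconsistency(
                            cls, spec.name, "bimodality", float(1.0 - ratio)))
            if pooled_var > 0:
                inflation = vals.var(ddof=1) / pooled_var
                if inflation > variance_factor:
                    items.append(Inconsistency(
                        cls, spec.name, "variance-inflation", float(inflation)))
    items.sort(key=lambda i: -i.evidence)
    return InconsistencyReport(items)
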