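"""Agreement statistics between algorithmic results and expert ratings:
diagnostic (predictive-validity) metrics, Cohen's kappa, consistency ICC,
and partition comparison helpers."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "KappaResult",
    "ICCResult",
    "diagnostic_metrics",
    "cohen_kappa",
    "icc_consistency",
    "align_partitions",
    "adjusted_rand_index",
]


@dataclass
class ConfusionTable:
    """k x k counts; rows = reference (expert), columns = test (model).

    For k = 2 the convention is positive first: [[TP, FN], [FP, TN]] with
    "positive" meaning the efficient group.
    """

    counts: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion table must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        if self.counts.sum() == 0:
            raise ValueError("confusion table is empty")

    @classmethod
    def binary(cls, tp: int, fn: int, fp: int, tn: int) -> "ConfusionTable":
        return cls(np.array([[tp, fn], [fp, tn]]), labels=["positive", "negative"])

    @classmethod
    def from_labels(cls, reference: Sequence, test: Sequence,
                    labels: Optional[Sequence] = None) -> "ConfusionTable":
        if len(reference) != len(test):
            raise ValueError("label vectors differ in length")
        if labels is None:
            labels = sorted(set(reference) | set(test), key=str)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for r, t in zip(reference, test):
            counts[index[r], index[t]] += 1
        return cls(counts, labels=list(labels))


def _wilson_ci(successes: float, total: float, alpha: float = 0.05
               ) -> tuple[float, float]:
    if total == 0:
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(1 - alpha / 2)
    p = successes / total
    denom = 1 + z**2 / total
    centre = (p + z**2 / (2 * total)) / denom
    half = z * math.sqrt(p * (1 - p) / total + z**2 / (4 * total**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def _lr_ci(lr: float, a: float, m: float, b: float, n: float,
           alpha: float = 0.05) -> tuple[float, float]:
    """Log-method CI for a likelihood ratio (a/m) / (b/n)."""
    if lr in (0.0, float("inf")) or 0 in (a, b):
        return (float("nan"), float("nan"))
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


@dataclass
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_positive: float  # inf sentinel when specificity == 1
    lr_negative: float
    ci: dict
    ci_method: str = "wilson"

    def as_percent(self) -> dict:
        return {
            "sensitivity": 100 * self.sensitivity,
            "specificity": 100 * self.specificity,
            "ppv": 100 * self.ppv,
            "npv": 100 * self.npv,
            "lr_positive": self.lr_positive,
            "lr_negative": self.lr_negative,
        }


def diagnostic_metrics(table: ConfusionTable, alpha: float = 0.05
                       ) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV with Wilson CIs and likelihood ratios
    with log-method CIs.  LR+ is the +inf sentinel when specificity = 1."""
    if table.counts.shape != (2, 2):
        raise ValueError("diagnostic metrics need a 2x2 table")
    (tp, fn), (fp, tn) = table.counts
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both reference rows must have positive totals")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    lr_pos = float("inf") if spec == 1 else sens / (1 - spec)
    lr_neg = 0.0 if sens == 1 else (
        float("inf") if spec == 0 else (1 - sens) / spec
    )
    ci = {
        "sensitivity": _wilson_ci(tp, tp + fn, alpha),
        "specificity": _wilson_ci(tn, fp + tn, alpha),
        "ppv": _wilson_ci(tp, tp + fp, alpha) if tp + fp > 0 else (float("nan"),) * 2,
        "npv": _wilson_ci(tn, tn + fn, alpha) if tn + fn > 0 else (float("nan"),) * 2,
        "lr_positive": _lr_ci(lr_pos, tp, tp + fn, fp, fp + tn, alpha),
        "lr_negative": _lr_ci(lr_neg, fn, tp + fn, tn, fp + tn, alpha),
    }
    return DiagnosticMetrics(sens, spec, ppv, npv, lr_pos, lr_neg, ci)


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    chance_agreement: float
    note: str = ""


def cohen_kappa(table: ConfusionTable) -> KappaResult:
    """Unweighted Cohen's kappa from a k x k confusion table."""
    counts = table.counts
    total = counts.sum()
    p_o = np.trace(counts) / total
    row = counts.sum(axis=1) / total
    col = counts.sum(axis=0) / total
    p_e = float(row @ col)
    if p_e >= 1.0:
        # single-cell degenerate table: agreement is trivially perfect
        note = "degenerate marginals (chance agreement = 1)"
        return KappaResult(1.0 if p_o == 1.0 else float("nan"), p_o, p_e, note)
    return KappaResult((p_o - p_e) / (1 - p_e), float(p_o), p_e)


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    ms_rows: float
    ms_error: float
    n_units: int
    n_raters: int


def icc_consistency(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Two-way consistency, single-measure ICC (rater effects removed).

    ICC = (MS_rows - MS_error) / (MS_rows + (k-1) MS_error) from the two-way
    ANOVA of a complete units x raters matrix; the CI comes from the
    F = MS_rows/MS_error ratio with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a units x raters matrix")
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 units and 2 raters")
    if np.isnan(ratings).any():
        raise ValueError("missing cells are not allowed; drop units first")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((ratings - grand) ** 2).sum()
    ss_error = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_error = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_error = ss_error / df_error
    if ms_error <= 0:
        icc = 1.0
        ci = (1.0, 1.0)
    else:
        icc = (ms_rows - ms_error) / (ms_rows + (k - 1) * ms_error)
        f_obs = ms_rows / ms_error
        f_upper = stats.f.ppf(1 - alpha / 2, df_rows, df_error)
        f_lower = stats.f.ppf(1 - alpha / 2, df_error, df_rows)
        fl = f_obs / f_upper
        fu = f_obs * f_lower
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    return ICCResult(float(icc), ci, float(ms_rows), float(ms_error), n, k)


# ---------------------------------------------------------------------------
# partition comparison helpers


def align_partitions(reference: Sequence, test: Sequence) -> ConfusionTable:
    """Confusion table after optimal one-to-one class matching.

    Test-class labels are permuted by a Hungarian assignment maximising the
    diagonal, so kappa can be computed for partitions with arbitrary label
    names and differing class counts.
    """
    ref_labels = sorted(set(reference), key=str)
    test_labels = sorted(set(test), key=str)
    k = max(len(ref_labels), len(test_labels))
    counts = np.zeros((k, k))
    ref_idx = {lab: i for i, lab in enumerate(ref_labels)}
    test_idx = {lab: i for i, lab in enumerate(test_labels)}
    for r, t in zip(reference, test):
        counts[ref_idx[r], test_idx[t]] += 1
    _, col_order = linear_sum_assignment(-counts)
    return ConfusionTable(counts[:, col_order])


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected Rand index between two labelings of the same items."""
    if len(a) != len(b):
        raise ValueError("labelings differ in length")
    n = len(a)
    labels_a = {lab: i for i, lab in enumerate(dict.fromkeys(a))}
    labels_b = {lab: i for i, lab in enumerate(dict.fromkeys(b))}
    table = np.zeros((len(labels_a), len(labels_b)))
    for x, y in zip(a, b):
        table[labels_a[x], labels_b[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(table).sum()
    sum_rows = comb2(table.sum(axis=1)).sum()
    sum_cols = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))
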