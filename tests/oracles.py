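"""Independent reference implementations used to cross-check the engines.

These deliberately take different routes than the package: DEA scores via the
multiplier (ratio/dual) LP instead of the envelopment form, and Ward
agglomeration via naive global-minimum greedy search instead of the NN-chain.
"""

import itertools

import numpy as np
from scipy.optimize import linprog

from ebca.clbr import pairwise_sq_distance


def ccr_multiplier_oracle(instance, target_idx: int) -> float:
    """CCR input-oriented score from the ratio (multiplier) form:
    max u.y_t  s.t.  v.x_t = 1,  u.y_j - v.x_j <= 0,  u, v >= 0."""
    X, Y = instance.inputs, instance.outputs
    n, p = X.shape
    q = Y.shape[1]
    c = np.concatenate([np.zeros(p), -Y[target_idx]])
    A_ub = np.hstack([-X, Y])
    b_ub = np.zeros(n)
    A_eq = np.concatenate([X[target_idx], np.zeros(q)]).reshape(1, -1)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0, None)] * (p + q), method="highs")
    assert res.success
    return float(-res.fun)


def bcc_multiplier_oracle(instance, target_idx: int) -> float:
    """Variable-returns input-oriented score from the multiplier form with a
    free intercept: max u.y_t + w  s.t.  v.x_t = 1, u.y_j + w - v.x_j <= 0."""
    X, Y = instance.inputs, instance.outputs
    n, p = X.shape
    q = Y.shape[1]
    c = np.concatenate([np.zeros(p), -Y[target_idx], [-1.0]])
    A_ub = np.hstack([-X, Y, np.ones((n, 1))])
    b_ub = np.zeros(n)
    A_eq = np.concatenate([X[target_idx], np.zeros(q), [0.0]]).reshape(1, -1)
    bounds = [(0, None)] * (p + q) + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=bounds, method="highs")
    assert res.success
    return float(-res.fun)


def greedy_ward_oracle(elements, params):
    """Exhaustive greedy Ward agglomeration: global minimum merge each step,
    Lance-Williams update, deterministic low-index tie-breaks.  Returns
    canonical (leafset, leafset, height) merges for comparison."""
    n = len(elements)
    d2 = pairwise_sq_distance(elements, params)
    masses = {i: elements[i].mass for i in range(n)}
    leafsets = {i: frozenset([i]) for i in range(n)}
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = masses[i] * masses[j] / (masses[i] + masses[j]) * d2[i, j]
    active = list(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        h, a, b = min(
            ((D[(min(x, y), max(x, y))], min(x, y), max(x, y))
             for x, y in itertools.combinations(active, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        left, right = leafsets[a], leafsets[b]
        if min(right) < min(left):
            left, right = right, left
        merges.append((left, right, h))
        for c in active:
            if c in (a, b):
                continue
            dac = D[(min(a, c), max(a, c))]
            dbc = D[(min(b, c), max(b, c))]
            D[(min(nxt, c), max(nxt, c))] = (
                (masses[a] + masses[c]) * dac
                + (masses[b] + masses[c]) * dbc
                - masses[c] * h
            ) / (masses[a] + masses[b] + masses[c])
        masses[nxt] = masses[a] + masses[b]
        leafsets[nxt] = left | right
        active = [c for c in active if c not in (a, b)] + [nxt]
        nxt += 1
    return merges
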