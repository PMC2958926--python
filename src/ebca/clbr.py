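"""Rule-guided hierarchical clustering of mixed-type data.

Records satisfying a knowledge-base rule are condensed into a mass-weighted
prototype; prototypes and the residual records are agglomerated by a
reciprocal-nearest-neighbour (NN-chain) algorithm under Ward's criterion on
a block-weighted mixed dissimilarity; the partition size is chosen by
maximising a Calinski-Harabasz pseudo-F over dendrogram cuts.  Because rule
classes enter as single leaves, every rule class lands intact in one final
class: the semantic constraints of the knowledge base survive clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .data import MixedTable
from .rules import KnowledgeBase, RulePartition, partition_by_rules

__all__ = [
    "Schema",
    "Element",
    "MixedDissimilarityParams",
    "Dendrogram",
    "Partition",
    "CHCurve",
    "build_prototype",
    "prototype_inertia",
    "mixed_distance",
    "pairwise_sq_distance",
    "rnn_ward_cluster",
    "calinski_cut",
    "cut_dendrogram",
    "clbr_cluster",
]


# ---------------------------------------------------------------------------
# schema and cluster summaries


@dataclass(frozen=True)
class Schema:
    numeric: tuple[str, ...]
    categorical: tuple[str, ...]
    categories: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_table(cls, table: MixedTable) -> "Schema":
        return cls(
            numeric=tuple(table.numeric_names()),
            categorical=tuple(table.categorical_names()),
            categories={
                name: tuple(table.specs[name].categories)
                for name in table.categorical_names()
            },
        )


class Element:
    """A record, prototype or cluster centroid: per-variable weighted sums.

    Numeric variables carry (weighted sum, weight); categorical variables a
    weighted category-frequency vector.  Missing cells contribute no weight,
    so means/frequencies are missing-aware by construction.
    """

    __slots__ = ("schema", "num_sum", "num_wt", "cat_sum", "cat_wt", "mass", "members")

    def __init__(self, schema: Schema):
        self.schema = schema
        p = len(schema.numeric)
        self.num_sum = np.zeros(p)
        self.num_wt = np.zeros(p)
        self.cat_sum = [np.zeros(len(schema.categories[c])) for c in schema.categorical]
        self.cat_wt = np.zeros(len(schema.categorical))
        self.mass = 0.0
        self.members: list = []

    @classmethod
    def from_record(cls, schema: Schema, record_id, record: Mapping) -> "Element":
        el = cls(schema)
        el.mass = 1.0
        el.members = [record_id]
        for k, name in enumerate(schema.numeric):
            v = record.get(name)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                el.num_sum[k] = float(v)
                el.num_wt[k] = 1.0
        for k, name in enumerate(schema.categorical):
            v = record.get(name)
            if v is not None and not (isinstance(v, float) and np.isnan(v)):
                idx = schema.categories[name].index(v)
                el.cat_sum[k][idx] = 1.0
                el.cat_wt[k] = 1.0
        return el

    def merged(self, other: "Element") -> "Element":
        el = Element(self.schema)
        el.num_sum = self.num_sum + other.num_sum
        el.num_wt = self.num_wt + other.num_wt
        el.cat_sum = [a + b for a, b in zip(self.cat_sum, other.cat_sum)]
        el.cat_wt = self.cat_wt + other.cat_wt
        el.mass = self.mass + other.mass
        el.members = self.members + other.members
        return el

    def numeric_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.num_wt > 0, self.num_sum / np.maximum(self.num_wt, 1e-300), np.nan)

    def category_frequencies(self, k: int) -> Optional[np.ndarray]:
        if self.cat_wt[k] <= 0:
            return None
        return self.cat_sum[k] / self.cat_wt[k]

    def to_dict(self) -> dict:
        means = self.numeric_means()
        out = {"mass": self.mass, "numeric": {}, "categorical": {}}
        for k, name in enumerate(self.schema.numeric):
            out["numeric"][name] = None if np.isnan(means[k]) else float(means[k])
        for k, name in enumerate(self.schema.categorical):
            freq = self.category_frequencies(k)
            out["categorical"][name] = (
                None if freq is None
                else {c: float(f) for c, f in zip(self.schema.categories[name], freq)}
            )
        return out


def build_prototype(schema: Schema, records: Iterable[tuple[object, Mapping]]) -> Element:
    """Condense a non-empty record subset into a mass-weighted prototype."""
    proto: Optional[Element] = None
    for rid, record in records:
        el = Element.from_record(schema, rid, record)
        proto = el if proto is None else proto.merged(el)
    if proto is None:
        raise ValueError("cannot build a prototype from an empty subset")
    return proto


# ---------------------------------------------------------------------------
# mixed dissimilarity


@dataclass
class MixedDissimilarityParams:
    """Block weights and per-numeric-variable scales for the mixed metric.

    d2(a, b) = alpha * mean_numeric ((a_k - b_k)/s_k)^2
             + beta  * mean_categorical (half L1 between frequency vectors)

    with per-pair renormalisation over comparable (non-missing) variables.
    Defaults: alpha = n_Q/(n_Q+n_C), beta = n_C/(n_Q+n_C), scales = column
    standard deviations (1 for constants).
    """

    alpha: float
    beta: float
    scales: np.ndarray

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("need alpha, beta >= 0 with alpha + beta > 0")
        self.scales = np.asarray(self.scales, dtype=float)
        if (self.scales <= 0).any():
            raise ValueError("numeric scales must be positive")

    @classmethod
    def from_table(cls, table: MixedTable,
                   alpha: Optional[float] = None,
                   beta: Optional[float] = None) -> "MixedDissimilarityParams":
        nq = len(table.numeric_names())
        nc = len(table.categorical_names())
        if nq + nc == 0:
            raise ValueError("table has no variables")
        if alpha is None:
            alpha = nq / (nq + nc)
        if beta is None:
            beta = nc / (nq + nc)
        scales = np.ones(nq)
        for k, name in enumerate(table.numeric_names()):
            col = table.df[name].to_numpy(dtype=float)
            present = col[~np.isnan(col)]
            if present.size > 1:
                sd = present.std(ddof=1)
                if sd > 0:
                    scales[k] = sd
        return cls(alpha, beta, scales)

    @classmethod
    def unscaled(cls, n_numeric: int, n_categorical: int = 0,
                 alpha: Optional[float] = None,
                 beta: Optional[float] = None) -> "MixedDissimilarityParams":
        total = n_numeric + n_categorical
        if alpha is None:
            alpha = n_numeric / total
        if beta is None:
            beta = n_categorical / total
        return cls(alpha, beta, np.ones(n_numeric))


def _freq_stack(elements: Sequence[Element], k: int) -> np.ndarray:
    """n x c matrix of category frequencies; missing rows are NaN."""
    n = len(elements)
    c = len(elements[0].schema.categories[elements[0].schema.categorical[k]])
    out = np.full((n, c), np.nan)
    for i, el in enumerate(elements):
        f = el.category_frequencies(k)
        if f is not None:
            out[i] = f
    return out


def pairwise_sq_distance(elements: Sequence[Element],
                         params: MixedDissimilarityParams) -> np.ndarray:
    """Symmetric matrix of squared mixed dissimilarities between elements."""
    n = len(elements)
    schema = elements[0].schema
    nq, nc = len(schema.numeric), len(schema.categorical)

    q_sum = np.zeros((n, n))
    q_cnt = np.zeros((n, n))
    if nq:
        M = np.vstack([el.numeric_means() for el in elements])  # n x p
        for k in range(nq):
            col = M[:, k]
            ok = ~np.isnan(col)
            both = np.outer(ok, ok)
            diff = (col[:, None] - col[None, :]) / params.scales[k]
            term = np.where(both, diff * diff, 0.0)
            q_sum += np.nan_to_num(term)
            q_cnt += both

    c_sum = np.zeros((n, n))
    c_cnt = np.zeros((n, n))
    for k in range(nc):
        F = _freq_stack(elements, k)
        ok = ~np.isnan(F[:, 0])
        both = np.outer(ok, ok)
        delta = 0.5 * np.abs(F[:, None, :] - F[None, :, :]).sum(axis=2)
        c_sum += np.where(both, np.nan_to_num(delta), 0.0)
        c_cnt += both

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_q = np.where(q_cnt > 0, q_sum / np.maximum(q_cnt, 1), 0.0)
        mean_c = np.where(c_cnt > 0, c_sum / np.maximum(c_cnt, 1), 0.0)
    wq = np.where(q_cnt > 0, params.alpha, 0.0)
    wc = np.where(c_cnt > 0, params.beta, 0.0)
    active = wq + wc
    if (active <= 0).any():
        bad = np.argwhere(active <= 0)
        i, j = bad[0]
        raise ValueError(
            f"elements {i} and {j} share no comparable variable"
        )
    d2 = (params.alpha * mean_q + params.beta * mean_c) * (params.alpha + params.beta) / active
    np.fill_diagonal(d2, 0.0)
    return d2


def mixed_distance(a: Element, b: Element,
                   params: MixedDissimilarityParams) -> float:
    """Squared mixed dissimilarity between two elements."""
    return float(pairwise_sq_distance([a, b], params)[0, 1])


# ---------------------------------------------------------------------------
# dendrogram


@dataclass
class Dendrogram:
    """Binary merge tree over leaves 0..n-1; merge t creates node n+t.

    Heights are Ward merge costs and are nondecreasing.  ``leaf_ids`` and
    ``leaf_masses`` describe the clustered leaves (records or prototypes).
    """

    leaf_ids: list
    leaf_masses: list[float]
    merges: list[tuple[int, int, float]]

    def __post_init__(self):
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 * max(1.0, abs(a)) for a, b in zip(heights, heights[1:])):
            raise ValueError("dendrogram heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_dict(self) -> dict:
        return {
            "leaves": [
                {"id": str(i), "mass": m}
                for i, m in zip(self.leaf_ids, self.leaf_masses)
            ],
            "merges": [
                {"left": a, "right": b, "height": h} for a, b, h in self.merges
            ],
        }

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        text = {i: str(self.leaf_ids[i]) for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            node = n + t
            la = max(h - node_height[a], 0.0)
            lb = max(h - node_height[b], 0.0)
            text[node] = f"({text[a]}:{la:g},{text[b]}:{lb:g})"
            node_height[node] = h
        return text[2 * n - 2] + ";"

    def canonical_merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge list as (leafset, leafset, height) for oracle comparison."""
        n = self.n_leaves
        sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
        out = []
        for t, (a, b, h) in enumerate(self.merges):
            left, right = sets[a], sets[b]
            if min(right) < min(left):
                left, right = right, left
            out.append((left, right, h))
            sets[n + t] = left | right
        return out


def rnn_ward_cluster(elements: Sequence[Element],
                     params: MixedDissimilarityParams) -> Dendrogram:
    """Agglomerate by reciprocal nearest neighbours under Ward's criterion.

    Initial pair costs are the mass-weighted Ward merge costs
    dW(i, j) = m_i m_j / (m_i + m_j) * d2(centroid_i, centroid_j); merged
    clusters are updated with the Ward Lance-Williams recurrence, which keeps
    the costs reducible, so the NN-chain reproduces greedy agglomeration.
    Ties break towards the lowest cluster index.
    """
    n = len(elements)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    masses = np.array([el.mass for el in elements], dtype=float)
    d2 = pairwise_sq_distance(elements, params)
    size = 2 * n - 1
    D = np.full((size, size), np.inf)
    m = np.zeros(size)
    m[:n] = masses
    with np.errstate(invalid="ignore"):
        pair_cost = (masses[:, None] * masses[None, :]
                     / (masses[:, None] + masses[None, :])) * d2
    D[:n, :n] = pair_cost
    np.fill_diagonal(D, np.inf)

    active = list(range(n))
    is_active = np.zeros(size, dtype=bool)
    is_active[:n] = True
    raw_merges: list[tuple[int, int, float]] = []
    next_node = n
    chain: list[int] = []

    while len(active) > 1:
        if not chain:
            chain.append(min(active))
        a = chain[-1]
        row = np.where(is_active, D[a], np.inf)
        row[a] = np.inf
        b = int(np.argmin(row))  # argmin returns the lowest index on ties
        if len(chain) >= 2 and chain[-2] == b:
            chain.pop()
            chain.pop()
            height = D[a, b]
            lo, hi = (a, b) if a < b else (b, a)
            raw_merges.append((lo, hi, float(height)))
            node = next_node
            next_node += 1
            # Ward Lance-Williams update on merge costs
            others = [c for c in active if c not in (a, b)]
            total = m[a] + m[b]
            for c in others:
                D[node, c] = D[c, node] = (
                    (m[a] + m[c]) * D[a, c]
                    + (m[b] + m[c]) * D[b, c]
                    - m[c] * D[a, b]
                ) / (total + m[c])
            m[node] = total
            is_active[a] = is_active[b] = False
            is_active[node] = True
            active = others + [node]
            active.sort()
        else:
            chain.append(b)

    # sort merges by height (stable: children precede parents on ties)
    order = sorted(range(len(raw_merges)), key=lambda t: raw_merges[t][2])
    remap = {n + old: n + new for new, old in enumerate(order)}
    merges = []
    for old_t in order:
        a, b, h = raw_merges[old_t]
        a = remap.get(a, a)
        b = remap.get(b, b)
        merges.append((min(a, b), max(a, b), h))
    leaf_ids = [
        el.members[0] if len(el.members) == 1 else f"group{idx}[{len(el.members)}]"
        for idx, el in enumerate(elements)
    ]
    return Dendrogram(leaf_ids=leaf_ids, leaf_masses=list(masses), merges=merges)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> list[int]:
    """Leaf labels (0..k-1) for the k-class cut at the k-1 highest merges."""
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} leaves")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _) in enumerate(dendrogram.merges[: n - k]):
        node = n + t
        parent[find(a)] = node
        parent[find(b)] = node
    roots = {}
    labels = []
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels.append(roots[r])
    return labels


# ---------------------------------------------------------------------------
# Calinski-Harabasz cut selection


@dataclass
class CHCurve:
    values: dict  # k -> CH value (may be inf)
    k_star: int

    def to_rows(self) -> list[dict]:
        return [{"k": k, "ch": v} for k, v in sorted(self.values.items())]


def _scatter(elements: Sequence[Element], labels: Sequence[int],
             params: MixedDissimilarityParams) -> tuple[float, float, float]:
    """Mass-weighted between/within sums of squared mixed distances."""
    classes: dict[int, Element] = {}
    for el, lab in zip(elements, labels):
        classes[lab] = el if lab not in classes else classes[lab].merged(el)
    overall = None
    for el in elements:
        overall = el if overall is None else overall.merged(el)
    within = 0.0
    for el, lab in zip(elements, labels):
        within += el.mass * mixed_distance(el, classes[lab], params)
    between = 0.0
    for centroid in classes.values():
        between += centroid.mass * mixed_distance(centroid, overall, params)
    total_mass = overall.mass
    return between, within, total_mass


def prototype_inertia(proto: Element, members: Sequence[Element],
                      params: MixedDissimilarityParams) -> float:
    """Mass-weighted scatter of member elements around their prototype."""
    return sum(m.mass * mixed_distance(m, proto, params) for m in members)


def calinski_cut(dendrogram: Dendrogram, elements: Sequence[Element],
                 params: MixedDissimilarityParams,
                 kmax: Optional[int] = None,
                 within_offset: float = 0.0) -> CHCurve:
    """Calinski-Harabasz pseudo-F over dendrogram cuts, k in [2, kmax].

    CH(k) = (B/(k-1)) / (W/(n-k)) with mass-weighted scatter around mixed
    centroids and n the total leaf mass; W = 0 yields +inf (that k wins).
    ``within_offset`` adds the internal inertia of condensed prototype
    leaves to W, so the curve matches the one computed over their expanded
    member records.
    """
    n = dendrogram.n_leaves
    if kmax is None:
        kmax = min(10, n - 1)
    if not (2 <= kmax <= n - 1):
        raise ValueError(f"kmax={kmax} out of range [2, {n - 1}]")
    values = {}
    for k in range(2, kmax + 1):
        labels = cut_dendrogram(dendrogram, k)
        between, within, total = _scatter(elements, labels, params)
        within += within_offset
        if within <= 1e-12:
            values[k] = float("inf")
        else:
            values[k] = (between / (k - 1)) / (within / (total - k))
    k_star = max(sorted(values), key=lambda k: values[k])
    return CHCurve(values, k_star)


# ---------------------------------------------------------------------------
# full ClBR pipeline


@dataclass
class Partition:
    """Final flat classes with rule provenance."""

    labels: dict  # record id -> class index (1..k)
    provenance: dict  # class index -> "rule-seeded" | "data-driven"
    rules_by_class: dict = field(default_factory=dict)  # class -> list of rule ids
    k: int = 0

    def __post_init__(self):
        if not self.k:
            self.k = len(set(self.labels.values()))

    def class_members(self) -> dict:
        out: dict = {}
        for rid, lab in self.labels.items():
            out.setdefault(lab, []).append(rid)
        return out


def clbr_cluster(table: MixedTable, kb: KnowledgeBase,
                 params: Optional[MixedDissimilarityParams] = None,
                 kmax: Optional[int] = None,
                 ) -> tuple[Dendrogram, Partition, CHCurve, RulePartition]:
    """Knowledge-guided clustering: rules -> prototypes -> Ward -> CH cut.

    With an empty KB this reduces to plain mixed-metric Ward clustering.
    Every rule class with at least one satisfying record is guaranteed to
    land intact in one final class.
    """
    schema = Schema.from_table(table)
    params = params or MixedDissimilarityParams.from_table(table)
    rule_partition = partition_by_rules(kb, table.records())

    groups: dict[str, list] = {}
    for rid, group in rule_partition.assignments.items():
        groups.setdefault(group, []).append(rid)

    records = dict(table.records())
    elements: list[Element] = []
    prototype_leaves: dict[int, str] = {}  # leaf index -> rule id
    within_offset = 0.0
    for rule in kb.rules:
        members = groups.get(rule.id, [])
        if not members:
            continue  # rule with no satisfying record: skipped with a warning upstream
        proto = build_prototype(schema, ((rid, records[rid]) for rid in members))
        member_els = [Element.from_record(schema, rid, records[rid])
                      for rid in members]
        within_offset += prototype_inertia(proto, member_els, params)
        prototype_leaves[len(elements)] = rule.id
        elements.append(proto)
    for rid in groups.get(RulePartition.RESIDUAL, []):
        elements.append(Element.from_record(schema, rid, records[rid]))

    if len(elements) < 2:
        # everything condensed into a single leaf: trivial one-class partition
        labels = {rid: 1 for rid in table.unit_ids}
        prov = {1: "rule-seeded" if prototype_leaves else "data-driven"}
        dendro = Dendrogram([0], [elements[0].mass], []) if elements else None
        return dendro, Partition(labels, prov, {1: list(prototype_leaves.values())}, 1), \
            CHCurve({}, 1), rule_partition

    dendrogram = rnn_ward_cluster(elements, params)
    curve = calinski_cut(dendrogram, elements, params, kmax=kmax,
                         within_offset=within_offset)
    leaf_labels = cut_dendrogram(dendrogram, curve.k_star)

    labels: dict = {}
    provenance: dict = {}
    rules_by_class: dict = {}
    for leaf_idx, (el, lab) in enumerate(zip(elements, leaf_labels)):
        cls = lab + 1
        for rid in el.members:
            labels[rid] = cls
        if leaf_idx in prototype_leaves:
            provenance[cls] = "rule-seeded"
            rules_by_class.setdefault(cls, []).append(prototype_leaves[leaf_idx])
        else:
            provenance.setdefault(cls, "data-driven")
    partition = Partition(labels, provenance, rules_by_class, k=curve.k_star)
    return dendrogram, partition, curve, rule_partition
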