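"""If-then rule knowledge base: grammar, three-valued evaluation, partitioning.

The rule file format is line oriented::

    # comment
    r1: if ((GAFCLA < 40) or (GAFSOCIAL < 40)) and (MAXECFOS_A > 15) then severely-ill

An antecedent is a boolean expression over atomic conditions.  Mixing ``and``
and ``or`` at the same parenthesis level is a parse error: the file author
must disambiguate explicitly.  Evaluation uses Kleene three-valued logic so
that missing cells propagate to an ``unknown`` outcome instead of silently
deciding a rule.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Condition",
    "Rule",
    "KnowledgeBase",
    "IOAnnotation",
    "RuleParseError",
    "RuleEvaluationError",
    "parse_rules",
    "parse_expression",
    "evaluate_rule",
    "partition_by_rules",
    "diff_kb",
    "FIRES",
    "NO_FIRE",
    "UNKNOWN",
]

FIRES = "fires"
NO_FIRE = "does-not-fire"
UNKNOWN = "unknown"

_ORDER_OPS = {"<", "<=", ">", ">="}
_EQ_OPS = {"=", "!="}


class RuleParseError(ValueError):
    """Raised when rule text does not conform to the grammar."""


class RuleEvaluationError(TypeError):
    """Raised on operator / cell-kind mismatch during evaluation."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


# ---------------------------------------------------------------------------
# expression tree


@dataclass(frozen=True)
class Condition:
    """Atomic test on a single variable.

    ``operator`` is one of ``< <= > >= = != in-interval in-set``.  For
    ``in-interval`` the operand is ``(low, high)`` and ``closed`` is a pair of
    booleans for the two bounds; for ``in-set`` the operand is a frozenset of
    category labels.
    """

    variable: str
    operator: str
    operand: object
    closed: tuple[bool, bool] = (True, True)

    def __post_init__(self):
        if self.operator == "in-interval":
            lo, hi = self.operand
            if lo > hi:
                raise RuleParseError(
                    f"interval bounds out of order for {self.variable}: [{lo}, {hi}]"
                )

    def evaluate(self, record: Mapping[str, object]) -> Optional[bool]:
        value = record.get(self.variable)
        if _is_missing(value):
            return None
        op = self.operator
        if op in _ORDER_OPS or op == "in-interval":
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise RuleEvaluationError(
                    f"ordering operator {op!r} applied to non-numeric cell "
                    f"{self.variable}={value!r}"
                )
        if op == "<":
            return value < self.operand
        if op == "<=":
            return value <= self.operand
        if op == ">":
            return value > self.operand
        if op == ">=":
            return value >= self.operand
        if op == "=":
            return value == self.operand
        if op == "!=":
            return value != self.operand
        if op == "in-interval":
            lo, hi = self.operand
            lo_ok = value >= lo if self.closed[0] else value > lo
            hi_ok = value <= hi if self.closed[1] else value < hi
            return lo_ok and hi_ok
        if op == "in-set":
            return value in self.operand
        raise RuleEvaluationError(f"unknown operator {op!r}")

    def to_text(self) -> str:
        if self.operator == "in-interval":
            lo, hi = self.operand
            lb = "[" if self.closed[0] else "("
            rb = "]" if self.closed[1] else ")"
            return f"({self.variable} in {lb}{_fmt_num(lo)}, {_fmt_num(hi)}{rb})"
        if self.operator == "in-set":
            items = ", ".join(sorted(str(c) for c in self.operand))
            return f"({self.variable} in {{{items}}})"
        operand = _fmt_num(self.operand) if isinstance(self.operand, (int, float)) else str(self.operand)
        return f"({self.variable} {self.operator} {operand})"

    def variables(self) -> set[str]:
        return {self.variable}


def _fmt_num(x) -> str:
    if isinstance(x, float) and x.is_integer():
        return str(int(x))
    return str(x)


@dataclass(frozen=True)
class BoolExpr:
    """Internal node: ``and`` / ``or`` over >=2 children, or unary ``not``."""

    op: str  # "and" | "or" | "not"
    children: tuple

    def evaluate(self, record: Mapping[str, object]) -> Optional[bool]:
        vals = [c.evaluate(record) for c in self.children]
        if self.op == "not":
            v = vals[0]
            return None if v is None else not v
        if self.op == "and":
            if any(v is False for v in vals):
                return False
            if any(v is None for v in vals):
                return None
            return True
        if self.op == "or":
            if any(v is True for v in vals):
                return True
            if any(v is None for v in vals):
                return None
            return False
        raise RuleEvaluationError(f"unknown connective {self.op!r}")

    def to_text(self) -> str:
        if self.op == "not":
            return f"(not {self.children[0].to_text()})"
        inner = f" {self.op} ".join(c.to_text() for c in self.children)
        return f"({inner})"

    def variables(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.variables()
        return out


@dataclass(frozen=True)
class Rule:
    id: str
    antecedent: object  # Condition | BoolExpr
    conclusion: str

    def to_text(self) -> str:
        return f"{self.id}: if {self.antecedent.to_text()} then {self.conclusion}"

    def variables(self) -> set[str]:
        return self.antecedent.variables()


@dataclass
class IOAnnotation:
    """DEA role annotation for one variable."""

    variable: str
    role: str  # "input" | "output"
    orientation: str = "standard"  # "standard" | "non-standard"
    margin_fraction: float = 0.1

    def __post_init__(self):
        if self.role not in ("input", "output"):
            raise ValueError(f"role must be input/output, got {self.role!r}")
        if self.orientation not in ("standard", "non-standard"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class KnowledgeBase:
    rules: list[Rule] = field(default_factory=list)
    mode: str = "clbr"  # "clbr" | "dea"
    version: int = 1
    changelog: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RuleParseError(f"duplicate rule ids: {dupes}")
        if self.mode not in ("clbr", "dea"):
            raise ValueError(f"mode must be clbr/dea, got {self.mode!r}")

    def to_text(self) -> str:
        return "\n".join(r.to_text() for r in self.rules) + ("\n" if self.rules else "")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "version": self.version,
                "changelog": self.changelog,
                "rules": [_node_to_dict_rule(r) for r in self.rules],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "KnowledgeBase":
        data = json.loads(text)
        rules = [
            Rule(r["id"], _node_from_dict(r["antecedent"]), r["conclusion"])
            for r in data["rules"]
        ]
        return cls(rules, data.get("mode", "clbr"), data.get("version", 1),
                   data.get("changelog", []))

    def get(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)


def _node_to_dict(node) -> dict:
    if isinstance(node, Condition):
        operand = node.operand
        if node.operator == "in-set":
            operand = sorted(operand)
        elif node.operator == "in-interval":
            operand = list(operand)
        return {
            "type": "condition",
            "variable": node.variable,
            "operator": node.operator,
            "operand": operand,
            "closed": list(node.closed),
        }
    return {"type": node.op, "children": [_node_to_dict(c) for c in node.children]}


def _node_to_dict_rule(rule: Rule) -> dict:
    return {"id": rule.id, "antecedent": _node_to_dict(rule.antecedent),
            "conclusion": rule.conclusion}


def _node_from_dict(d: dict):
    if d["type"] == "condition":
        operand = d["operand"]
        if d["operator"] == "in-set":
            operand = frozenset(operand)
        elif d["operator"] == "in-interval":
            operand = tuple(operand)
        return Condition(d["variable"], d["operator"], operand,
                         tuple(d.get("closed", (True, True))))
    return BoolExpr(d["type"], tuple(_node_from_dict(c) for c in d["children"]))


# ---------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)"
    r"|(?P<op><=|>=|!=|<|>|=)"
    r"|(?P<punct>[()\[\]{},:])"
    r"|(?P<word>[A-Za-z_][A-Za-z0-9_\-]*))"
)

_KEYWORDS = {"if", "then", "and", "or", "not", "in"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleParseError(f"unexpected character {text[pos]!r} at column {pos}")
        pos = m.end()
        for kind in ("num", "op", "punct", "word"):
            val = m.group(kind)
            if val is not None:
                if kind == "word" and val.lower() in _KEYWORDS:
                    tokens.append(("kw", val.lower()))
                else:
                    tokens.append((kind, val))
                break
    return tokens


class _Parser:
    def __init__(self, tokens: Sequence[tuple[str, str]],
                 declared: Optional[Mapping[str, object]]):
        self.tokens = list(tokens)
        self.pos = 0
        self.declared = declared

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expect(self, kind, value=None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise RuleParseError(f"expected {value or kind!r}, found {v!r}")
        return v

    def parse_expr(self):
        first = self.parse_unary()
        parts = [first]
        connective = None
        while self.peek() == ("kw", "and") or self.peek() == ("kw", "or"):
            _, word = self.next()
            if connective is None:
                connective = word
            elif word != connective:
                raise RuleParseError(
                    "ambiguous mix of 'and'/'or' at the same level; "
                    "add explicit parentheses"
                )
            parts.append(self.parse_unary())
        if connective is None:
            return first
        return BoolExpr(connective, tuple(parts))

    def parse_unary(self):
        kind, value = self.peek()
        if (kind, value) == ("kw", "not"):
            self.next()
            return BoolExpr("not", (self.parse_unary(),))
        if (kind, value) == ("punct", "("):
            self.next()
            expr = self.parse_expr()
            self.expect("punct", ")")
            return expr
        return self.parse_atom()

    def parse_atom(self) -> Condition:
        kind, var = self.next()
        if kind != "word":
            raise RuleParseError(f"expected variable name, found {var!r}")
        self._check_declared(var)
        kind, op = self.next()
        if (kind, op) == ("kw", "in"):
            return self._parse_membership(var)
        if kind != "op":
            raise RuleParseError(f"expected comparison operator after {var!r}, found {op!r}")
        lk, lv = self.next()
        if lk == "num":
            operand: object = float(lv)
        elif lk == "word":
            operand = lv
        else:
            raise RuleParseError(f"expected literal after operator, found {lv!r}")
        cond = Condition(var, op, operand)
        self._check_kinds(cond)
        return cond

    def _parse_membership(self, var: str) -> Condition:
        kind, value = self.next()
        if (kind, value) == ("punct", "{"):
            items = []
            while True:
                k, v = self.next()
                if k not in ("word", "num"):
                    raise RuleParseError(f"bad set element {v!r}")
                items.append(float(v) if k == "num" else v)
                k, v = self.next()
                if (k, v) == ("punct", "}"):
                    break
                if (k, v) != ("punct", ","):
                    raise RuleParseError(f"expected ',' or '}}' in set, found {v!r}")
            cond = Condition(var, "in-set", frozenset(items))
        elif (kind, value) in (("punct", "["), ("punct", "(")):
            left_closed = value == "["
            lo = float(self.expect("num"))
            self.expect("punct", ",")
            hi = float(self.expect("num"))
            k, v = self.next()
            if (k, v) not in (("punct", "]"), ("punct", ")")):
                raise RuleParseError(f"expected interval close, found {v!r}")
            cond = Condition(var, "in-interval", (lo, hi), (left_closed, v == "]"))
        else:
            raise RuleParseError(f"expected interval or set after 'in', found {value!r}")
        self._check_kinds(cond)
        return cond

    def _check_declared(self, var: str):
        if self.declared is not None and var not in self.declared:
            raise RuleParseError(f"undeclared variable: {var!r}")

    def _check_kinds(self, cond: Condition):
        if self.declared is None:
            return
        kind = self.declared.get(cond.variable)
        kind = getattr(kind, "kind", kind)  # accept VariableSpec or plain string
        if kind is None:
            return
        if kind == "categorical" and (
            cond.operator in _ORDER_OPS or cond.operator == "in-interval"
        ):
            raise RuleParseError(
                f"ordering operator {cond.operator!r} on categorical "
                f"variable {cond.variable!r}"
            )
        if kind == "numeric" and cond.operator == "in-set":
            ok = all(isinstance(x, float) for x in cond.operand)
            if not ok:
                raise RuleParseError(
                    f"non-numeric set for numeric variable {cond.variable!r}"
                )
        if kind == "numeric" and cond.operator in _EQ_OPS and isinstance(cond.operand, str):
            raise RuleParseError(
                f"category literal compared with numeric variable {cond.variable!r}"
            )


def parse_expression(text: str, metadata: Optional[Mapping[str, object]] = None):
    """Parse a bare antecedent expression (no 'id: if ... then')."""
    parser = _Parser(_tokenize(text), metadata)
    expr = parser.parse_expr()
    if parser.peek() != (None, None):
        raise RuleParseError(f"trailing tokens after expression: {parser.peek()[1]!r}")
    return expr


def parse_rules(text: str, metadata: Optional[Mapping[str, object]] = None,
                mode: str = "clbr", version: int = 1) -> KnowledgeBase:
    """Parse a rule file into a :class:`KnowledgeBase`.

    ``metadata`` maps variable name -> kind (``"numeric"``/``"categorical"``)
    or to a ``VariableSpec``; when given, undeclared variables and
    kind-incompatible operators are parse errors.
    """
    rules = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            head, _, rest = line.partition(":")
            rule_id = head.strip()
            if not rule_id or not _:
                raise RuleParseError("missing 'id:' prefix")
            parser = _Parser(_tokenize(rest), metadata)
            parser.expect("kw", "if")
            antecedent = parser.parse_expr()
            parser.expect("kw", "then")
            # conclusion: everything left (labels may contain several words)
            leftovers = [v for _, v in parser.tokens[parser.pos:]]
            if not leftovers:
                raise RuleParseError("missing conclusion after 'then'")
            conclusion = " ".join(leftovers)
            rules.append(Rule(rule_id, antecedent, conclusion))
        except RuleParseError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from None
    return KnowledgeBase(rules, mode=mode, version=version)


# ---------------------------------------------------------------------------
# evaluation / partitioning


def evaluate_rule(rule: Rule, record: Mapping[str, object]) -> str:
    """Evaluate a rule on one record under Kleene three-valued logic.

    Returns :data:`FIRES`, :data:`NO_FIRE` or :data:`UNKNOWN` (the latter iff
    the truth value depends on a missing cell).
    """
    value = rule.antecedent.evaluate(record)
    if value is None:
        return UNKNOWN
    return FIRES if value else NO_FIRE


@dataclass
class RulePartition:
    """Assignment of records to the first matching rule or the residual."""

    assignments: dict  # record id -> rule id or "residual"
    counts: dict  # group -> size
    unknown_count: int
    overlap_warnings: list  # (record id, fired rule ids)

    RESIDUAL = "residual"


def partition_by_rules(kb: KnowledgeBase, records: Iterable[tuple[object, Mapping]],
                       ) -> RulePartition:
    """First-match partition of records by the KB's rules.

    ``records`` yields ``(id, mapping)`` pairs (e.g. ``MixedTable.records()``).
    Records whose status is unknown on every candidate rule up to a firing one
    fall to the residual group and are counted as unknown.
    """
    if kb.mode != "clbr":
        raise ValueError("partition_by_rules requires a KB in clbr mode")
    assignments: dict = {}
    counts: dict = {r.id: 0 for r in kb.rules}
    counts[RulePartition.RESIDUAL] = 0
    unknown_count = 0
    overlaps = []
    for rid, record in records:
        fired = []
        saw_unknown = False
        for rule in kb.rules:
            status = evaluate_rule(rule, record)
            if status == FIRES:
                fired.append(rule.id)
            elif status == UNKNOWN:
                saw_unknown = True
        if fired:
            assignments[rid] = fired[0]
            counts[fired[0]] += 1
            if len(fired) > 1:
                overlaps.append((rid, tuple(fired)))
        else:
            assignments[rid] = RulePartition.RESIDUAL
            counts[RulePartition.RESIDUAL] += 1
            if saw_unknown:
                unknown_count += 1
    return RulePartition(assignments, counts, unknown_count, overlaps)


# ---------------------------------------------------------------------------
# versioning


@dataclass
class KBChangeset:
    added: list[str]
    removed: list[str]
    modified: list[str]

    def is_empty(self) -> bool:
        return not (self.added or self.removed or self.modified)

    def describe(self) -> str:
        parts = []
        if self.added:
            parts.append("added: " + ", ".join(self.added))
        if self.removed:
            parts.append("removed: " + ", ".join(self.removed))
        if self.modified:
            parts.append("modified: " + ", ".join(self.modified))
        return "; ".join(parts) if parts else "no changes"


def diff_kb(old: KnowledgeBase, new: KnowledgeBase) -> KBChangeset:
    """Diff two KBs by rule id; the changeset is appended to ``new.changelog``."""
    if old.mode != new.mode:
        raise ValueError(f"mode mismatch: {old.mode!r} vs {new.mode!r}")
    old_by_id = {r.id: r for r in old.rules}
    new_by_id = {r.id: r for r in new.rules}
    added = sorted(set(new_by_id) - set(old_by_id))
    removed = sorted(set(old_by_id) - set(new_by_id))
    modified = sorted(
        rid for rid in set(old_by_id) & set(new_by_id)
        if old_by_id[rid].to_text() != new_by_id[rid].to_text()
    )
    changes = KBChangeset(added, removed, modified)
    new.changelog.append(f"v{old.version}->v{new.version}: {changes.describe()}")
    return changes
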