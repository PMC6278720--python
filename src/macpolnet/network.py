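"""Logical-network container types.

A :class:`BooleanNetwork` is an ordered list of named nodes, a Boolean update
rule for every non-input node, and a designated set of *input* nodes that are
held constant during dynamics (extracellular stimuli in the macrophage model).
States are numpy boolean vectors index-aligned with the node order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .expr import (
    And,
    Const,
    Expr,
    Not,
    Or,
    RuleSyntaxError,
    Var,
    literal_signs,
    monotone_signs,
    parse_expression,
    truth_table,
)

__all__ = [
    "NodeSpec",
    "BooleanRule",
    "BooleanNetwork",
    "NetworkValidationError",
    "EdgeValidationReport",
    "parse_rules",
    "write_rules",
]

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

CATEGORIES = ("input", "receptor", "regulator", "output")


@dataclass(frozen=True)
class NodeSpec:
    """A network node: canonical identifier plus display metadata."""

    name: str
    category: str = "regulator"
    display: str | None = None

    def __post_init__(self):
        if not _NAME_RE.match(self.name):
            raise NetworkValidationError(f"invalid node name {self.name!r}")
        if self.category not in CATEGORIES:
            raise NetworkValidationError(
                f"unknown category {self.category!r} for node {self.name}"
            )

    @property
    def display_name(self) -> str:
        return self.display if self.display is not None else self.name


@dataclass(frozen=True)
class BooleanRule:
    """Update rule ``target := expression``.

    ``regulators`` optionally declares the regulator set explicitly; a
    uniform random truth table can be constant or ignore a regulator, and
    the declared set is what degree-matched null models preserve. When
    absent, the regulators are the variables appearing in the expression.
    """

    target: str
    expression: Expr
    regulators: tuple[str, ...] | None = None

    def variables(self) -> set[str]:
        if self.regulators is not None:
            return set(self.regulators)
        return self.expression.variables()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.target}, {self.expression.to_string()}"


class NetworkValidationError(ValueError):
    pass


class _CompiledRules:
    """Vectorized evaluators for every non-input rule of a network.

    Each rule is compiled to a closure over bitwise numpy operators, so the
    same callable serves plain boolean columns and packed uint64 bit-planes.
    """

    def __init__(self, net: "BooleanNetwork"):
        self.net = net
        self.funcs: list = [None] * net.n_nodes  # index-aligned
        self.consts: list = [None] * net.n_nodes
        for name, rule in net.rules.items():
            i = net.index[name]
            expr = rule.expression
            if isinstance(expr, Const):
                self.consts[i] = int(expr.value)
                continue
            self.funcs[i] = self._compile(expr)

    def _compile(self, expr: Expr):
        def render(e: Expr) -> str:
            if isinstance(e, Var):
                return f"x[{self.net.index[e.name]}]"
            if isinstance(e, Not):
                return f"~({render(e.operand)})"
            if isinstance(e, And):
                return "(" + " & ".join(render(op) for op in e.operands) + ")"
            if isinstance(e, Or):
                return "(" + " | ".join(render(op) for op in e.operands) + ")"
            raise NetworkValidationError(
                f"constant sub-expression survived simplification: {e}"
            )

        return eval(f"lambda x: {render(expr)}", {}, {})  # noqa: S307 - own AST

    def sync_matrix(self, states: np.ndarray) -> np.ndarray:
        """Synchronous successor of each row of a (m, n) boolean matrix."""
        cols = states.T
        out = states.copy()
        for i in range(self.net.n_nodes):
            if self.funcs[i] is not None:
                out[:, i] = self.funcs[i](cols)
            elif self.consts[i] is not None:
                out[:, i] = bool(self.consts[i])
        return out

    def eval_packed(self, planes: list[np.ndarray], n_words: int) -> list[np.ndarray]:
        """Successor bit-planes from per-node uint64 bit-planes."""
        full = np.uint64(0xFFFFFFFFFFFFFFFF)
        out = []
        for i in range(self.net.n_nodes):
            if self.funcs[i] is not None:
                out.append(self.funcs[i](planes) & full)
            elif self.consts[i] is not None:
                fill = full if self.consts[i] else np.uint64(0)
                out.append(np.full(n_words, fill, dtype=np.uint64))
            else:  # input: held constant
                out.append(planes[i])
        return out


class BooleanNetwork:
    """An ordered logical network with constant input nodes.

    Parameters
    ----------
    nodes
        Ordered node specifications; order fixes the state-vector layout.
    rules
        One :class:`BooleanRule` for every node whose category is not
        ``input``. Inputs carry no rule and are held constant by every
        update scheme.
    """

    def __init__(self, nodes: list[NodeSpec], rules: list[BooleanRule]):
        self.nodes = list(nodes)
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate node names")
        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.rules: dict[str, BooleanRule] = {}
        for rule in rules:
            if rule.target not in self.index:
                raise NetworkValidationError(f"rule for unknown node {rule.target!r}")
            if rule.target in self.rules:
                raise NetworkValidationError(f"duplicate rule for {rule.target!r}")
            for ref in rule.variables() | rule.expression.variables():
                if ref not in self.index:
                    raise NetworkValidationError(
                        f"rule for {rule.target} references unknown node {ref!r}"
                    )
            if rule.regulators is not None and not (
                rule.expression.variables() <= set(rule.regulators)
            ):
                raise NetworkValidationError(
                    f"rule for {rule.target} uses nodes outside its declared "
                    f"regulator set"
                )
            self.rules[rule.target] = rule
        self.inputs = [n.name for n in self.nodes if n.category == "input"]
        self.internal = [n.name for n in self.nodes if n.category != "input"]
        for name in self.inputs:
            if name in self.rules:
                raise NetworkValidationError(f"input node {name} must not have a rule")
        for name in self.internal:
            if name not in self.rules:
                raise NetworkValidationError(f"missing rule for non-input node {name}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def n_internal(self) -> int:
        return len(self.internal)

    @property
    def input_indices(self) -> np.ndarray:
        return np.array([self.index[n] for n in self.inputs], dtype=np.intp)

    @property
    def internal_indices(self) -> np.ndarray:
        return np.array([self.index[n] for n in self.internal], dtype=np.intp)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index[name]]

    def rule(self, name: str) -> BooleanRule:
        return self.rules[name]

    def in_degrees(self) -> dict[str, int]:
        """Number of distinct (declared) regulators per non-input node."""
        return {t: len(r.variables()) for t, r in self.rules.items()}

    @cached_property
    def compiled(self) -> _CompiledRules:
        return _CompiledRules(self)

    # -- derived structure ---------------------------------------------------
    def signed_edges(self, semantic: bool = False) -> list[tuple[str, str, int]]:
        """Edges ``(source, target, sign)`` derived from the rules.

        By default the sign is the syntactic NOT-parity of the literal
        (negative iff the source appears under an odd number of negations).
        With ``semantic=True`` signs come from truth-table monotonicity
        instead; the two agree exactly on unate rules.
        """
        edges = []
        for target in self.internal:
            expr = self.rules[target].expression
            if semantic:
                for src, sign in monotone_signs(expr).items():
                    edges.append((src, target, sign))
            else:
                for src, parities in sorted(literal_signs(expr).items()):
                    if parities == {1, -1}:
                        sign = 0  # appears with both parities: not unate
                    else:
                        sign = 1 if 1 in parities else -1
                    edges.append((src, target, sign))
        return edges

    def is_unate(self) -> bool:
        """True iff every rule depends monotonically on each of its regulators."""
        return all(
            0 not in monotone_signs(r.expression).values() for r in self.rules.values()
        )

    def rule_truth_table(self, target: str) -> tuple[list[str], np.ndarray]:
        """Regulators (sorted) and the rule's output over their 2**k states."""
        expr = self.rules[target].expression
        regs = sorted(expr.variables())
        return regs, truth_table(expr, regs)

    # -- states --------------------------------------------------------------
    def zero_state(self) -> np.ndarray:
        return np.zeros(self.n_nodes, dtype=bool)

    def state_from_active(self, active) -> np.ndarray:
        s = self.zero_state()
        for name in active:
            s[self.index[name]] = True
        return s

    def active_nodes(self, state: np.ndarray) -> list[str]:
        return [self.names[i] for i in np.flatnonzero(state)]

    def state_to_bits(self, state: np.ndarray) -> str:
        return "".join("1" if b else "0" for b in state)

    def check_state(self, state: np.ndarray) -> np.ndarray:
        state = np.asarray(state)
        if state.shape != (self.n_nodes,):
            raise ValueError(
                f"state length {state.shape} does not match {self.n_nodes} nodes"
            )
        return state.astype(bool)

    # -- perturbations -------------------------------------------------------
    def apply_perturbation(self, node: str, value: int) -> "BooleanNetwork":
        """Clamp a non-input node: knockout (0) or ectopic expression (1).

        The node's rule becomes the constant, removing all regulatory edges
        into it; everything else is untouched. Inputs are clamped through the
        simulation interfaces instead, so perturbing one is an error.
        """
        if node not in self.index:
            raise KeyError(f"unknown node {node!r}")
        if node in self.inputs:
            raise ValueError(
                f"{node} is an input; clamp it via the input assignment instead"
            )
        rules = [
            BooleanRule(t, Const(int(value))) if t == node else r
            for t, r in self.rules.items()
        ]
        return BooleanNetwork(self.nodes, rules)

    # -- equality ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return (
            self.names == other.names
            and self.inputs == other.inputs
            and {t: r.expression for t, r in self.rules.items()}
            == {t: r.expression for t, r in other.rules.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return (
            f"<BooleanNetwork {self.n_nodes} nodes "
            f"({self.n_inputs} inputs, {len(self.rules)} rules)>"
        )


# -- rule-file round-trip ----------------------------------------------------

HEADER = "targets, factors"


def parse_rules(text: str, categories: dict[str, str] | None = None) -> BooleanNetwork:
    """Parse a ``targets, factors`` rule file into a network.

    A line ``NAME, NAME`` (a pure self-rule) declares an input node held
    constant during dynamics. ``#`` starts a comment; the header line is
    required. Node order is the order of first appearance as a target.
    """
    categories = categories or {}
    rules_raw: list[tuple[str, str, int]] = []
    lines = text.splitlines()
    seen_header = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not seen_header:
            if line.lower().replace(" ", "") != HEADER.replace(" ", ""):
                raise RuleSyntaxError(
                    f"expected header {HEADER!r}, found {line!r}", lineno
                )
            seen_header = True
            continue
        if "," not in line:
            raise RuleSyntaxError("expected 'TARGET, EXPRESSION'", lineno)
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not _NAME_RE.match(target):
            raise RuleSyntaxError(f"invalid target name {target!r}", lineno)
        rules_raw.append((target, expr_text.strip(), lineno))
    if not seen_header:
        raise RuleSyntaxError(f"missing header {HEADER!r}", len(lines) or 1)

    targets = [t for t, _, _ in rules_raw]
    if len(set(targets)) != len(targets):
        dup = sorted({t for t in targets if targets.count(t) > 1})
        raise RuleSyntaxError(f"duplicate target(s): {', '.join(dup)}", None)

    nodes: list[NodeSpec] = []
    rules: list[BooleanRule] = []
    known = set(targets)
    for target, expr_text, lineno in rules_raw:
        expr = parse_expression(expr_text, lineno)
        for ref in expr.variables():
            if ref not in known:
                raise RuleSyntaxError(
                    f"rule for {target} references undeclared node {ref!r}", lineno
                )
        if isinstance(expr, Var) and expr.name == target:
            nodes.append(NodeSpec(target, categories.get(target, "input")))
        else:
            nodes.append(NodeSpec(target, categories.get(target, "regulator")))
            rules.append(BooleanRule(target, expr))
    return BooleanNetwork(nodes, rules)


def write_rules(net: BooleanNetwork) -> str:
    """Serialize a network to the ``targets, factors`` dialect.

    Inputs are written as self-rules, so ``parse_rules(write_rules(net))``
    reproduces the network (structural round-trip identity).
    """
    lines = [HEADER]
    for spec in net.nodes:
        if spec.category == "input":
            lines.append(f"{spec.name}, {spec.name}")
        else:
            lines.append(f"{spec.name}, {net.rules[spec.name].expression.to_string()}")
    return "\n".join(lines) + "\n"


# -- edge-table validation ---------------------------------------------------


@dataclass
class EdgeValidationReport:
    """Difference between rule-derived edges and a curated signed edge table."""

    missing_from_rules: list[tuple[str, str, int]] = field(default_factory=list)
    missing_from_table: list[tuple[str, str, int]] = field(default_factory=list)
    sign_mismatches: list[tuple[str, str, int, int]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.missing_from_rules or self.missing_from_table or self.sign_mismatches
        )

    def summary(self) -> str:
        lines = []
        for src, tgt, sign in self.missing_from_rules:
            lines.append(f"table edge {src} -> {tgt} ({sign:+d}) absent from rules")
        for src, tgt, sign in self.missing_from_table:
            lines.append(f"rule edge {src} -> {tgt} ({sign:+d}) absent from table")
        for src, tgt, s_rule, s_table in self.sign_mismatches:
            lines.append(
                f"sign mismatch {src} -> {tgt}: rules {s_rule:+d}, table {s_table:+d}"
            )
        return "\n".join(lines) if lines else "edge table and rules agree"


def validate_against_edge_table(
    net: BooleanNetwork, edges: list[tuple[str, str, int]]
) -> EdgeValidationReport:
    """Compare rule-derived signed edges with a curated ``(source, target, sign)`` list."""
    for src, tgt, _sign in edges:
        for name in (src, tgt):
            if name not in net.index:
                raise NetworkValidationError(f"edge table names unknown node {name!r}")
    rule_edges = {(s, t): sign for s, t, sign in net.signed_edges()}
    table_edges = {(s, t): sign for s, t, sign in edges}
    report = EdgeValidationReport()
    for key, sign in sorted(table_edges.items()):
        if key not in rule_edges:
            report.missing_from_rules.append((*key, sign))
        elif rule_edges[key] != sign:
            report.sign_mismatches.append((*key, rule_edges[key], sign))
    for key, sign in sorted(rule_edges.items()):
        if key not in table_edges:
            report.missing_from_table.append((*key, sign))
    return report
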