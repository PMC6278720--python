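"""Boolean expression trees for logical-network update rules.

Rules are small propositional formulas over node names, written in the
``targets, factors`` dialect used by common Boolean-network tools::

    NF_kB, (IL1R | TLR4) & !(STAT3 | FcgR | PPARg | KLF4)

The AST deliberately supports only ``&``, ``|``, ``!``, parentheses and the
constants ``0``/``1``; that is the entire expressiveness of the modelling
formalism, and keeping the grammar closed makes round-tripping and sign
derivation exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "RuleSyntaxError",
    "parse_expression",
]


class Expr:
    """Base class for rule expressions (immutable)."""

    def variables(self) -> set[str]:
        return {v.name for v in self.iter_vars()}

    def iter_vars(self) -> Iterator["Var"]:
        raise NotImplementedError

    def evaluate(self, env) -> object:
        """Evaluate with ``env[name] -> value``.

        Values may be Python bools/ints or numpy arrays; only ``&``, ``|``
        and ``~`` are applied, so boolean arrays and packed uint64 bit-planes
        both work unchanged.
        """
        raise NotImplementedError

    def substitute(self, assignment: dict[str, int]) -> "Expr":
        """Partially evaluate: replace known variables and constant-fold."""
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __repr__(self) -> str:  # pragma: no cover - convenience
        return f"{type(self).__name__}({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Expr) and self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def iter_vars(self):
        yield self

    def evaluate(self, env):
        return env[self.name]

    def substitute(self, assignment):
        if self.name in assignment:
            return Const(int(assignment[self.name]))
        return self

    def to_string(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Const(Expr):
    value: int

    def iter_vars(self):
        return iter(())

    def evaluate(self, env):
        return bool(self.value)

    def substitute(self, assignment):
        return self

    def to_string(self):
        return str(int(self.value))


@dataclass(frozen=True, eq=False)
class Not(Expr):
    operand: Expr

    def iter_vars(self):
        return self.operand.iter_vars()

    def evaluate(self, env):
        return ~self.operand.evaluate(env)

    def substitute(self, assignment):
        inner = self.operand.substitute(assignment)
        if isinstance(inner, Const):
            return Const(1 - inner.value)
        if isinstance(inner, Not):
            return inner.operand
        return Not(inner)

    def to_string(self):
        inner = self.operand.to_string()
        if isinstance(self.operand, (And, Or)):
            return f"!({inner})"
        return f"!{inner}"


def _nary_init(cls, operands):
    flat = []
    for op in operands:
        if isinstance(op, cls):
            flat.extend(op.operands)
        else:
            flat.append(op)
    return tuple(flat)


@dataclass(frozen=True, eq=False)
class And(Expr):
    operands: tuple[Expr, ...]

    def __init__(self, *operands):
        if len(operands) == 1 and isinstance(operands[0], (tuple, list)):
            operands = tuple(operands[0])
        object.__setattr__(self, "operands", _nary_init(And, operands))

    def iter_vars(self):
        for op in self.operands:
            yield from op.iter_vars()

    def evaluate(self, env):
        acc = self.operands[0].evaluate(env)
        for op in self.operands[1:]:
            acc = acc & op.evaluate(env)
        return acc

    def substitute(self, assignment):
        parts = []
        for op in self.operands:
            sub = op.substitute(assignment)
            if isinstance(sub, Const):
                if sub.value == 0:
                    return Const(0)
                continue
            parts.append(sub)
        if not parts:
            return Const(1)
        if len(parts) == 1:
            return parts[0]
        return And(*parts)

    def to_string(self):
        parts = []
        for op in self.operands:
            s = op.to_string()
            if isinstance(op, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)


@dataclass(frozen=True, eq=False)
class Or(Expr):
    operands: tuple[Expr, ...]

    def __init__(self, *operands):
        if len(operands) == 1 and isinstance(operands[0], (tuple, list)):
            operands = tuple(operands[0])
        object.__setattr__(self, "operands", _nary_init(Or, operands))

    def iter_vars(self):
        for op in self.operands:
            yield from op.iter_vars()

    def evaluate(self, env):
        acc = self.operands[0].evaluate(env)
        for op in self.operands[1:]:
            acc = acc | op.evaluate(env)
        return acc

    def substitute(self, assignment):
        parts = []
        for op in self.operands:
            sub = op.substitute(assignment)
            if isinstance(sub, Const):
                if sub.value == 1:
                    return Const(1)
                continue
            parts.append(sub)
        if not parts:
            return Const(0)
        if len(parts) == 1:
            return parts[0]
        return Or(*parts)

    def to_string(self):
        return " | ".join(op.to_string() for op in self.operands)


class RuleSyntaxError(ValueError):
    """Malformed rule expression; carries the (1-based) source line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


_IDENT_START = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ_")
_IDENT_CONT = _IDENT_START | set("0123456789")


def _tokenize(text: str, line: int | None):
    tokens = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()&|!":
            tokens.append((c, c))
            i += 1
        elif c in "01" and (i + 1 == n or text[i + 1] not in _IDENT_CONT):
            tokens.append(("const", int(c)))
            i += 1
        elif c in _IDENT_START:
            j = i + 1
            while j < n and text[j] in _IDENT_CONT:
                j += 1
            tokens.append(("name", text[i:j]))
            i = j
        else:
            raise RuleSyntaxError(f"unexpected character {c!r}", line)
    return tokens


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse one rule expression.

    Grammar (``|`` binds loosest, then ``&``, then ``!``)::

        expr   := term ('|' term)*
        term   := factor ('&' factor)*
        factor := '!' factor | '(' expr ')' | NAME | '0' | '1'
    """
    tokens = _tokenize(text, line)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        parts = [parse_and()]
        while peek() == "|":
            take()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def parse_and():
        parts = [parse_factor()]
        while peek() == "&":
            take()
            parts.append(parse_factor())
        return parts[0] if len(parts) == 1 else And(*parts)

    def parse_factor():
        kind = peek()
        if kind is None:
            raise RuleSyntaxError("unexpected end of expression", line)
        if kind == "!":
            take()
            return Not(parse_factor())
        if kind == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise RuleSyntaxError("unbalanced parenthesis", line)
            take()
            return inner
        if kind == "name":
            return Var(take()[1])
        if kind == "const":
            return Const(take()[1])
        raise RuleSyntaxError(f"unexpected token {tokens[pos][1]!r}", line)

    if not tokens:
        raise RuleSyntaxError("empty expression", line)
    result = parse_or()
    if pos != len(tokens):
        raise RuleSyntaxError(f"trailing input {tokens[pos][1]!r}", line)
    return result


def truth_table(expr: Expr, variables: list[str]) -> np.ndarray:
    """Boolean output of ``expr`` for all 2**k assignments of ``variables``.

    Assignment ``j`` sets ``variables[i]`` to bit ``i`` of ``j``.
    """
    k = len(variables)
    idx = np.arange(1 << k)
    env = {v: ((idx >> i) & 1).astype(bool) for i, v in enumerate(variables)}
    out = expr.evaluate(env)
    if isinstance(out, (bool, np.bool_)):
        out = np.full(1 << k, bool(out))
    return np.asarray(out, dtype=bool)


def literal_signs(expr: Expr) -> dict[str, set[int]]:
    """NOT-parity of every variable occurrence: +1 (even) / -1 (odd parities seen)."""
    signs: dict[str, set[int]] = {}

    def walk(e: Expr, parity: int):
        if isinstance(e, Var):
            signs.setdefault(e.name, set()).add(parity)
        elif isinstance(e, Not):
            walk(e.operand, -parity)
        elif isinstance(e, (And, Or)):
            for op in e.operands:
                walk(op, parity)

    walk(expr, +1)
    return signs


def monotone_signs(expr: Expr) -> dict[str, int]:
    """Semantic edge signs from the truth table.

    Returns +1 / -1 per variable for monotone (unate) dependence, 0 for a
    non-monotone dependence and omits fictitious variables entirely.
    """
    variables = sorted(expr.variables())
    table = truth_table(expr, variables)
    out: dict[str, int] = {}
    for i, v in enumerate(variables):
        idx = np.arange(table.size)
        hi = table[idx | (1 << i)]
        lo = table[idx & ~(1 << i)]
        if np.array_equal(hi, lo):
            continue  # fictitious
        up = bool(np.any(hi & ~lo))
        down = bool(np.any(lo & ~hi))
        out[v] = 0 if (up and down) else (+1 if up else -1)
    return out
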