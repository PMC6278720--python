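"""Synthetic data: random Boolean networks and random states.

The study's only "data" are networks and states, so this module is the
data generator: degree-matched random networks provide the null model for
the robustness test, and uniform random states feed perturbation sampling
and property tests.

The null model preserves what makes the comparison meaningful — node count,
the constant-input set, and each node's number of regulators — and
randomizes everything else: regulator identities (uniform without
replacement, self excluded) and the update function (a uniform random truth
table, so rules need not be unate, unlike the curated biology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expr import And, Const, Expr, Not, Or, Var
from .network import BooleanNetwork, BooleanRule, NodeSpec

__all__ = ["RandomNetworkSpec", "random_network", "random_states", "expr_from_truth_table"]


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of the random-network generator."""

    n_nodes: int
    n_inputs: int = 0
    in_degrees: tuple[int, ...] | None = None  # per non-input node
    fixed_k: int | None = None
    seed: int = 0


def expr_from_truth_table(regulators: list[str], table: np.ndarray) -> Expr:
    """Disjunctive normal form of an arbitrary truth table.

    ``table[j]`` is the output when ``regulators[i]`` holds bit ``i`` of
    ``j``. Constant tables collapse to ``0``/``1``.
    """
    table = np.asarray(table, dtype=bool)
    if table.size != 1 << len(regulators):
        raise ValueError("truth table size does not match regulator count")
    if not table.any():
        return Const(0)
    if table.all():
        return Const(1)
    minterms = []
    for j in np.flatnonzero(table):
        literals = [
            Var(r) if (j >> i) & 1 else Not(Var(r))
            for i, r in enumerate(regulators)
        ]
        minterms.append(literals[0] if len(literals) == 1 else And(*literals))
    return minterms[0] if len(minterms) == 1 else Or(*minterms)


def random_network(
    spec: RandomNetworkSpec | None = None,
    reference: BooleanNetwork | None = None,
    seed: int | None = None,
) -> BooleanNetwork:
    """Generate a random Boolean network.

    With ``reference`` given (and no explicit spec), the generated network
    matches its node count, input count and per-node in-degree multiset
    (in node order); otherwise the spec fields apply. Regulators are drawn
    uniformly without replacement from all nodes except the target, and each
    rule is a uniform random truth table over its regulators.
    """
    if spec is None:
        if reference is None:
            raise ValueError("either a spec or a reference network is required")
        degrees = tuple(
            len(reference.rules[name].variables()) for name in reference.internal
        )
        spec = RandomNetworkSpec(
            n_nodes=reference.n_nodes,
            n_inputs=reference.n_inputs,
            in_degrees=degrees,
            seed=0 if seed is None else int(seed),
        )
    elif seed is not None:
        spec = RandomNetworkSpec(
            n_nodes=spec.n_nodes,
            n_inputs=spec.n_inputs,
            in_degrees=spec.in_degrees,
            fixed_k=spec.fixed_k,
            seed=int(seed),
        )
    n_internal = spec.n_nodes - spec.n_inputs
    if spec.in_degrees is not None:
        degrees = spec.in_degrees
        if len(degrees) != n_internal:
            raise ValueError("in_degrees length must equal the non-input node count")
    elif spec.fixed_k is not None:
        degrees = tuple([spec.fixed_k] * n_internal)
    else:
        raise ValueError("spec needs in_degrees or fixed_k")
    if any(k > spec.n_nodes - 1 for k in degrees):
        raise ValueError("in-degree exceeds n_nodes - 1")

    rng = np.random.default_rng(spec.seed)
    names = [f"n{i}" for i in range(spec.n_nodes)]
    nodes = [
        NodeSpec(nm, "input" if i < spec.n_inputs else "regulator")
        for i, nm in enumerate(names)
    ]
    rules = []
    for j, k in enumerate(degrees):
        target = names[spec.n_inputs + j]
        pool = [nm for nm in names if nm != target]
        regs = [str(r) for r in rng.choice(pool, size=k, replace=False)] if k else []
        table = rng.random(1 << k) < 0.5
        rules.append(
            BooleanRule(target, expr_from_truth_table(regs, table), tuple(regs))
        )
    return BooleanNetwork(nodes, rules)


def random_states(n_nodes: int, count: int, seed: int = 0) -> np.ndarray:
    """Uniform i.i.d. boolean states as a (count, n_nodes) matrix."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.random((count, n_nodes)) < 0.5
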