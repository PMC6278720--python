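"""Exhaustive attractor enumeration under the synchronous scheme.

Because input nodes are constant, the synchronous state space decomposes
exactly into 2^|inputs| independent functional graphs over the internal
nodes. For each input assignment the enumeration either

* sweeps all 2^k internal states with bit-parallel rule evaluation and finds
  every cycle of the functional graph by iterated-map composition
  (``method="exhaustive"``), or
* first removes nodes whose rules collapse to constants once the inputs are
  substituted (they are eventually constant along every trajectory, so they
  cannot participate in an attractor), and sweeps only the remaining
  free-node subspace (``method="reduced"``).

Both are exact; ``reduced`` is typically orders of magnitude faster and is
property-tested against ``exhaustive``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import PackedStateBlock, batch_successors, sync_step
from .expr import Const
from .network import BooleanNetwork

__all__ = [
    "Attractor",
    "AttractorReport",
    "fixed_points_for_inputs",
    "all_attractors",
    "verify_attractor",
]

_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or synchronous limit cycle (state sequence).

    Cycle states are listed starting from the lexicographically smallest
    state (big-endian in node order), following the synchronous map.
    """

    kind: str  # "fixed_point" | "cycle"
    states: tuple[tuple[int, ...], ...]
    input_assignment: dict[str, int]

    @property
    def length(self) -> int:
        return len(self.states)

    def state_arrays(self) -> np.ndarray:
        return np.array(self.states, dtype=bool)


@dataclass
class AttractorReport:
    """Census of every synchronous attractor of a network."""

    network_nodes: list[str]
    attractors: list[Attractor] = field(default_factory=list)

    @property
    def n_fixed_points(self) -> int:
        return sum(1 for a in self.attractors if a.kind == "fixed_point")

    @property
    def n_cycles(self) -> int:
        return sum(1 for a in self.attractors if a.kind == "cycle")

    @property
    def n_total(self) -> int:
        return len(self.attractors)

    @property
    def cycle_lengths(self) -> list[int]:
        return sorted(a.length for a in self.attractors if a.kind == "cycle")

    def steady_states(self) -> np.ndarray:
        """All fixed points as an (n_fixed_points, n_nodes) boolean matrix."""
        fps = [a.states[0] for a in self.attractors if a.kind == "fixed_point"]
        if not fps:
            return np.zeros((0, len(self.network_nodes)), dtype=bool)
        return np.array(fps, dtype=bool)

    def steady_state_frame(self) -> pd.DataFrame:
        """One row per steady state, one 0/1 column per node."""
        return pd.DataFrame(
            self.steady_states().astype(int), columns=self.network_nodes
        )

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.network_nodes,
            "n_fixed_points": self.n_fixed_points,
            "n_cycles": self.n_cycles,
            "n_total": self.n_total,
            "cycle_lengths": self.cycle_lengths,
            "attractors": [
                {
                    "kind": a.kind,
                    "inputs": a.input_assignment,
                    "states": [
                        "".join(str(int(b)) for b in s) for s in a.states
                    ],
                }
                for a in self.attractors
            ],
        }


def _canonical_rotation(states: list[tuple[int, ...]]) -> tuple[tuple[int, ...], ...]:
    k = min(range(len(states)), key=lambda i: states[i])
    return tuple(states[k:] + states[:k])


def _propagate_constants(
    net: BooleanNetwork, input_assignment: dict[str, int]
) -> tuple[dict[str, int], list[str]]:
    """Nodes forced to constants by the inputs, plus the remaining free nodes.

    Iterates partial evaluation to a fixed point: a node joins the constant
    set when its rule folds to 0/1 given inputs and already-constant nodes.
    Constant nodes converge to those values along every trajectory, so every
    attractor lives in the free-node subspace.
    """
    known = {k: int(v) for k, v in input_assignment.items()}
    changed = True
    while changed:
        changed = False
        for name in net.internal:
            if name in known:
                continue
            folded = net.rules[name].expression.substitute(known)
            if isinstance(folded, Const):
                known[name] = int(folded.value)
                changed = True
    free = [n for n in net.internal if n not in known]
    return known, free


def _free_successor_map(
    net: BooleanNetwork, known: dict[str, int], free: list[str]
) -> np.ndarray:
    """Successor index array of the 2^k dynamics on the free nodes."""
    k = len(free)
    if k > 24:
        raise ValueError(
            f"{k} coupled free nodes exceed the exhaustive sweep guard (24)"
        )
    rows = 1 << k
    idx = np.arange(rows)
    env: dict[str, np.ndarray | bool] = {n: bool(v) for n, v in known.items()}
    for i, name in enumerate(free):
        env[name] = ((idx >> i) & 1).astype(bool)
    succ = np.zeros(rows, dtype=np.int64)
    for i, name in enumerate(free):
        out = net.rules[name].expression.evaluate(env)
        if isinstance(out, (bool, np.bool_)):
            out = np.full(rows, bool(out))
        succ += out.astype(np.int64) << i
    return succ


def _cycles_of_map(succ: np.ndarray) -> list[list[int]]:
    """All cycles of a functional graph given as a successor index array.

    The image of the iterated map stabilizes exactly on the union of cycles
    (repeated squaring; the image is monotone decreasing), after which each
    cycle is read off by walking successors.
    """
    g = succ
    prev = -1
    while True:
        on = np.zeros(succ.size, dtype=bool)
        on[g] = True
        size = int(on.sum())
        if size == prev:
            break
        prev = size
        g = g[g]
    cycles = []
    seen: set[int] = set()
    for a in np.flatnonzero(on):
        a = int(a)
        if a in seen:
            continue
        cyc = [a]
        x = int(succ[a])
        while x != a:
            cyc.append(x)
            x = int(succ[x])
        seen.update(cyc)
        cycles.append(cyc)
    return cycles


def _full_state(
    net: BooleanNetwork,
    known: dict[str, int],
    free: list[str],
    free_index: int,
) -> tuple[int, ...]:
    state = np.zeros(net.n_nodes, dtype=int)
    for name, v in known.items():
        state[net.index[name]] = v
    for i, name in enumerate(free):
        state[net.index[name]] = (free_index >> i) & 1
    return tuple(int(b) for b in state)


def _internal_planes(net: BooleanNetwork, input_assignment: dict[str, int]):
    """Bit-planes spanning all 2^k internal states for one input assignment."""
    k = net.n_internal
    n_states = 1 << k
    n_words = max(1, n_states // 64)
    planes: list[np.ndarray] = [None] * net.n_nodes  # type: ignore[list-item]
    for name in net.inputs:
        fill = _FULL if input_assignment[name] else np.uint64(0)
        planes[net.index[name]] = np.full(n_words, fill, dtype=np.uint64)
    words = np.arange(n_words, dtype=np.uint64)
    for i, name in enumerate(net.internal):
        if i < 6 and k > 6:
            pattern = np.uint64(sum(1 << j for j in range(64) if (j >> i) & 1))
            plane = np.full(n_words, pattern, dtype=np.uint64)
        elif k > 6:
            bit = ((words >> np.uint64(i - 6)) & np.uint64(1)).astype(bool)
            plane = np.where(bit, _FULL, np.uint64(0))
        else:  # tiny network: one word
            pattern = sum(
                1 << j for j in range(n_states) if (j >> i) & 1
            )
            plane = np.array([pattern], dtype=np.uint64)
        planes[net.index[name]] = plane
    return PackedStateBlock(n_states=n_states, planes=planes), n_words


def _exhaustive_successor_map(
    net: BooleanNetwork, input_assignment: dict[str, int]
) -> np.ndarray:
    """Successor index array over all 2^k internal states via bit-parallel eval."""
    k = net.n_internal
    if k > 24:
        raise ValueError(f"{k} internal nodes exceed the exhaustive sweep guard (24)")
    block, _ = _internal_planes(net, input_assignment)
    succ_block = batch_successors(net, block)
    n_states = 1 << k
    succ = np.zeros(n_states, dtype=np.int64)
    for i, name in enumerate(net.internal):
        plane = succ_block.planes[net.index[name]]
        bits = np.unpackbits(plane.view(np.uint8), bitorder="little")[:n_states]
        succ += bits.astype(np.int64) << i
    return succ


def fixed_points_for_inputs(
    net: BooleanNetwork,
    input_assignment: dict[str, int],
    method: str = "reduced",
) -> np.ndarray:
    """All synchronous fixed points with the given input values.

    Returns an (m, n_nodes) boolean matrix in ascending bit order of the
    free-node index. ``method="exhaustive"`` brute-forces all internal
    states bit-parallel; ``"reduced"`` solves by constant propagation plus
    exhaustive search over the remaining coupled nodes. Both are exact.
    """
    missing = [n for n in net.inputs if n not in input_assignment]
    if missing:
        raise ValueError(f"input assignment misses {missing}")
    input_assignment = {n: int(input_assignment[n]) for n in net.inputs}
    if method == "exhaustive":
        succ = _exhaustive_successor_map(net, input_assignment)
        fixed = np.flatnonzero(succ == np.arange(succ.size))
        states = []
        for s in fixed:
            st = np.zeros(net.n_nodes, dtype=bool)
            for name, v in input_assignment.items():
                st[net.index[name]] = bool(v)
            for i, name in enumerate(net.internal):
                st[net.index[name]] = bool((int(s) >> i) & 1)
            states.append(st)
        return (
            np.array(states, dtype=bool)
            if states
            else np.zeros((0, net.n_nodes), dtype=bool)
        )
    if method != "reduced":
        raise ValueError(f"unknown method {method!r}")
    known, free = _propagate_constants(net, input_assignment)
    known = {**input_assignment, **known}
    succ = _free_successor_map(net, known, free)
    fixed = np.flatnonzero(succ == np.arange(succ.size))
    states = [
        np.array(_full_state(net, known, free, int(s)), dtype=bool) for s in fixed
    ]
    return (
        np.array(states, dtype=bool)
        if states
        else np.zeros((0, net.n_nodes), dtype=bool)
    )


def all_attractors(net: BooleanNetwork, method: str = "reduced") -> AttractorReport:
    """Enumerate every synchronous attractor over all input assignments.

    Iterates the 2^|inputs| input conditions; within each, finds all cycles
    of the internal functional graph. Fixed points are cycles of length 1.
    """
    if net.n_internal > 24 and method == "exhaustive":
        raise ValueError("network too large for exhaustive sweep")
    report = AttractorReport(network_nodes=list(net.names))
    for values in itertools.product((0, 1), repeat=net.n_inputs):
        assignment = dict(zip(net.inputs, values))
        if method == "exhaustive":
            succ = _exhaustive_successor_map(net, assignment)
            known: dict[str, int] = dict(assignment)
            free = list(net.internal)
        else:
            known_i, free = _propagate_constants(net, assignment)
            known = {**assignment, **known_i}
            succ = _free_successor_map(net, known, free)
        for cyc in _cycles_of_map(succ):
            states = [_full_state(net, known, free, s) for s in cyc]
            if len(states) == 1:
                report.attractors.append(
                    Attractor("fixed_point", (states[0],), assignment)
                )
            else:
                report.attractors.append(
                    Attractor("cycle", _canonical_rotation(states), assignment)
                )
    return report


def verify_attractor(net: BooleanNetwork, attractor: Attractor) -> bool:
    """Check the cyclic-successor property and input constancy directly."""
    states = attractor.state_arrays()
    length = states.shape[0]
    if attractor.kind == "fixed_point" and length != 1:
        return False
    if attractor.kind == "cycle" and length < 2:
        return False
    input_idx = net.input_indices
    for k in range(length):
        expected = states[(k + 1) % length]
        if not np.array_equal(sync_step(net, states[k]), expected):
            return False
        if not np.array_equal(states[k][input_idx], states[0][input_idx]):
            return False
    for name, v in attractor.input_assignment.items():
        if bool(states[0][net.index[name]]) != bool(v):
            return False
    return True
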