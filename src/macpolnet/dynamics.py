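"""Synchronous and stochastic asynchronous update schemes.

Two update semantics are provided:

* synchronous — every non-input node recomputes simultaneously from the
  previous state; deterministic, and the scheme under which attractors are
  enumerated;
* asynchronous random sweep — one "time step" updates every non-input node
  once, sequentially, in a fresh uniformly random permutation, each node
  seeing the partially updated state. Eight such sweeps with 10^4 replicates
  is the default polarization protocol.

Fixed points coincide under both schemes; trajectories do not.

For exhaustive state-space work, states are packed 64-per-word into per-node
uint64 bit-planes (:class:`PackedStateBlock`) and all rules are evaluated
bitwise, which is what makes the 2^23-state sweeps per input condition cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BooleanNetwork

__all__ = [
    "sync_step",
    "async_sweep_step",
    "simulate_ensemble",
    "ensemble_from_states",
    "PackedStateBlock",
    "pack_states",
    "batch_successors",
    "TrajectoryEnsemble",
]


def sync_step(net: BooleanNetwork, state: np.ndarray) -> np.ndarray:
    """Synchronous successor: all rules applied to the same predecessor state."""
    state = net.check_state(state)
    return net.compiled.sync_matrix(state[None, :])[0]


def sync_step_matrix(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous successor of each row of an (m, n) boolean state matrix."""
    states = np.asarray(states, dtype=bool)
    if states.ndim != 2 or states.shape[1] != net.n_nodes:
        raise ValueError("expected an (m, n_nodes) state matrix")
    return net.compiled.sync_matrix(states)


def async_sweep_step(
    net: BooleanNetwork, state: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One asynchronous time step: a full random-permutation sweep.

    Every non-input node is updated exactly once, in a uniformly random
    order, each update seeing the current (partially updated) state. A state
    is a fixed point of the synchronous map iff it is returned unchanged for
    every permutation.
    """
    state = net.check_state(state).copy()
    compiled = net.compiled
    order = rng.permutation(net.internal_indices)
    cols = state[:, None]  # (n, 1) view: compiled funcs index rows
    for i in order:
        if compiled.funcs[i] is not None:
            state[i] = bool(np.asarray(compiled.funcs[i](cols)).ravel()[0])
        elif compiled.consts[i] is not None:
            state[i] = bool(compiled.consts[i])
        cols = state[:, None]
    return state


def _async_sweep_matrix(
    net: BooleanNetwork, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized asynchronous sweep with an independent permutation per row.

    Rows are grouped by which node they update at each sweep position, so the
    inner work stays vectorized while preserving per-replicate orders.
    """
    compiled = net.compiled
    internal = net.internal_indices
    m = internal.size
    n_rep = states.shape[0]
    # row r updates internal[perm[r, j]] at position j
    perm = np.argsort(rng.random((n_rep, m)), axis=1)
    out = states.copy()
    for j in range(m):
        node_of_row = perm[:, j]
        for k in range(m):
            rows = np.flatnonzero(node_of_row == k)
            if rows.size == 0:
                continue
            i = internal[k]
            if compiled.funcs[i] is not None:
                out[rows, i] = compiled.funcs[i](out[rows].T)
            elif compiled.consts[i] is not None:
                out[rows, i] = bool(compiled.consts[i])
    return out


@dataclass
class TrajectoryEnsemble:
    """Per-node mean activation across stochastic asynchronous replicates."""

    node_names: list[str]
    steps: int
    replicates: int
    mean_activation: np.ndarray  # (steps + 1, n_nodes), row 0 = initial
    rng_seed: int
    final_states: np.ndarray | None = field(default=None, repr=False)

    def mean_of(self, node: str) -> np.ndarray:
        return self.mean_activation[:, self.node_names.index(node)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns ``step, node, mean_activation``."""
        t, n = self.mean_activation.shape
        return pd.DataFrame(
            {
                "step": np.repeat(np.arange(t), n),
                "node": np.tile(np.array(self.node_names, dtype=object), t),
                "mean_activation": self.mean_activation.ravel(),
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.node_names,
            "steps": self.steps,
            "replicates": self.replicates,
            "rng_seed": self.rng_seed,
            "mean_activation": self.mean_activation.tolist(),
        }


def ensemble_from_states(
    net: BooleanNetwork,
    initial_states: np.ndarray,
    steps: int,
    seed: int,
    keep_final: bool = True,
) -> TrajectoryEnsemble:
    """Asynchronous sweep ensemble from an explicit (R, n) initial-state matrix.

    Each row evolves independently with its own random sweep permutations;
    mean activation is averaged across rows after every sweep.
    """
    states = np.array(initial_states, dtype=bool)
    if states.ndim != 2 or states.shape[1] != net.n_nodes:
        raise ValueError("expected an (R, n_nodes) initial-state matrix")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.empty((steps + 1, net.n_nodes), dtype=float)
    means[0] = states.mean(axis=0)
    for t in range(1, steps + 1):
        states = _async_sweep_matrix(net, states, rng)
        means[t] = states.mean(axis=0)
    return TrajectoryEnsemble(
        node_names=list(net.names),
        steps=steps,
        replicates=states.shape[0],
        mean_activation=means,
        rng_seed=seed,
        final_states=states if keep_final else None,
    )


def simulate_ensemble(
    net: BooleanNetwork,
    initial: np.ndarray,
    clamped_inputs: dict[str, int] | None = None,
    steps: int = 8,
    replicates: int = 10_000,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Ensemble of asynchronous trajectories from one initial state.

    ``clamped_inputs`` overrides input-node values in the initial state;
    inputs are never updated, so a clamp holds for the whole simulation.
    """
    state = net.check_state(initial).copy()
    if clamped_inputs:
        for name, value in clamped_inputs.items():
            if name not in net.inputs:
                raise KeyError(f"{name!r} is not an input node")
            state[net.index[name]] = bool(value)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    states = np.tile(state, (replicates, 1))
    return ensemble_from_states(net, states, steps=steps, seed=seed)


# -- bit-parallel batch evaluation -------------------------------------------

_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class PackedStateBlock:
    """A block of states packed 64-per-word into per-node bit-planes.

    ``planes[i]`` holds node ``i`` for all states: bit ``j`` of word ``w`` is
    the value of node ``i`` in state ``64*w + j``.
    """

    n_states: int
    planes: list[np.ndarray]

    @property
    def n_words(self) -> int:
        return self.planes[0].size

    def unpack(self) -> np.ndarray:
        """Back to an (n_states, n_nodes) boolean matrix."""
        cols = [
            np.unpackbits(p.view(np.uint8), bitorder="little")[: self.n_states]
            for p in self.planes
        ]
        return np.array(cols, dtype=bool).T


def pack_states(states: np.ndarray) -> PackedStateBlock:
    """Pack an (m, n) boolean state matrix into bit-planes."""
    states = np.asarray(states, dtype=bool)
    m, n = states.shape
    n_words = (m + 63) // 64
    planes = []
    for i in range(n):
        bits = np.zeros(n_words * 64, dtype=np.uint8)
        bits[:m] = states[:, i]
        planes.append(np.packbits(bits, bitorder="little").view(np.uint64).copy())
    return PackedStateBlock(n_states=m, planes=planes)


def batch_successors(net: BooleanNetwork, block: PackedStateBlock) -> PackedStateBlock:
    """Synchronous successors of every packed state, evaluated bitwise.

    Bit-exact with :func:`sync_step` applied state-by-state; this is the
    workhorse behind exhaustive attractor enumeration (64 states per word
    per numpy op).
    """
    if len(block.planes) != net.n_nodes:
        raise ValueError("block plane count does not match network size")
    succ = net.compiled.eval_packed(block.planes, block.n_words)
    mask_bits = block.n_states % 64
    if mask_bits:
        # zero the padding bits so unpack() of successors stays clean
        tail = np.uint64((1 << mask_bits) - 1)
        for p in succ:
            p[-1] &= tail
    return PackedStateBlock(n_states=block.n_states, planes=succ)
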