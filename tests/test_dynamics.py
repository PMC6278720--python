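"""Update schemes: synchronous, asynchronous sweeps, bit-parallel batches."""

import numpy as np
import pytest

from macpolnet import (
    async_sweep_step,
    batch_successors,
    macrophage_network,
    pack_states,
    parse_rules,
    simulate_ensemble,
    sync_step,
)
from macpolnet.dynamics import ensemble_from_states, sync_step_matrix
from macpolnet.synthetic import random_states


class TestSyncStep:
    def test_zero_state_is_fixed_without_inputs(self, macnet):
        zero = macnet.zero_state()
        assert np.array_equal(sync_step(macnet, zero), zero)

    def test_il4_cascade_first_two_steps(self, macnet):
        """IL-4 reaches its receptor first, then the three M2a regulators."""
        s = macnet.state_from_active(["IL4_e"])
        s1 = sync_step(macnet, s)
        assert macnet.active_nodes(s1) == ["IL4_e", "IL4Ra"]
        s2 = sync_step(macnet, s1)
        assert set(macnet.active_nodes(s2)) == {
            "IL4_e", "IL4Ra", "PPARg", "STAT6", "JMJD3"
        }

    def test_inputs_held_constant(self, macnet):
        s = macnet.state_from_active(["LPS_e", "IC_e"])
        for _ in range(10):
            s = sync_step(macnet, s)
            assert s[macnet.index["LPS_e"]] and s[macnet.index["IC_e"]]

    def test_state_length_mismatch(self, macnet):
        with pytest.raises(ValueError):
            sync_step(macnet, np.zeros(7, dtype=bool))


class TestAsyncSweep:
    def test_fixed_points_invariant_for_any_permutation(self, macnet):
        fp = macnet.state_from_active(["IL10R", "STAT3", "IL10_out"])
        for seed in range(25):
            rng = np.random.default_rng(seed)
            assert np.array_equal(async_sweep_step(macnet, fp, rng), fp)

    def test_acyclic_cascade_matches_iterated_sync(self):
        """Without feedback one sweep can only land on the sync limit path."""
        net = parse_rules("targets, factors\nS, S\nA, S\nB, A\nC, B")
        start = net.state_from_active(["S"])
        # sync fixed point of the cascade
        target = start
        for _ in range(5):
            target = sync_step(net, target)
        rng = np.random.default_rng(0)
        s = start
        for _ in range(4):  # at most depth sweeps to converge
            s = async_sweep_step(net, s, rng)
        assert np.array_equal(s, target)

    def test_vectorized_sweep_matches_scalar_distribution(self, macnet):
        """Mean activation from the matrix path agrees with per-state sweeps."""
        start = macnet.state_from_active(["IL4_e"])
        ens = simulate_ensemble(macnet, start, steps=3, replicates=4000, seed=5)
        rng = np.random.default_rng(99)
        scalar = np.zeros(macnet.n_nodes)
        n = 1500
        for _ in range(n):
            s = start
            for _ in range(3):
                s = async_sweep_step(macnet, s, rng)
            scalar += s
        scalar /= n
        # binomial error at n=1500 is ~1.3% per node; allow 5 sigma
        assert np.max(np.abs(scalar - ens.mean_activation[3])) < 0.065


class TestEnsembles:
    def test_determinism_same_seed(self, macnet):
        a = simulate_ensemble(macnet, macnet.zero_state(),
                              {"IL4_e": 1}, steps=4, replicates=200, seed=42)
        b = simulate_ensemble(macnet, macnet.zero_state(),
                              {"IL4_e": 1}, steps=4, replicates=200, seed=42)
        assert np.array_equal(a.mean_activation, b.mean_activation)
        assert np.array_equal(a.final_states, b.final_states)

    def test_single_replicate_is_binary(self):
        net = parse_rules("targets, factors\nS, S\nA, S\nB, A")
        ens = simulate_ensemble(net, net.state_from_active(["S"]),
                                steps=3, replicates=1, seed=0)
        assert set(np.unique(ens.mean_activation)) <= {0.0, 1.0}

    def test_no_inputs_zero_state_stays_zero(self, macnet):
        ens = simulate_ensemble(macnet, macnet.zero_state(),
                                steps=8, replicates=50, seed=3)
        assert not ens.mean_activation.any()

    def test_row_zero_is_initial_state(self, macnet):
        start = macnet.state_from_active(["IL10_e"])
        ens = simulate_ensemble(macnet, macnet.zero_state(),
                                {"IL10_e": 1}, steps=2, replicates=10, seed=1)
        assert np.array_equal(ens.mean_activation[0], start.astype(float))

    def test_unknown_clamp_rejected(self, macnet):
        with pytest.raises(KeyError):
            simulate_ensemble(macnet, macnet.zero_state(), {"STAT1": 1},
                              steps=1, replicates=1, seed=0)

    def test_tidy_frame_shape(self, macnet):
        ens = simulate_ensemble(macnet, macnet.zero_state(),
                                steps=2, replicates=5, seed=0)
        frame = ens.to_frame()
        assert list(frame.columns) == ["step", "node", "mean_activation"]
        assert len(frame) == 3 * macnet.n_nodes


class TestBitParallel:
    def test_pack_unpack_identity(self, macnet):
        states = random_states(macnet.n_nodes, 1000, seed=0)
        assert np.array_equal(pack_states(states).unpack(), states)

    def test_single_state_block_equals_sync_step(self, macnet):
        s = macnet.state_from_active(["LPS_e", "IL10_e"])
        block = pack_states(s[None, :])
        succ = batch_successors(macnet, block).unpack()[0]
        assert np.array_equal(succ, sync_step(macnet, s))

    def test_batch_equals_rowwise_on_large_sample(self, macnet):
        """Bit-parallel evaluation is bit-exact with the boolean-matrix path."""
        states = random_states(macnet.n_nodes, 100_000, seed=7)
        packed = batch_successors(macnet, pack_states(states)).unpack()
        assert np.array_equal(packed, sync_step_matrix(macnet, states))

    def test_batch_equals_scalar_loop(self, macnet):
        states = random_states(macnet.n_nodes, 500, seed=11)
        packed = batch_successors(macnet, pack_states(states)).unpack()
        for row in range(0, 500, 7):
            assert np.array_equal(packed[row], sync_step(macnet, states[row]))
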