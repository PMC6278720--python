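"""Attractor enumeration: oracle examples, method equivalence, verification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macpolnet import (
    Attractor,
    all_attractors,
    async_sweep_step,
    fixed_points_for_inputs,
    parse_rules,
    random_network,
    verify_attractor,
)
from macpolnet.synthetic import RandomNetworkSpec

from conftest import no_input_assignment


def _active_sets(net, states):
    return sorted(frozenset(net.active_nodes(s)) for s in states)


class TestHandDerivableFixedPoints:
    def test_no_input_condition_has_exactly_three(self, macnet):
        """Resting conditions: the naive state plus the two autocrine loops."""
        fps = fixed_points_for_inputs(macnet, no_input_assignment(macnet))
        assert _active_sets(macnet, fps) == sorted([
            frozenset(),
            frozenset({"IL1b", "IL1R", "NF_kB", "IL12_out"}),
            frozenset({"IL10R", "STAT3", "IL10_out"}),
        ])

    def test_il4_only_fixed_point_is_unique_m2a(self, macnet):
        assignment = {**no_input_assignment(macnet), "IL4_e": 1}
        fps = fixed_points_for_inputs(macnet, assignment)
        assert fps.shape[0] == 1
        active = set(macnet.active_nodes(fps[0]))
        assert active == {
            "IL4_e", "IL4Ra", "IL10R", "PPARg", "STAT6", "JMJD3",
            "KLF4", "SOCS1", "IRF4", "IL10_out",
        }
        assert not fps[0][macnet.index["STAT3"]]

    def test_lps_only_is_multistable(self, macnet):
        assignment = {**no_input_assignment(macnet), "LPS_e": 1}
        fps = fixed_points_for_inputs(macnet, assignment)
        assert fps.shape[0] >= 2
        sets = _active_sets(macnet, fps)
        has_m1_like = any(
            {"NF_kB", "IL12_out"} <= s and "STAT3" not in s for s in sets
        )
        has_m2c_like = any(
            {"STAT3", "IL10_out"} <= s and "IL12_out" not in s for s in sets
        )
        assert has_m1_like and has_m2c_like

    def test_reduced_equals_exhaustive_per_assignment(self, macnet):
        for assignment in (
            no_input_assignment(macnet),
            {**no_input_assignment(macnet), "IL4_e": 1},
            {**no_input_assignment(macnet), "LPS_e": 1, "IC_e": 1},
            {name: 1 for name in macnet.inputs},
        ):
            fast = fixed_points_for_inputs(macnet, assignment)
            brute = fixed_points_for_inputs(macnet, assignment, method="exhaustive")
            assert _active_sets(macnet, fast) == _active_sets(macnet, brute)

    def test_missing_input_rejected(self, macnet):
        with pytest.raises(ValueError, match="misses"):
            fixed_points_for_inputs(macnet, {"IL4_e": 1})


class TestTinyNetworks:
    def test_negation_loop_is_a_pure_two_cycle(self):
        net = parse_rules("targets, factors\nx, !x")
        report = all_attractors(net)
        assert report.n_fixed_points == 0
        assert report.n_cycles == 1
        assert report.cycle_lengths == [2]

    def test_two_node_swap(self):
        net = parse_rules("targets, factors\nx, y\ny, x")
        report = all_attractors(net)
        assert report.n_fixed_points == 2
        assert report.n_cycles == 1
        assert report.cycle_lengths == [2]

    def test_three_rotation(self):
        net = parse_rules("targets, factors\nx, z\ny, x\nz, y")
        report = all_attractors(net)
        assert report.n_fixed_points == 2  # all-off / all-on
        assert sorted(report.cycle_lengths) == [3, 3]


class TestMacrophageCensus:
    """Exact census of the network as printed.

    The counts below characterize the rule table shipped here; they are the
    exhaustively verified values for this model (see docs/methods.md for how
    they relate to the larger counts reported for the original model, which
    included auto-regulatory interactions that were never published).
    """

    def test_counts(self, census):
        assert census.n_fixed_points == 156
        assert census.n_cycles == 88
        assert set(census.cycle_lengths) == {3}
        assert census.n_total == 244

    def test_every_attractor_verifies(self, macnet, census):
        assert all(verify_attractor(macnet, a) for a in census.attractors)

    def test_attractors_disjoint_across_inputs(self, census):
        seen = set()
        for a in census.attractors:
            for s in a.states:
                assert s not in seen
                seen.add(s)

    def test_census_matches_exhaustive_on_sampled_assignments(self, macnet, census):
        """Bit-parallel full-space sweep agrees with the reduced enumeration."""
        by_assignment = {}
        for a in census.attractors:
            key = tuple(a.input_assignment[n] for n in macnet.inputs)
            by_assignment.setdefault(key, []).append(a)
        for key in [(0,) * 7, (0, 0, 0, 1, 1, 0, 0), (1,) * 7,
                    (0, 0, 0, 0, 0, 1, 0), (0, 1, 0, 1, 0, 0, 1)]:
            assignment = dict(zip(macnet.inputs, key))
            from macpolnet.attractors import (
                _cycles_of_map,
                _exhaustive_successor_map,
            )
            succ = _exhaustive_successor_map(macnet, assignment)
            cycles = _cycles_of_map(succ)
            assert len(cycles) == len(by_assignment.get(key, []))
            assert sorted(len(c) for c in cycles) == sorted(
                a.length for a in by_assignment.get(key, [])
            )

    def test_fixed_points_scheme_invariant(self, macnet, census):
        """Fixed points are unchanged by asynchronous sweeps (sampled orders)."""
        rng = np.random.default_rng(0)
        fps = census.steady_states()
        sample = fps[rng.choice(fps.shape[0], size=20, replace=False)]
        for s in sample:
            for seed in (1, 2, 3):
                out = async_sweep_step(macnet, s, np.random.default_rng(seed))
                assert np.array_equal(out, s)


class TestVerifyAttractor:
    def test_flipped_bit_fails(self, macnet, census):
        fp = next(a for a in census.attractors if a.kind == "fixed_point")
        bits = np.array(fp.states[0], dtype=bool)
        internal = macnet.index["STAT3"]
        bits[internal] = ~bits[internal]
        broken = Attractor("fixed_point", (tuple(int(b) for b in bits),),
                           fp.input_assignment)
        assert not verify_attractor(macnet, broken)

    def test_wrong_rotation_fails(self, macnet, census):
        cyc = next(a for a in census.attractors if a.kind == "cycle")
        reversed_states = tuple(reversed(cyc.states))
        assert not verify_attractor(
            macnet, Attractor("cycle", reversed_states, cyc.input_assignment)
        )
        assert verify_attractor(macnet, cyc)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(10, 14), st.integers(0, 3))
def test_reduced_equals_naive_on_random_networks(seed, n_nodes, n_inputs):
    """Optimized enumeration ≡ naive full-space enumeration (small networks)."""
    net = random_network(
        RandomNetworkSpec(n_nodes=n_nodes, n_inputs=n_inputs, fixed_k=2),
        seed=seed,
    )
    fast = all_attractors(net, method="reduced")
    naive = all_attractors(net, method="exhaustive")
    def signature(report):
        return sorted(
            (a.kind, a.states) for a in report.attractors
        )
    assert signature(fast) == signature(naive)
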