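"""Polarization, repolarization, resilience and knockout protocols.

The biological protocols drive the network with the eliciting stimuli of the
four polarized phenotypes:

* M1  — any combination of IFN-γ, IL-1β, LPS and GM-CSF (a fresh uniformly
  random non-empty subset per replicate in stochastic ensembles);
* M2a — IL-4;
* M2b — immune complexes together with LPS (or IL-1β);
* M2c — IL-10.

Starting states are representative steady states of each phenotype: among
the fixed points reached under a phenotype's own eliciting stimulus that
classify canonically to it, the lexicographically smallest state (a
deterministic, reproducible choice). When a polarized cell is restimulated,
all seven inputs are reset to the new stimulus before simulating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attractors import all_attractors, fixed_points_for_inputs
from .dynamics import TrajectoryEnsemble, ensemble_from_states
from .network import BooleanNetwork
from .phenotypes import ALL_LABELS, classify_matrix, classify_report

__all__ = [
    "STIMULI",
    "M1_STIMULUS_POOL",
    "M1_MARKERS",
    "derive_seed",
    "representative_states",
    "polarize",
    "repolarization_matrix",
    "m1_resilience_stat",
    "knockout_scan",
    "RepolarizationResult",
    "KnockoutScanResult",
]

#: Pro-inflammatory stimuli; ensembles draw random non-empty subsets of these.
M1_STIMULUS_POOL = ["IFNg_e", "IL1b_e", "LPS_e", "GM_CSF_e"]

#: Deterministic eliciting stimulus per phenotype (used for start-state
#: selection and for non-randomized simulations).
STIMULI: dict[str, dict[str, int]] = {
    "M1": {name: 1 for name in M1_STIMULUS_POOL},
    "M2a": {"IL4_e": 1},
    "M2b": {"IC_e": 1, "LPS_e": 1},
    "M2c": {"IL10_e": 1},
    "none": {},
}

#: Pro-inflammatory marker nodes used by the resilience statistic.
M1_MARKERS = ["STAT1", "STAT5", "NF_kB", "IL12_out"]


def derive_seed(seed: int, *tags) -> int:
    """Deterministic child seed (< 2^31) for a tagged sub-experiment.

    Tags are hashed with CRC32 (stable across processes, unlike ``hash``).
    """
    import zlib

    crcs = [zlib.crc32(str(t).encode()) % (2**31) for t in tags]
    ss = np.random.SeedSequence([int(seed)] + crcs)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def m2b_stimulus(variant: str = "LPS") -> dict[str, int]:
    """M2b eliciting stimulus: IC plus LPS (default) or IC plus IL-1β."""
    if variant == "LPS":
        return {"IC_e": 1, "LPS_e": 1}
    if variant == "IL1b":
        return {"IC_e": 1, "IL1b_e": 1}
    raise ValueError(f"unknown M2b variant {variant!r}")


def _full_input_assignment(net: BooleanNetwork, stimulus: dict[str, int]) -> dict[str, int]:
    for name in stimulus:
        if name not in net.inputs:
            raise KeyError(f"{name!r} is not an input node")
    return {name: int(stimulus.get(name, 0)) for name in net.inputs}


def representative_states(
    net: BooleanNetwork, m2b_variant: str = "LPS"
) -> dict[str, np.ndarray]:
    """One representative steady state per polarized phenotype.

    For each phenotype, enumerate the fixed points under its eliciting
    stimulus, keep those classified canonically to the phenotype, and return
    the lexicographically smallest (bit order = node order).
    """
    stimuli = dict(STIMULI)
    stimuli["M2b"] = m2b_stimulus(m2b_variant)
    out: dict[str, np.ndarray] = {}
    for phenotype in ("M1", "M2a", "M2b", "M2c"):
        assignment = _full_input_assignment(net, stimuli[phenotype])
        fps = fixed_points_for_inputs(net, assignment)
        labels = classify_matrix(net, fps)
        candidates = fps[labels == phenotype]
        if candidates.shape[0] == 0:
            raise ValueError(
                f"no steady state classifies as {phenotype} under its stimulus"
            )
        order = np.lexsort(candidates.T[::-1])
        out[phenotype] = candidates[order[0]]
    return out


def _initial_matrix(
    net: BooleanNetwork,
    start: np.ndarray,
    stimulus: dict[str, int] | str,
    replicates: int,
    rng: np.random.Generator,
    randomize_m1: bool = True,
) -> np.ndarray:
    """Tile the start state and impose the stimulus on the input nodes.

    All inputs are reset (stimulus on, everything else off), modelling the
    change of extracellular environment. The "M1" stimulus draws an
    independent uniformly random non-empty subset of the pro-inflammatory
    pool for every replicate.
    """
    states = np.tile(net.check_state(start), (replicates, 1))
    if isinstance(stimulus, str) and stimulus == "M1" and randomize_m1:
        for name in net.inputs:
            states[:, net.index[name]] = False
        pool_idx = [net.index[n] for n in M1_STIMULUS_POOL]
        n_pool = len(pool_idx)
        # uniform over the 2^4 - 1 non-empty subsets
        subsets = rng.integers(1, 1 << n_pool, size=replicates)
        for b, i in enumerate(pool_idx):
            states[:, i] = (subsets >> b) & 1
        return states
    if isinstance(stimulus, str):
        stimulus = STIMULI[stimulus]
    assignment = _full_input_assignment(net, stimulus)
    for name, value in assignment.items():
        states[:, net.index[name]] = bool(value)
    return states


def polarize(
    net: BooleanNetwork,
    stimulus: dict[str, int] | str,
    start: np.ndarray | None = None,
    steps: int = 8,
    replicates: int = 10_000,
    seed: int = 0,
    randomize_m1: bool = True,
) -> TrajectoryEnsemble:
    """Asynchronous polarization ensemble from a start state under a stimulus.

    ``start=None`` uses the naive M0 state (all nodes off). ``stimulus`` is
    a phenotype name from :data:`STIMULI` or an explicit input assignment.
    """
    if start is None:
        start = net.zero_state()
    rng = np.random.default_rng(derive_seed(seed, "stimulus-draw"))
    states = _initial_matrix(net, start, stimulus, replicates, rng, randomize_m1)
    return ensemble_from_states(net, states, steps=steps, seed=derive_seed(seed, "sweeps"))


@dataclass
class RepolarizationResult:
    """4x4 grid of repolarization ensembles and endpoint phenotype calls."""

    ensembles: dict[tuple[str, str], TrajectoryEnsemble] = field(default_factory=dict)
    endpoint_distributions: dict[tuple[str, str], pd.Series] = field(
        default_factory=dict
    )

    def endpoint_frame(self) -> pd.DataFrame:
        """Rows (start, stimulus), columns phenotype labels, values fractions."""
        rows = {
            f"{start}+{stim}": dist
            for (start, stim), dist in self.endpoint_distributions.items()
        }
        frame = pd.DataFrame(rows).T
        frame.index.name = "start+stimulus"
        return frame


def repolarization_matrix(
    net: BooleanNetwork,
    steps: int = 8,
    replicates: int = 10_000,
    seed: int = 0,
    m2b_variant: str = "LPS",
) -> RepolarizationResult:
    """All 16 (initial phenotype x stimulus) repolarization ensembles.

    For each pair, the representative steady state of the start phenotype is
    driven by the stimulus for ``steps`` asynchronous sweeps in
    ``replicates`` independent replicates; endpoint states are classified
    and returned as a label distribution (fractions summing to one).
    """
    starts = representative_states(net, m2b_variant=m2b_variant)
    result = RepolarizationResult()
    phenotypes = ("M1", "M2a", "M2b", "M2c")
    for start_name in phenotypes:
        for stim_name in phenotypes:
            stimulus: dict[str, int] | str = stim_name
            if stim_name == "M2b":
                stimulus = m2b_stimulus(m2b_variant)
            ens = polarize(
                net,
                stimulus if stim_name != "M1" else "M1",
                start=starts[start_name],
                steps=steps,
                replicates=replicates,
                seed=derive_seed(seed, start_name, stim_name),
            )
            labels = classify_matrix(net, ens.final_states)
            dist = pd.Series(0.0, index=ALL_LABELS, name="fraction")
            uniq, cnt = np.unique(labels, return_counts=True)
            for lbl, c in zip(uniq, cnt):
                dist[lbl] = c / labels.size
            result.ensembles[(start_name, stim_name)] = ens
            result.endpoint_distributions[(start_name, stim_name)] = dist
    return result


def m1_resilience_stat(
    net: BooleanNetwork,
    steps: int = 8,
    replicates: int = 10_000,
    seed: int = 0,
    m2b_variant: str = "LPS",
) -> pd.Series:
    """Peak reactivation of pro-inflammatory markers in M2 -> M1 challenges.

    For each anti-inflammatory start (M2a, M2b, M2c) under M1 stimuli, the
    statistic is the maximum over time steps and over the M1 markers that
    were inactive at step 0 of the ensemble mean activation. Values stay low
    when the anti-inflammatory programme locks out re-polarization.
    """
    starts = representative_states(net, m2b_variant=m2b_variant)
    out = {}
    for start_name in ("M2a", "M2b", "M2c"):
        ens = polarize(
            net,
            "M1",
            start=starts[start_name],
            steps=steps,
            replicates=replicates,
            seed=derive_seed(seed, start_name, "M1"),
        )
        peak = 0.0
        for marker in M1_MARKERS:
            track = ens.mean_of(marker)
            if track[0] == 0:  # restrict to initially-inactive markers
                peak = max(peak, float(track.max()))
        out[start_name] = peak
    return pd.Series(out, name="peak_m1_marker_activation")


@dataclass
class KnockoutScanResult:
    """Per-phenotype steady-state counts for systematic node clamps."""

    counts: pd.DataFrame  # rows: WT + (node, mode); columns: phenotype labels

    def fold_change(self) -> pd.DataFrame:
        """Perturbed / wild-type counts; infinite where the WT count is zero."""
        wt = self.counts.loc["WT"].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = self.counts.astype(float).div(wt, axis=1)
        fc[self.counts.eq(0) & (wt == 0)] = 1.0  # 0/0: unchanged
        return fc.drop(index="WT")

    def to_csv(self) -> str:
        fc = self.fold_change().replace(np.inf, np.nan)
        merged = self.counts.join(fc, rsuffix="_fold_change")
        return merged.to_csv(na_rep="NA")


def knockout_scan(
    net: BooleanNetwork, regulators: list[str] | None = None
) -> KnockoutScanResult:
    """Systematic knockout (clamp 0) and ectopic expression (clamp 1) screen.

    Every internal regulator is clamped in turn, the full attractor census
    is recomputed, and the steady states are classified; the wild-type row
    makes the fold changes of the phenotype counts explicit.
    """
    if regulators is None:
        regulators = [
            n.name
            for n in net.nodes
            if n.category == "regulator" and n.name not in net.inputs
        ]
    rows = {}
    wt_states = all_attractors(net).steady_states()
    rows["WT"] = classify_report(net, wt_states)
    for node in regulators:
        for mode, value in (("knockout", 0), ("ectopic", 1)):
            perturbed = net.apply_perturbation(node, value)
            states = all_attractors(perturbed).steady_states()
            rows[f"{node}:{mode}"] = classify_report(perturbed, states)
    counts = pd.DataFrame(rows).T
    counts.index.name = "perturbation"
    return KnockoutScanResult(counts=counts)
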