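"""Phenotype classification of network states.

Ten marker nodes determine the polarization fate. A state matches

* M0  — no node active anywhere in the network;
* M1  — IL-12 plus at least one of STAT1, STAT5, NF-κB;
* M2a — all of PPARγ, STAT6, JMJD3 and IL-10;
* M2b — ERK and IL-10;
* M2c — STAT3 and IL-10.

The definitions constrain only the named nodes, so they can overlap; a state
matching exactly one definition gets that canonical label, a state matching
two or more is *hybrid* (mixed-marker expression, the substrate of the
polarization-continuum interpretation), and a state matching none is
*unclassified*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BooleanNetwork

__all__ = [
    "MARKER_NODES",
    "CANONICAL_LABELS",
    "PhenotypeCall",
    "classify",
    "classify_matrix",
    "classify_report",
]

#: The marker panel determining polarization fate.
MARKER_NODES = [
    "STAT1",
    "STAT5",
    "NF_kB",
    "IL12_out",
    "PPARg",
    "STAT6",
    "JMJD3",
    "ERK",
    "STAT3",
    "IL10_out",
]

CANONICAL_LABELS = ["M0", "M1", "M2a", "M2b", "M2c"]
ALL_LABELS = CANONICAL_LABELS + ["hybrid", "unclassified"]


@dataclass(frozen=True)
class PhenotypeCall:
    """Classification of one state: final label plus the matched definitions."""

    label: str
    matched: frozenset[str]


#: Markers named by each definition (used by the strict pattern variant).
_DEFINITION_MARKERS = {
    "M0": MARKER_NODES,
    "M1": ["STAT1", "STAT5", "NF_kB", "IL12_out"],
    "M2a": ["PPARg", "STAT6", "JMJD3", "IL10_out"],
    "M2b": ["ERK", "IL10_out"],
    "M2c": ["STAT3", "IL10_out"],
}


def _definition_matrix(
    net: BooleanNetwork, states: np.ndarray, mode: str = "definitions"
) -> np.ndarray:
    """(m, 5) boolean matrix: which of M0..M2c each state matches.

    ``mode="definitions"`` applies the marker definitions literally (they
    constrain only the nodes they name). ``mode="patterns"`` additionally
    requires every marker *not* named by a definition to be inactive — the
    marker-row reading of the expression-pattern figure.
    """

    def col(name: str) -> np.ndarray:
        return states[:, net.index[name]]

    m = np.zeros((states.shape[0], 5), dtype=bool)
    m[:, 0] = ~states.any(axis=1)
    m[:, 1] = col("IL12_out") & (col("STAT1") | col("STAT5") | col("NF_kB"))
    m[:, 2] = col("PPARg") & col("STAT6") & col("JMJD3") & col("IL10_out")
    m[:, 3] = col("ERK") & col("IL10_out")
    m[:, 4] = col("STAT3") & col("IL10_out")
    if mode == "patterns":
        for j, lbl in enumerate(CANONICAL_LABELS):
            named = set(_DEFINITION_MARKERS[lbl])
            for marker in MARKER_NODES:
                if marker not in named:
                    m[:, j] &= ~col(marker)
    elif mode != "definitions":
        raise ValueError(f"unknown classification mode {mode!r}")
    return m


def classify(
    net: BooleanNetwork, state: np.ndarray, mode: str = "definitions"
) -> PhenotypeCall:
    """Classify a single state (pure function of the state bits)."""
    state = net.check_state(state)
    row = _definition_matrix(net, state[None, :], mode)[0]
    matched = frozenset(
        lbl for lbl, hit in zip(CANONICAL_LABELS, row) if hit
    )
    if not matched:
        label = "unclassified"
    elif len(matched) == 1:
        (label,) = matched
    else:
        label = "hybrid"
    return PhenotypeCall(label=label, matched=matched)


def classify_matrix(
    net: BooleanNetwork, states: np.ndarray, mode: str = "definitions"
) -> np.ndarray:
    """Vectorized labels for an (m, n) state matrix (array of label strings)."""
    states = np.asarray(states, dtype=bool)
    defs = _definition_matrix(net, states, mode)
    n_matched = defs.sum(axis=1)
    labels = np.full(states.shape[0], "unclassified", dtype=object)
    labels[n_matched > 1] = "hybrid"
    for j, lbl in enumerate(CANONICAL_LABELS):
        labels[(n_matched == 1) & defs[:, j]] = lbl
    return labels


def classify_report(
    net: BooleanNetwork, states: np.ndarray, mode: str = "definitions"
) -> pd.Series:
    """Per-label counts over a set of states.

    Canonical labels count states matching exactly one definition; the
    counts always sum to the number of states.
    """
    labels = classify_matrix(
        net, np.asarray(states, dtype=bool).reshape(-1, net.n_nodes), mode
    )
    counts = pd.Series(0, index=ALL_LABELS, dtype=int, name="count")
    uniques, freq = np.unique(labels, return_counts=True)
    for lbl, c in zip(uniques, freq):
        counts[lbl] = int(c)
    return counts
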