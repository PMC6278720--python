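"""The curated macrophage polarization network.

Thirty nodes: seven extracellular stimuli (inputs), seven receptors, fourteen
intracellular transducers/transcription factors and the two secreted products
IL-12 and IL-10. Update rules encode the published regulatory logic: M1
polarization runs through IFN-γ/JAK-STAT1, GM-CSF/STAT5 and LPS/IL-1β/NF-κB
signalling onto IL-12; the alternative (M2) programmes run through
IL-4Rα/STAT6/PPARγ/JMJD3 (M2a), FcγR/ERK (M2b) and IL-10R/STAT3 (M2c) onto
IL-10, with mutual inhibition between the pro- and anti-inflammatory arms.
"""

from __future__ import annotations

from .network import BooleanNetwork, BooleanRule, NodeSpec
from .expr import parse_expression

__all__ = [
    "macrophage_network",
    "INPUT_NODES",
    "RECEPTOR_NODES",
    "REGULATOR_NODES",
    "OUTPUT_NODES",
    "DISPLAY_NAMES",
    "CURATED_EDGES",
    "curated_edge_table",
]

#: Extracellular stimuli, held constant during dynamics.
INPUT_NODES = ["IFNg_e", "IL1b_e", "GM_CSF_e", "LPS_e", "IC_e", "IL4_e", "IL10_e"]

#: Membrane receptors.
RECEPTOR_NODES = ["IFNgR", "CSF2Ra", "IL1R", "TLR4", "FcgR", "IL4Ra", "IL10R"]

#: Intracellular transducers / transcription factors.
REGULATOR_NODES = [
    "STAT1",
    "STAT5",
    "NF_kB",
    "PPARg",
    "STAT6",
    "JMJD3",
    "STAT3",
    "IRF3",
    "ERK",
    "KLF4",
    "SOCS1",
    "IRF4",
    "IL1b",
    "IFNb",
]

#: Secreted products defining the polarized phenotypes.
OUTPUT_NODES = ["IL12_out", "IL10_out"]

#: Canonical identifier -> display name (Greek letters, hyphens).
DISPLAY_NAMES = {
    "IFNg_e": "IFN-γ_e",
    "IL1b_e": "IL-1β_e",
    "GM_CSF_e": "GM-CSF_e",
    "LPS_e": "LPS_e",
    "IC_e": "IC_e",
    "IL4_e": "IL-4_e",
    "IL10_e": "IL-10_e",
    "IFNgR": "IFN-γR",
    "CSF2Ra": "CSF2Rα",
    "IL1R": "IL-1R",
    "TLR4": "TLR4",
    "FcgR": "FcγR",
    "IL4Ra": "IL-4Rα",
    "IL10R": "IL-10R",
    "STAT1": "STAT1",
    "STAT5": "STAT5",
    "NF_kB": "NF-κB",
    "PPARg": "PPARγ",
    "STAT6": "STAT6",
    "JMJD3": "JMJD3",
    "STAT3": "STAT3",
    "IRF3": "IRF3",
    "ERK": "ERK",
    "KLF4": "KLF4",
    "SOCS1": "SOCS1",
    "IRF4": "IRF4",
    "IL1b": "IL-1β",
    "IFNb": "IFN-β",
    "IL12_out": "IL-12",
    "IL10_out": "IL-10",
}

#: Update rules for the 23 non-input nodes (``targets, factors`` dialect).
RULES = {
    "IFNgR": "IFNg_e | IFNb",
    "CSF2Ra": "GM_CSF_e",
    "IL1R": "IL1b_e | IL1b",
    "TLR4": "LPS_e & !FcgR",
    "FcgR": "(IC_e & LPS_e) | (IC_e & IL1b_e)",
    "IL4Ra": "IL4_e",
    "IL10R": "IL10_e | IL10_out",
    "STAT1": "IFNgR & !(SOCS1 | STAT3)",
    "STAT5": "CSF2Ra & !(STAT3 | IRF4)",
    "NF_kB": "(IL1R | TLR4) & !(STAT3 | FcgR | PPARg | KLF4)",
    "PPARg": "IL4Ra",
    "STAT6": "IL4Ra",
    "JMJD3": "IL4Ra",
    "STAT3": "IL10R & !(FcgR | PPARg)",
    "IRF3": "TLR4",
    "ERK": "FcgR",
    "KLF4": "STAT6",
    "SOCS1": "STAT6",
    "IRF4": "JMJD3",
    "IL1b": "NF_kB",
    "IFNb": "IRF3",
    "IL12_out": "STAT1 | STAT5 | NF_kB",
    "IL10_out": "PPARg | STAT6 | JMJD3 | STAT3 | ERK",
}

#: Curated signed interaction list (source, sign, target); the published
#: interaction table. Three rule-derived edges (IL1b->IL1R, IL10_out->IL10R,
#: JMJD3->IL10_out) are absent from it, which validate_against_edge_table
#: reports; the rules are authoritative for dynamics.
CURATED_EDGES = [
    ("IFNg_e", "+", "IFNgR"),
    ("IL1b_e", "+", "IL1R"),
    ("GM_CSF_e", "+", "CSF2Ra"),
    ("LPS_e", "+", "TLR4"),
    ("LPS_e", "+", "FcgR"),
    ("IC_e", "+", "FcgR"),
    ("IL1b_e", "+", "FcgR"),
    ("IL4_e", "+", "IL4Ra"),
    ("IL10_e", "+", "IL10R"),
    ("IFNgR", "+", "STAT1"),
    ("CSF2Ra", "+", "STAT5"),
    ("IL1R", "+", "NF_kB"),
    ("TLR4", "+", "IRF3"),
    ("TLR4", "+", "NF_kB"),
    ("FcgR", "+", "ERK"),
    ("FcgR", "-", "NF_kB"),
    ("FcgR", "-", "STAT3"),
    ("FcgR", "-", "TLR4"),
    ("IL4Ra", "+", "PPARg"),
    ("IL4Ra", "+", "STAT6"),
    ("IL4Ra", "+", "JMJD3"),
    ("IL10R", "+", "STAT3"),
    ("STAT1", "+", "IL12_out"),
    ("STAT5", "+", "IL12_out"),
    ("NF_kB", "+", "IL12_out"),
    ("NF_kB", "+", "IL1b"),
    ("PPARg", "+", "IL10_out"),
    ("PPARg", "-", "NF_kB"),
    ("PPARg", "-", "STAT3"),
    ("STAT6", "+", "KLF4"),
    ("STAT6", "+", "SOCS1"),
    ("STAT6", "+", "IL10_out"),
    ("JMJD3", "+", "IRF4"),
    ("STAT3", "+", "IL10_out"),
    ("STAT3", "-", "NF_kB"),
    ("STAT3", "-", "STAT1"),
    ("STAT3", "-", "STAT5"),
    ("IRF3", "+", "IFNb"),
    ("ERK", "+", "IL10_out"),
    ("KLF4", "-", "NF_kB"),
    ("SOCS1", "-", "STAT1"),
    ("IRF4", "-", "STAT5"),
    ("IFNb", "+", "IFNgR"),
]


def curated_edge_table() -> list[tuple[str, str, int]]:
    """Curated edges as ``(source, target, +1/-1)`` triples."""
    return [(s, t, 1 if sign == "+" else -1) for s, sign, t in CURATED_EDGES]


def _category(name: str) -> str:
    if name in INPUT_NODES:
        return "input"
    if name in RECEPTOR_NODES:
        return "receptor"
    if name in OUTPUT_NODES:
        return "output"
    return "regulator"


def macrophage_network() -> BooleanNetwork:
    """Build the 30-node macrophage polarization network.

    Node order is inputs first, then receptors/regulators/outputs in the
    order of the rule table; this order fixes the bit layout of every state
    vector, packed block and report produced by the package.
    """
    order = INPUT_NODES + list(RULES.keys())
    nodes = [NodeSpec(n, _category(n), DISPLAY_NAMES.get(n)) for n in order]
    rules = [
        BooleanRule(target, parse_expression(text)) for target, text in RULES.items()
    ]
    return BooleanNetwork(nodes, rules)
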