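"""File-format helpers shared by the command-line interface.

Formats are deliberately plain text: ``targets, factors`` rule files,
``source,sign,target`` edge CSVs, tidy CSV tables and JSON summaries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .model import macrophage_network
from .network import BooleanNetwork, parse_rules, write_rules

__all__ = [
    "load_network",
    "save_network",
    "read_edge_csv",
    "write_json",
    "file_checksum",
]


def load_network(model: str = "builtin") -> BooleanNetwork:
    """Load the built-in macrophage network or parse a rule file."""
    if model == "builtin":
        return macrophage_network()
    return parse_rules(Path(model).read_text())


def save_network(net: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(write_rules(net))


def read_edge_csv(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a ``source,sign,target`` CSV with sign in {+,-}."""
    frame = pd.read_csv(path, comment="#")
    expected = {"source", "sign", "target"}
    if set(map(str.lower, frame.columns)) != expected:
        raise ValueError(f"edge CSV needs columns {sorted(expected)}")
    frame.columns = [c.lower() for c in frame.columns]
    edges = []
    for row in frame.itertuples(index=False):
        sign = str(row.sign).strip()
        if sign not in {"+", "-"}:
            raise ValueError(f"sign must be '+' or '-', got {sign!r}")
        edges.append((str(row.source), str(row.target), 1 if sign == "+" else -1))
    return edges


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
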