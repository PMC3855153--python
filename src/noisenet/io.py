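"""Readers, writers and run configuration.

Expression matrices travel as delimited text (CSV/TSV, header row, one
sample per row); PDAGs as edge-list TSV, DOT or JSON; run configuration as
YAML or JSON with lossless round-trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .motif_models import ExpressionMatrix
from .structure_learning import PDAG

__all__ = [
    "RunConfig",
    "read_expression_csv",
    "write_expression_csv",
    "write_graph",
    "read_graph",
]


@dataclasses.dataclass
class RunConfig:
    """Bundled knobs of one experiment run; serialisable round-trip."""

    seed: int = 0
    alpha: float = 0.01
    algorithm: str = "gs"
    symmetry_rule: str = "AND"
    confidence_threshold: float = 0.8
    R: int = 200
    n: int = 2000
    m: int = 800
    coupling: float = 2.0
    large_variance: float = 1e4
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.algorithm not in ("gs", "iamb"):
            raise ValueError("algorithm must be 'gs' or 'iamb'")
        if self.symmetry_rule not in ("AND", "OR"):
            raise ValueError("symmetry_rule must be 'AND' or 'OR'")

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        else:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**payload)

    def digest(self) -> str:
        """Short provenance hash of the configuration."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_expression_csv(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a samples-x-variables table with a header row (CSV or TSV;
    delimiter sniffed from the extension/content unless given)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix in (".tsv", ".tab") else None  # None => sniff
    with open(path) as fh:
        header = fh.readline().strip()
    sep = delimiter or ("\t" if "\t" in header else ",")
    names = [h.strip() for h in header.split(sep)]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column names: {dups}")
    df = pd.read_csv(path, sep=delimiter, engine="python")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"missing value at row {row}, column {col!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        raise ValueError(f"non-numeric cells in column(s) {bad}") from exc
    return ExpressionMatrix(values, [str(c) for c in df.columns])


def write_expression_csv(data: ExpressionMatrix, path: str | Path, delimiter: str = ",") -> None:
    data.to_dataframe().to_csv(path, sep=delimiter, index=False)


def write_graph(pdag: PDAG, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a PDAG as 'edge_tsv' (from/to/type), 'dot' or 'json'."""
    path = Path(path)
    if format == "edge_tsv":
        lines = ["from\tto\ttype"]
        lines += [f"{a}\t{b}\t{kind}" for a, b, kind in pdag.edge_list()]
        path.write_text("\n".join(lines) + "\n")
    elif format == "dot":
        lines = ["digraph pdag {"]
        for a, b in sorted(pdag.directed_arcs):
            lines.append(f'  "{a}" -> "{b}";')
        for e in sorted(tuple(sorted(e)) for e in pdag.undirected_edges):
            lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
        for node in sorted(pdag.nodes):
            lines.append(f'  "{node}";')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        payload = {
            "nodes": sorted(pdag.nodes),
            "directed_arcs": sorted(list(a) for a in pdag.directed_arcs),
            "undirected_edges": sorted(sorted(e) for e in pdag.undirected_edges),
            "separation_sets": [
                {"pair": sorted(k), "set": sorted(v)} for k, v in sorted(
                    pdag.separation_sets.items(), key=lambda kv: sorted(kv[0])
                )
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(path: str | Path, format: str = "edge_tsv") -> PDAG:
    """Read a PDAG written by :func:`write_graph` (edge_tsv or json)."""
    path = Path(path)
    if format == "edge_tsv":
        lines = path.read_text().strip().splitlines()
        nodes: set[str] = set()
        directed: set[tuple[str, str]] = set()
        undirected: set[frozenset[str]] = set()
        for line in lines[1:]:
            a, b, kind = line.split("\t")
            nodes |= {a, b}
            if kind == "directed":
                directed.add((a, b))
            else:
                undirected.add(frozenset((a, b)))
        return PDAG(sorted(nodes), directed, undirected)
    if format == "json":
        payload = json.loads(path.read_text())
        return PDAG(
            list(payload["nodes"]),
            {tuple(a) for a in payload["directed_arcs"]},
            {frozenset(e) for e in payload["undirected_edges"]},
            {
                frozenset(item["pair"]): frozenset(item["set"])
                for item in payload.get("separation_sets", [])
            },
        )
    raise ValueError(f"unknown graph format {format!r} for reading")
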