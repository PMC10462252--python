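"""Table and graph serialization.

Tables are TSV with a header row and a ``sample_id`` first column.
Graphs round-trip through a TSV edge list (source, target, mark,
p_value) and export to GraphML and SIF for network viewers.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .graph import MixedGraph, _pair


class TableFormatError(ValueError):
    pass


def read_table(path: str | Path, required: Iterable[str] = (),
               numeric: Iterable[str] | None = None,
               index_col: str = "sample_id") -> pd.DataFrame:
    """Schema-validated TSV load.

    Checks the required columns exist, the named (or all, when
    ``numeric`` is None) columns parse as numbers, and the index has no
    duplicates; errors carry the offending line number."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise TableFormatError(f"{path}: missing column {index_col!r}")
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    dup = df[index_col].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # header is line 1
        raise TableFormatError(
            f"{path}:{line}: duplicated identifier "
            f"{df[index_col][dup].iloc[0]!r}")
    df = df.set_index(index_col)
    check = list(numeric) if numeric is not None else list(df.columns)
    for col in check:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TableFormatError(
                f"{path}:{line}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r}")
        df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                index_label: str = "sample_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=("time", "event"),
                    numeric=("time", "event"))
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise TableFormatError(
            f"{path}: nonpositive follow-up time for sample {bad!r}")
    if not df["event"].isin((0, 1)).all():
        raise TableFormatError(f"{path}: event indicator must be 0 or 1")
    return df


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def write_graph_tsv(g: MixedGraph, path: str | Path) -> None:
    """Edge list: source, target, mark, p_value (directed rows give
    source -> target; other marks list endpoints in sorted order)."""
    rows = []
    for u, v, mark in sorted(g.edges()):
        p = g.edge_pvalues.get(_pair(u, v), math.nan)
        rows.append((u, v, mark, p))
    df = pd.DataFrame(rows, columns=["source", "target", "mark", "p_value"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_graph_tsv(path: str | Path,
                   kinds: dict | None = None) -> MixedGraph:
    df = pd.read_csv(path, sep="\t")
    for col in ("source", "target", "mark"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing column {col!r}")
    g = MixedGraph()
    for _, row in df.iterrows():
        for n in (row["source"], row["target"]):
            g.add_node(n, (kinds or {}).get(n, "metabolite"))
        g.add_edge(row["source"], row["target"], row["mark"])
        if "p_value" in df.columns and not pd.isna(row["p_value"]):
            g.edge_pvalues[_pair(row["source"], row["target"])] = \
                float(row["p_value"])
    return g


def write_graphml(g: MixedGraph, path: str | Path) -> None:
    out = nx.DiGraph()
    for n in g.nodes:
        out.add_node(n, kind=g.kind(n))
    for u, v, mark in sorted(g.edges()):
        p = g.edge_pvalues.get(_pair(u, v))
        attrs = {"mark": mark}
        if p is not None:
            attrs["p_value"] = float(p)
        out.add_edge(u, v, **attrs)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(out, path)


def write_sif(g: MixedGraph, path: str | Path) -> None:
    lines = [f"{u}\t{mark}\t{v}" for u, v, mark in sorted(g.edges())]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
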