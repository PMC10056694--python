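"""Thresholded correlation networks and Cytoscape-compatible export.

Networks keep the top fraction of the strongest correlations (the
count follows the ceiling rule, with ties at the cutoff included so the
result is deterministic), can be merged across two sample groups with a
group tag per edge, and are written as SIF, GraphML or a plain edge
TSV.  SIF itself carries no attributes, so node- and edge-attribute
sidecar TSVs accompany it; all three formats round-trip losslessly
through the matching importer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrMatrix

__all__ = [
    "EdgeList",
    "build_network",
    "merge_group_networks",
    "node_degrees",
    "export_network",
    "import_network",
]

EDGE_COLUMNS = ["source", "target", "weight", "method", "group"]
NODE_COLUMNS = ["id", "layer", "superpathway"]


@dataclass
class EdgeList:
    """Weighted undirected edges plus a node attribute table."""

    edges: pd.DataFrame
    nodes: pd.DataFrame

    def __post_init__(self):
        self.edges = self.edges.reset_index(drop=True)[EDGE_COLUMNS]
        if self.nodes is None or not len(self.nodes):
            ids = sorted(set(self.edges.source) | set(self.edges.target))
            self.nodes = pd.DataFrame(
                {"id": ids, "layer": "", "superpathway": ""}
            )
        self.nodes = self.nodes.reset_index(drop=True)[NODE_COLUMNS]
        if len(self.edges):
            if (self.edges.source == self.edges.target).any():
                raise ValueError("self-edges are not allowed")
            key = self.edges.apply(
                lambda r: tuple(sorted((str(r.source), str(r.target)))), axis=1
            )
            if key.duplicated().any():
                raise ValueError("duplicate undirected edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(
    corr: CorrMatrix,
    top_fraction: float = 0.30,
    positive_only: bool = False,
    use_absolute: bool = False,
    group: str = "",
    node_layers: Optional[dict] = None,
    superpathways: Optional[dict] = None,
) -> EdgeList:
    """Keep the ceil(top_fraction x eligible pairs) strongest correlations.

    For a square (within-layer) matrix the eligible pairs are the upper
    triangle; for a bipartite block, every (row, column) pair.
    Non-finite entries are dropped, and with ``positive_only`` so are
    negative values before ranking.  "Strongest" means largest signed
    value, or largest magnitude with ``use_absolute`` (for signed
    estimators).  All values tied with the cutoff are kept.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    v = corr.values
    if corr.square:
        iu, ju = np.triu_indices(v.shape[0], k=1)
        rows = v.index[iu]
        cols = v.columns[ju]
        weights = v.to_numpy()[iu, ju]
    else:
        rows = v.index.repeat(v.shape[1])
        cols = np.tile(v.columns, v.shape[0])
        weights = v.to_numpy().ravel()
    df = pd.DataFrame({"source": rows, "target": cols, "weight": weights})
    df = df[np.isfinite(df.weight)]
    if positive_only:
        df = df[df.weight >= 0]
    if len(df) == 0:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    else:
        rank_key = df.weight.abs() if use_absolute else df.weight
        n_keep = math.ceil(top_fraction * len(df))
        cutoff = np.sort(rank_key.to_numpy())[::-1][n_keep - 1]
        edges = df[rank_key >= cutoff].copy()
        edges["method"] = corr.method
        edges["group"] = group
    nodes = _node_table(
        list(v.index) + [c for c in v.columns if c not in set(v.index)],
        node_layers,
        superpathways,
    )
    return EdgeList(edges, nodes)


def _node_table(ids, layers, superpathways):
    layers = layers or {}
    superpathways = superpathways or {}
    return pd.DataFrame(
        {
            "id": ids,
            "layer": [layers.get(i, "") for i in ids],
            "superpathway": [superpathways.get(i, "") for i in ids],
        }
    )


def _edge_key(df: pd.DataFrame) -> pd.Series:
    return df.apply(lambda r: tuple(sorted((r.source, r.target))), axis=1)


def merge_group_networks(
    netA: EdgeList, netB: EdgeList, labelA: str = "groupA", labelB: str = "groupB"
) -> EdgeList:
    """Union of two per-group networks; edges present in both are tagged
    'both' (the weight reported is the larger of the two)."""
    a = netA.edges.copy()
    b = netB.edges.copy()
    a["group"] = labelA
    b["group"] = labelB
    a["_key"] = _edge_key(a) if len(a) else pd.Series(dtype=object)
    b["_key"] = _edge_key(b) if len(b) else pd.Series(dtype=object)
    shared = set(a["_key"]) & set(b["_key"])
    rows = []
    for _, r in a.iterrows():
        r = r.copy()
        if r["_key"] in shared:
            r["group"] = "both"
            r["weight"] = max(
                r.weight, float(b.loc[b["_key"] == r["_key"], "weight"].iloc[0])
            )
        rows.append(r.drop("_key"))
    for _, r in b.iterrows():
        if r["_key"] not in shared:
            rows.append(r.drop("_key"))
    edges = (
        pd.DataFrame(rows, columns=EDGE_COLUMNS)
        if rows
        else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    nodes = (
        pd.concat([netA.nodes, netB.nodes])
        .drop_duplicates("id")
        .reset_index(drop=True)
    )
    return EdgeList(edges, nodes)


def node_degrees(net: EdgeList, groups=None) -> pd.DataFrame:
    """Per-node degree table with per-group breakdown ('both' edges
    count toward both groups).  ``groups`` names the per-group columns;
    by default the labels present on the edges are used, which misses a
    group whose every edge was shared -- pass the labels explicitly for
    merged networks."""
    if not net.n_edges:
        return pd.DataFrame(columns=["node", "degree"])
    if groups is None:
        groups = [g for g in net.edges.group.unique() if g and g != "both"]
    recs = {}
    for _, r in net.edges.iterrows():
        for node in (r.source, r.target):
            rec = recs.setdefault(node, {"degree": 0, **{g: 0 for g in groups}})
            rec["degree"] += 1
            for g in groups:
                if r.group in (g, "both"):
                    rec[g] += 1
    out = pd.DataFrame.from_dict(recs, orient="index").sort_index()
    out.index.name = "node"
    return out.reset_index()


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

FORMATS = ("sif", "graphml", "edge_tsv")


def export_network(net: EdgeList, fmt: str, path) -> None:
    path = Path(path)
    if fmt == "sif":
        try:
            lines = [
                f"{r.source}\tcc\t{r.target}" for r in net.edges.itertuples()
            ]
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
            net.nodes.to_csv(_sidecar(path, "nodes"), sep="\t", index=False)
            net.edges.to_csv(_sidecar(path, "edges"), sep="\t", index=False)
        except OSError as exc:
            raise OSError(f"failed writing SIF network to {path}: {exc}") from exc
    elif fmt == "graphml":
        g = nx.Graph()
        for r in net.nodes.itertuples():
            g.add_node(r.id, layer=r.layer, superpathway=r.superpathway)
        for r in net.edges.itertuples():
            g.add_edge(
                r.source, r.target, weight=float(r.weight),
                method=r.method, group=r.group,
            )
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        try:
            net.edges.to_csv(path, sep="\t", index=False)
            net.nodes.to_csv(_sidecar(path, "nodes"), sep="\t", index=False)
        except OSError as exc:
            raise OSError(f"failed writing edge TSV to {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")


def import_network(fmt: str, path) -> EdgeList:
    path = Path(path)
    if fmt == "sif":
        edges = pd.read_csv(_sidecar(path, "edges"), sep="\t").fillna("")
        nodes = pd.read_csv(_sidecar(path, "nodes"), sep="\t").fillna("")
        return EdgeList(edges, nodes)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        edges = pd.DataFrame(
            [
                {
                    "source": u,
                    "target": v,
                    "weight": d.get("weight", np.nan),
                    "method": d.get("method", ""),
                    "group": d.get("group", ""),
                }
                for u, v, d in g.edges(data=True)
            ],
            columns=EDGE_COLUMNS,
        )
        nodes = pd.DataFrame(
            [
                {
                    "id": n,
                    "layer": d.get("layer", ""),
                    "superpathway": d.get("superpathway", ""),
                }
                for n, d in g.nodes(data=True)
            ],
            columns=NODE_COLUMNS,
        )
        return EdgeList(edges, nodes)
    if fmt == "edge_tsv":
        edges = pd.read_csv(path, sep="\t").fillna("")
        nodes_path = _sidecar(path, "nodes")
        nodes = (
            pd.read_csv(nodes_path, sep="\t").fillna("")
            if nodes_path.exists()
            else None
        )
        return EdgeList(edges, nodes)
    raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_suffix(path.suffix + f".{kind}.tsv")
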