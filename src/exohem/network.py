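"""Admission of early-death-associated RNAs and construction of their
log2FC correlation network.

An RNA enters the network pool when either
(1) it is significantly linked to at least three of the eight hematological
    groups (ANC, PLT, Hb, ALC, Mo, NLR, PLR, LMR; a group is linked through
    its baseline / nadir / geometric-mean variables) AND significantly
    correlated with both the early-death and the early-progression
    indicator, or
(2) it is strongly correlated with early death (|R| > 0.5).

Edges connect admitted RNAs whose per-patient log2FC profiles correlate with
|R| above the chosen threshold (0.5 or 0.6); the signed R is kept as an edge
attribute. Isolated admitted RNAs are dropped, so the reported node count is
that of the connected graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .expression import Log2FCTable


def admit_rnas(
    assoc: AssociationMatrix,
    flags: pd.DataFrame,
    alpha: float = 0.05,
    min_links: int = 3,
    ed_r_threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply the two admission conditions; returns a DataFrame indexed by
    admitted RNA with boolean provenance columns ``via_cbc_ed`` and
    ``via_strong_ed``."""
    if flags.attrs.get("variant") not in (None, "network_admission"):
        raise ValueError("admission requires flags computed with variant='network_admission'")
    cond1 = (flags["n_hematologic"] >= min_links) & flags["ed_sig"] & flags["ep_sig"]
    cond2 = flags["r_ed"].abs() > ed_r_threshold
    admitted = cond1 | cond2
    out = pd.DataFrame(
        {
            "via_cbc_ed": cond1[admitted],
            "via_strong_ed": cond2[admitted],
            "r_ed": flags.loc[admitted, "r_ed"],
            "ed_sign": flags.loc[admitted, "ed_sign"],
            "biotype": assoc.biotype.reindex(flags.index[admitted]),
        }
    )
    return out.sort_index()


@dataclass
class RNANetwork:
    """Correlation graph over admitted RNAs at a given |R| threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_table(self) -> pd.DataFrame:
        if self.n_nodes == 0:
            return pd.DataFrame()
        return pd.DataFrame.from_dict(dict(self.graph.nodes(data=True)), orient="index").sort_index()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"rna_a": a, "rna_b": b, **d}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows)


def build_graph(
    lfc: Log2FCTable,
    admitted: pd.DataFrame,
    threshold: float,
    annotations: pd.DataFrame | None = None,
) -> RNANetwork:
    """Build the |R| > threshold correlation graph over the admitted RNAs.

    ``annotations`` (e.g. annotation-variant link flags) contributes extra
    node attributes where its columns are scalar.
    """
    ids = [r for r in admitted.index if r in lfc.lfc.columns]
    if len(ids) < 2:
        warnings.warn("fewer than 2 admitted RNAs; empty network", stacklevel=2)
        return RNANetwork(nx.Graph(), threshold)
    sub = lfc.lfc[ids]
    corr = sub.corr(method="pearson")
    g = nx.Graph()
    arr = corr.to_numpy()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            r = arr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                g.add_edge(a, ids[j], r=float(r), weight=float(abs(r)),
                           sign=int(np.sign(r)))
    # isolated admitted RNAs never entered g; annotate surviving nodes
    for node in g.nodes:
        g.nodes[node]["biotype"] = str(admitted.loc[node, "biotype"])
        g.nodes[node]["ed_sign"] = int(admitted.loc[node, "ed_sign"])
        g.nodes[node]["r_ed"] = float(admitted.loc[node, "r_ed"])
        g.nodes[node]["via_cbc_ed"] = bool(admitted.loc[node, "via_cbc_ed"])
        g.nodes[node]["via_strong_ed"] = bool(admitted.loc[node, "via_strong_ed"])
        if annotations is not None and node in annotations.index:
            for col, val in annotations.loc[node].items():
                if isinstance(val, (bool, np.bool_)):
                    g.nodes[node][str(col)] = bool(val)
                elif isinstance(val, (int, np.integer)):
                    g.nodes[node][str(col)] = int(val)
                elif isinstance(val, (float, np.floating)) and np.isfinite(val):
                    g.nodes[node][str(col)] = float(val)
    if g.number_of_nodes() == 0:
        warnings.warn("no edges above threshold; empty network", stacklevel=2)
    return RNANetwork(g, threshold)


def export_graph(net: RNANetwork, path, format: str = "graphml") -> None:
    """Write the network; GraphML round-trips attributes losslessly, the
    edge-list TSV carries rna_a, rna_b, r, sign."""
    if net.n_nodes == 0:
        raise ValueError("refusing to export an empty network")
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        net.edge_table().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path, threshold: float | None = None) -> RNANetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, str)
    return RNANetwork(g, threshold if threshold is not None else float("nan"))
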