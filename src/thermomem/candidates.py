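"""Candidate-gene triangulation and subnetwork export.

Candidates are the module genes that are simultaneously (i) differentially
expressed, (ii) in the top quantile of gene significance within the module,
and (iii) in the top quantile of intramodular weighted degree ("hub" genes).
Around a candidate, a subnetwork of its most-correlated neighbours is built
by binarizing strong positive correlations, annotated with the other
family's module labels (or "NI" for genes absent there), and exported as
GraphML or node/edge TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NI_LABEL = "NI"


@dataclass
class TriageConfig:
    gs_quantile: float = 0.90
    degree_quantile: float = 0.90
    top_corr_fraction: float = 0.01
    edge_quantile: float = 0.90

    def __post_init__(self):
        for q in (self.gs_quantile, self.degree_quantile, self.edge_quantile):
            if not (0.0 < q < 1.0):
                raise ValueError("quantiles must lie in (0, 1)")
        if not (0.0 < self.top_corr_fraction <= 1.0):
            raise ValueError("top_corr_fraction must lie in (0, 1]")


@dataclass
class SubNetwork:
    """Unweighted undirected gene subnetwork with node attributes."""

    nodes: pd.DataFrame  # index gene_id; columns: degree, other_family_module
    edges: list[tuple[str, str]] = field(default_factory=list)


def triangulate(
    deg_set: set[str],
    gs: pd.Series,
    degree: pd.Series,
    module_genes: Sequence[str],
    cfg: TriageConfig | None = None,
) -> list[str]:
    """Module genes that are DE, top-GS, and top-degree (quantiles within module).

    Ties at the quantile boundary are included (>= threshold).
    """
    cfg = cfg or TriageConfig()
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("empty module")
    gs_m = gs.loc[module_genes]
    deg_m = degree.loc[module_genes]
    gs_thr = np.quantile(gs_m.to_numpy(), cfg.gs_quantile)
    deg_thr = np.quantile(deg_m.to_numpy(), cfg.degree_quantile)
    keep = [
        g
        for g in module_genes
        if g in deg_set and gs_m[g] >= gs_thr and deg_m[g] >= deg_thr
    ]
    return sorted(keep)


def top_correlated(corr: pd.DataFrame, seed_gene: str, fraction: float = 0.01) -> list[str]:
    """The ceil(fraction * (n-1)) genes most correlated (signed) with the seed.

    Ties at the cutoff are broken lexicographically by gene id.
    """
    if seed_gene not in corr.index:
        raise KeyError(f"seed gene {seed_gene!r} not in correlation matrix")
    r = corr.loc[seed_gene].drop(index=seed_gene)
    k = math.ceil(fraction * len(r))
    order = sorted(r.index, key=lambda g: (-r[g], g))
    return order[:k]


def binarize_edges(corr: pd.DataFrame, edge_quantile: float = 0.90) -> list[tuple[str, str]]:
    """Edges = pairs with correlation >= the edge_quantile of off-diagonal
    upper-triangle values, positive correlations only."""
    if corr.shape[0] < 2:
        raise ValueError("binarize_edges needs >= 2 nodes")
    vals = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices_from(vals, k=1)
    tri = vals[iu, ju]
    thr = np.quantile(tri, edge_quantile)
    edges = [
        (corr.index[i], corr.index[j])
        for i, j in zip(iu, ju)
        if vals[i, j] >= thr and vals[i, j] > 0
    ]
    if not edges:
        logger.warning("no positive correlations above the edge threshold; empty edge set")
    return edges


def annotate_cross_family(
    nodes: Sequence[str],
    other_family_labels: pd.Series,
    other_family_universe: Sequence[str],
) -> pd.Series:
    """Other-family module label per node, or "NI" when the gene is absent
    from the other family's filtered matrix."""
    universe = set(other_family_universe)
    out = {}
    for g in nodes:
        if g not in universe:
            out[g] = NI_LABEL
        else:
            out[g] = str(other_family_labels.get(g, 0))
    return pd.Series(out, name="other_family_module")


def build_subnetwork(
    corr: pd.DataFrame,
    genes: Sequence[str],
    other_family_labels: pd.Series | None = None,
    other_family_universe: Sequence[str] | None = None,
    edge_quantile: float = 0.90,
) -> SubNetwork:
    """Binarized subnetwork over `genes` with degree and cross-family tags."""
    genes = list(genes)
    sub = corr.loc[genes, genes]
    edges = binarize_edges(sub, edge_quantile)
    deg = {g: 0 for g in genes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    nodes = pd.DataFrame({"degree": pd.Series(deg)})
    nodes.index.name = "gene_id"
    if other_family_labels is not None and other_family_universe is not None:
        nodes["other_family_module"] = annotate_cross_family(
            genes, other_family_labels, other_family_universe
        )
    return SubNetwork(nodes=nodes, edges=edges)


def export_graph(subnet: SubNetwork, path, fmt: str = "graphml") -> list[str]:
    """Write the subnetwork as GraphML or a node/edge TSV pair."""
    import pathlib

    path = pathlib.Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for gene, row in subnet.nodes.sort_index().iterrows():
            g.add_node(gene, **{k: _graphml_safe(v) for k, v in row.items()})
        g.add_edges_from(sorted(tuple(sorted(e)) for e in subnet.edges))
        nx.write_graphml(g, path)
        return [str(path)]
    if fmt == "edge_tsv":
        node_path = path.with_suffix(".nodes.tsv")
        edge_path = path.with_suffix(".edges.tsv")
        subnet.nodes.sort_index().to_csv(node_path, sep="\t", index_label="gene_id")
        pd.DataFrame(
            sorted(tuple(sorted(e)) for e in subnet.edges), columns=["source", "target"]
        ).to_csv(edge_path, sep="\t", index=False)
        return [str(node_path), str(edge_path)]
    raise ValueError(f"unsupported export format {fmt!r}")


def _graphml_safe(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def read_graph(path, fmt: str = "graphml") -> SubNetwork:
    """Round-trip reader for :func:`export_graph` output."""
    import pathlib

    path = pathlib.Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = pd.DataFrame.from_dict(dict(g.nodes(data=True)), orient="index").sort_index()
        nodes.index.name = "gene_id"
        edges = [tuple(sorted(e)) for e in g.edges()]
        return SubNetwork(nodes=nodes, edges=sorted(edges))
    if fmt == "edge_tsv":
        nodes = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t", index_col="gene_id")
        edf = pd.read_csv(path.with_suffix(".edges.tsv"), sep="\t")
        edges = [tuple(sorted((a, b))) for a, b in zip(edf["source"], edf["target"])]
        return SubNetwork(nodes=nodes, edges=sorted(edges))
    raise ValueError(f"unsupported format {fmt!r}")
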