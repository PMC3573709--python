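"""Protein-protein interaction subnetworks, hub rules and hub expression tests.

Given an undirected PPI edge list, the analysis extracts the subnetwork
spanned by two seed gene sets (e.g. transcription-factor subunits and their
candidate target genes) together with intermediates lying on short paths
between them, then classifies intermediates as hubs:

* *primary hub* — a non-seed node with at least ``primary_min`` (default 3)
  edges to the second seed set;
* *secondary hub* — a remaining non-seed node with at least 2 edges to the
  second seed set and at least 2 edges to primary hubs.

Hub genes can then be tested for coordinated expression against a reference
gene (e.g. a growth-factor receptor) with a two-sample t-test comparing their
per-gene correlation coefficients with those of all genes in the matrix.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cascade import pearson_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "build_graph",
    "build_subnetwork",
    "find_hubs",
    "HubReport",
    "group_correlation_test",
    "GroupCorrelationTest",
]


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph: self-loops dropped, duplicate edges collapsed."""
    g = nx.Graph()
    n_self = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        g.add_edge(u, v)
    if n_self:
        logger.info("dropped %d self-loops", n_self)
    return g


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV of gene symbols (extra columns ignored)."""
    edges = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: edge line needs two columns")
            edges.append((parts[0], parts[1]))
    return build_graph(edges)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "wt", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            w.writerow([u, v])


def _present(graph: nx.Graph, seeds: Iterable[str], label: str) -> set[str]:
    seeds = set(seeds)
    present = seeds & set(graph.nodes)
    absent = seeds - present
    if absent:
        logger.info("%d %s seeds absent from the graph", len(absent), label)
    return present


def build_subnetwork(
    graph: nx.Graph,
    seeds_a: Iterable[str],
    seeds_b: Iterable[str],
    max_path: int = 2,
) -> nx.Graph:
    """Induced subgraph on both seed sets plus connecting intermediates.

    An intermediate is a non-seed node lying on a simple path of length at
    most ``max_path`` between a member of one seed set and a member of the
    other.  ``max_path=1`` keeps only the seeds themselves (direct edges need
    no intermediate).
    """
    if max_path < 1:
        raise ValueError("max_path must be >= 1")
    sa = _present(graph, seeds_a, "set-A")
    sb = _present(graph, seeds_b, "set-B")
    if graph.number_of_nodes() == 0:
        logger.warning("empty input graph; returning empty subnetwork")
        return nx.Graph()
    keep = set(sa) | set(sb)
    if max_path == 2:
        # fast path: intermediates are exactly the common neighbors
        for x in graph.nodes:
            if x in keep:
                continue
            nbrs = set(graph.adj[x])
            if nbrs & sa and nbrs & sb:
                keep.add(x)
    elif max_path > 2:
        interior: set[str] = set()
        for a in sa:
            for path in nx.all_simple_paths(graph, a, sb, cutoff=max_path):
                interior.update(path[1:-1])
        keep |= interior - sa - sb
    return graph.subgraph(keep).copy()


@dataclass
class HubReport:
    """Hub classification over an extracted subnetwork."""

    subnetwork: nx.Graph = field(repr=False)
    primary_hubs: set[str]
    secondary_hubs: set[str]
    seed_degree: dict[str, int]
    hub_degree: dict[str, int]

    @property
    def all_hubs(self) -> set[str]:
        return self.primary_hubs | self.secondary_hubs

    def node_roles(
        self, seeds_a: Iterable[str] = (), seeds_b: Iterable[str] = ()
    ) -> pd.DataFrame:
        """Node-attribute table (role per node) for graph viewers."""
        sa, sb = set(seeds_a), set(seeds_b)
        rows = []
        for node in sorted(self.subnetwork.nodes):
            if node in sa:
                role = "seed_a"
            elif node in sb:
                role = "seed_b"
            elif node in self.primary_hubs:
                role = "hub"
            elif node in self.secondary_hubs:
                role = "secondary_hub"
            else:
                role = "intermediate"
            rows.append((node, role, self.seed_degree.get(node, 0),
                         self.hub_degree.get(node, 0)))
        return pd.DataFrame(rows, columns=["node", "role", "seed_degree",
                                           "hub_degree"])


def find_hubs(
    sub: nx.Graph,
    seeds_b: Iterable[str],
    *,
    seeds_a: Iterable[str] = (),
    primary_min: int = 3,
    secondary_min_seed: int = 2,
    secondary_min_hub: int = 2,
) -> HubReport:
    """Classify non-seed nodes of a subnetwork as primary/secondary hubs.

    ``seeds_b`` is the target seed set whose connectivity defines hubness;
    ``seeds_a`` (optional) is excluded from hub candidacy as well.
    """
    sb, sa = set(seeds_b), set(seeds_a)
    candidates = [n for n in sub.nodes if n not in sb and n not in sa]
    seed_degree = {n: sum(1 for x in sub.adj[n] if x in sb) for n in candidates}
    primary = {n for n in candidates if seed_degree[n] >= primary_min}
    hub_degree = {n: sum(1 for x in sub.adj[n] if x in primary) for n in candidates}
    secondary = {
        n for n in candidates
        if n not in primary
        and seed_degree[n] >= secondary_min_seed
        and hub_degree[n] >= secondary_min_hub
    }
    return HubReport(sub, primary, secondary, seed_degree, hub_degree)


@dataclass(frozen=True)
class GroupCorrelationTest:
    group_mean: float
    background_mean: float
    t: float
    p: float
    n_group: int
    n_background: int
    variance_mode: str


def group_correlation_test(
    expr: pd.DataFrame,
    group: Sequence[str],
    reference: str,
    variance_mode: str = "pooled",
) -> GroupCorrelationTest:
    """Two-sample t-test of group-vs-background correlation with a reference.

    Every gene's Pearson coefficient with ``reference`` is computed; the
    coefficients of ``group`` genes are compared with those of all other
    genes (the background: every matrix gene except the reference itself).
    """
    if variance_mode not in ("pooled", "welch"):
        raise ValueError("variance_mode must be 'pooled' or 'welch'")
    group = [g for g in dict.fromkeys(group) if g != reference]
    if not group:
        raise ValueError("group is empty")
    missing = [g for g in group if g not in expr.index]
    if missing:
        raise KeyError(f"group gene(s) missing from matrix: {missing[:10]}")
    if reference not in expr.index:
        raise KeyError(f"reference {reference!r} missing from matrix")
    background_genes = [g for g in expr.index if g != reference]
    r = pearson_matrix(expr, background_genes, [reference]).iloc[:, 0]
    group_r = r.loc[group].dropna().to_numpy()
    bg_r = r.dropna().to_numpy()
    if len(group_r) < 2 and variance_mode == "pooled":
        raise ValueError("pooled t-test needs a group of size >= 2")
    t, p = stats.ttest_ind(group_r, bg_r, equal_var=(variance_mode == "pooled"))
    return GroupCorrelationTest(
        float(np.mean(group_r)), float(np.mean(bg_r)), float(t), float(p),
        len(group_r), len(bg_r), variance_mode,
    )
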