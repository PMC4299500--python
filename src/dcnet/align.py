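"""Dual-network alignment: maximal gene sets connected in two networks.

The aligner is a simplified recursive Match-and-Split: take the connected
components of the first network (restricted to the shared gene universe);
output a component if it is also connected in the second network,
otherwise split it into its connected components there and recurse with
the networks' roles alternating, stopping below a minimum size. The
outputs are pairwise disjoint and each is connected in the induced
subgraphs of both networks; they are exactly the maximal dual-connected
gene sets of size >= min_size (the refinement fixpoint is order
independent, which the test suite certifies against brute force).

By default the DC network seeds the recursion (its pairs carry the
biology; the physical network splits them); an order-swapped mode is
available and can, for sets below the size floor, prune differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import DCNetwork
from .stats import GOC, LOC

__all__ = ["AlignedSubnetwork", "match_and_split", "align_networks",
           "label_direction_genes", "neighborhood"]


@dataclass
class AlignedSubnetwork:
    """A gene set connected in both the DC and the physical network."""

    genes: frozenset
    dc_edges: pd.DataFrame  # gene_i, gene_j, direction
    physical_edges: list  # (gene, gene) tuples
    loc_genes: set = field(default_factory=set)
    goc_genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.loc_genes and not self.goc_genes:
            self.loc_genes, self.goc_genes, _ = _direction_sets(self.dc_edges)

    def __len__(self) -> int:
        return len(self.genes)


def _graph(edges) -> nx.Graph:
    g = nx.Graph()
    if isinstance(edges, DCNetwork):
        return edges.graph()
    if isinstance(edges, nx.Graph):
        return edges.to_undirected()
    for e in edges:
        a, b = e[0], e[1]
        if a != b:
            g.add_edge(a, b)
    return g


def match_and_split(net_a, net_b, min_size: int = 10) -> list[frozenset]:
    """All maximal gene sets connected in both networks (size >= min_size).

    ``net_a`` seeds the recursion; both inputs may be edge lists,
    networkx graphs, or DCNetwork objects, treated as undirected. The two
    networks are first restricted to their common gene universe.
    """
    ga, gb = _graph(net_a), _graph(net_b)
    common = set(ga.nodes) & set(gb.nodes)
    if not common:
        warnings.warn("networks share no genes; empty alignment")
        return []
    ga, gb = ga.subgraph(common), gb.subgraph(common)
    out: list[frozenset] = []

    def recurse(genes: set, first: nx.Graph, second: nx.Graph) -> None:
        for comp in nx.connected_components(first.subgraph(genes)):
            if len(comp) < min_size:
                continue
            if nx.is_connected(second.subgraph(comp)):
                out.append(frozenset(comp))
            else:
                recurse(comp, second, first)

    recurse(common, ga, gb)
    return sorted(out, key=lambda s: (-len(s), min(s)))


def align_networks(
    dc: DCNetwork, physical_edges, min_size: int = 10, first: str = "dc"
) -> list[AlignedSubnetwork]:
    """Run Match-and-Split and package each output with its edges.

    ``first`` selects which network seeds the recursion ("dc" default,
    "physical" for the swapped order).
    """
    phys = _graph(physical_edges)
    nets = (dc, phys) if first == "dc" else (phys, dc)
    gene_sets = match_and_split(*nets, min_size=min_size)
    out = []
    for genes in gene_sets:
        mask = dc.pairs["gene_i"].isin(genes) & dc.pairs["gene_j"].isin(genes)
        dc_edges = dc.pairs.loc[mask, ["gene_i", "gene_j", "direction"]].reset_index(
            drop=True
        )
        phys_edges = sorted(
            tuple(sorted(e)) for e in phys.subgraph(genes).edges
        )
        out.append(AlignedSubnetwork(genes=genes, dc_edges=dc_edges,
                                     physical_edges=phys_edges))
    return out


def _direction_sets(dc_edges: pd.DataFrame):
    loc_genes, goc_genes = set(), set()
    for row in dc_edges.itertuples(index=False):
        target = loc_genes if row.direction == LOC else goc_genes
        target.add(row.gene_i)
        target.add(row.gene_j)
    return loc_genes, goc_genes, loc_genes & goc_genes


def label_direction_genes(sub: AlignedSubnetwork):
    """LOC genes, GOC genes, their overlap, and the cross-process count.

    A LOC gene touches at least one LOC edge, a GOC gene at least one GOC
    edge (a gene with both kinds of edges is in both sets). The
    cross-process count is the number of physical edges joining a
    LOC-only gene to a GOC-only gene — the wiring between the two
    dysregulated processes.
    """
    loc_genes, goc_genes, overlap = _direction_sets(sub.dc_edges)
    loc_only = loc_genes - goc_genes
    goc_only = goc_genes - loc_genes
    cross = sum(
        1
        for a, b in sub.physical_edges
        if (a in loc_only and b in goc_only) or (a in goc_only and b in loc_only)
    )
    return loc_genes, goc_genes, {"overlap": overlap, "cross_process_edges": cross}


def neighborhood(sub: AlignedSubnetwork, gene: str) -> AlignedSubnetwork:
    """Immediate neighbourhood of a gene within an aligned subnetwork.

    The induced sub-subnetwork on the gene plus all of its DC or physical
    neighbours inside ``sub``.
    """
    if gene not in sub.genes:
        raise KeyError(f"gene {gene!r} is not in the aligned subnetwork")
    keep = {gene}
    for row in sub.dc_edges.itertuples(index=False):
        if gene == row.gene_i:
            keep.add(row.gene_j)
        elif gene == row.gene_j:
            keep.add(row.gene_i)
    for a, b in sub.physical_edges:
        if gene == a:
            keep.add(b)
        elif gene == b:
            keep.add(a)
    mask = sub.dc_edges["gene_i"].isin(keep) & sub.dc_edges["gene_j"].isin(keep)
    return AlignedSubnetwork(
        genes=frozenset(keep),
        dc_edges=sub.dc_edges.loc[mask].reset_index(drop=True),
        physical_edges=[e for e in sub.physical_edges if e[0] in keep and e[1] in keep],
    )
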