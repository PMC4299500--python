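"""DC network modules: spectral clustering tree parsed by modularity.

A binary clustering tree over the network's genes is grown by recursive
spectral bisection using the leading eigenvector of the modularity matrix
(per connected component, with the generalized subgraph form for deeper
splits). The tree is then parsed into modules by choosing the
tree-consistent set of disjoint clusters, within configured size bounds,
that maximises the total Newman-Girvan modularity

    Q = sum_c ( e_c / m  -  (d_c / 2m)^2 )

where e_c is the number of intra-cluster edges, d_c the total degree of
cluster c, and m the edge count of the whole (unweighted) DC network.
Genes in no qualifying cluster stay unassigned and contribute nothing.
Modules are numbered M1, M2, ... by decreasing modularity contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genesets import adjust_p
from .network import DCNetwork
from .stats import GOC, LOC

__all__ = [
    "TreeNode",
    "ModulePartition",
    "ModuleGraph",
    "build_clustering_tree",
    "parse_modules",
    "partition_modularity",
    "module_graph",
    "annotate_direction",
    "shared_overrep",
    "module_enrichment",
]


@dataclass
class TreeNode:
    """Node of the binary clustering tree; leaves hold single genes."""

    genes: tuple
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            yield from self.left.leaves()
            yield from self.right.leaves()


@dataclass
class ModulePartition:
    """Gene-to-module assignment with per-module modularity scores."""

    assignment: dict  # gene -> module label (M1, M2, ...); absent = unassigned
    module_scores: dict  # label -> modularity contribution
    modules: dict  # label -> frozenset of genes

    def coverage(self, genes) -> float:
        genes = set(genes)
        return len(set(self.assignment) & genes) / len(genes) if genes else 0.0

    def sizes(self) -> dict:
        return {label: len(m) for label, m in self.modules.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["gene", "module"]
        )


@dataclass
class ModuleGraph:
    """Module-level aggregation of a DC network.

    ``edges`` rows: module_a, module_b (equal for self-loops), weight
    (number of aggregated DC pairs), shared_fraction, and an ``exported``
    flag that is False for edges under the display threshold (they are
    retained internally so weight conservation holds exactly).
    """

    nodes: pd.DataFrame  # module, size, direction, shared_overrep_p, significant
    edges: pd.DataFrame

    def total_weight(self) -> int:
        return int(self.edges["weight"].sum())


# ---------------------------------------------------------------------------
# spectral tree
# ---------------------------------------------------------------------------


def _leading_eigvec(bmat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(bmat)
    u = vecs[:, -1]
    nz = np.nonzero(u)[0]
    if nz.size and u[nz[0]] < 0:  # deterministic sign: first nonzero entry positive
        u = -u
    return u


def _bisect(genes: list, adj: np.ndarray, degrees: np.ndarray, two_m: float):
    """Split genes into two non-empty halves by the modularity eigenvector."""
    idx = np.arange(len(genes))
    b = adj - np.outer(degrees, degrees) / two_m
    b = b - np.diag(b.sum(axis=1))  # generalized modularity matrix for subgraphs
    u = _leading_eigvec(b)
    left = idx[u > 0]
    right = idx[u <= 0]
    if len(left) == 0 or len(right) == 0:
        # indivisible by sign: fall back to an ordered median split so the
        # tree still reaches single-gene leaves
        order = sorted(idx, key=lambda k: (u[k], genes[k]))
        half = len(order) // 2
        left, right = np.array(order[:half]), np.array(order[half:])
    return sorted(left.tolist()), sorted(right.tolist())


def build_clustering_tree(net: DCNetwork | nx.Graph) -> TreeNode:
    """Binary clustering tree over the network's genes.

    Works per connected component (the top splits separate components);
    inside a component, recursive spectral bisection by the leading
    eigenvector of the (generalized) modularity matrix. Deterministic: the
    eigenvector sign is fixed and all orderings are lexicographic.
    """
    g = net.graph() if isinstance(net, DCNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    subtrees = [_component_tree(g.subgraph(c)) for c in comps]
    return _join(subtrees)


def _join(subtrees: list[TreeNode]) -> TreeNode:
    tree = subtrees[0]
    for other in subtrees[1:]:
        tree = TreeNode(genes=tree.genes + other.genes, left=tree, right=other)
    return tree


def _component_tree(g: nx.Graph) -> TreeNode:
    genes = sorted(g.nodes)
    if len(genes) == 1:
        return TreeNode(genes=(genes[0],))
    adj = nx.to_numpy_array(g, nodelist=genes)
    degrees = adj.sum(axis=1)
    two_m = max(degrees.sum(), 1.0)

    def grow(indices: list[int]) -> TreeNode:
        if len(indices) == 1:
            return TreeNode(genes=(genes[indices[0]],))
        sub_genes = [genes[i] for i in indices]
        li, ri = _bisect(sub_genes, adj[np.ix_(indices, indices)],
                         degrees[indices], two_m)
        left = grow([indices[i] for i in li])
        right = grow([indices[i] for i in ri])
        return TreeNode(genes=left.genes + right.genes, left=left, right=right)

    return grow(list(range(len(genes))))


# ---------------------------------------------------------------------------
# modularity parsing
# ---------------------------------------------------------------------------


def _modularity_terms(net: DCNetwork | nx.Graph):
    g = net.graph() if isinstance(net, DCNetwork) else net
    m = g.number_of_edges()
    degrees = dict(g.degree())
    return g, float(m), degrees


def cluster_score(genes, g: nx.Graph, m: float, degrees: dict) -> float:
    """Modularity contribution e_c/m - (d_c/2m)^2 of one gene set."""
    sub = set(genes)
    e_c = sum(1 for a, b in g.edges(sub) if a in sub and b in sub)
    d_c = sum(degrees.get(x, 0) for x in sub)
    return e_c / m - (d_c / (2.0 * m)) ** 2


def partition_modularity(modules, net: DCNetwork | nx.Graph) -> float:
    """Total Newman-Girvan modularity of a list of disjoint gene sets."""
    g, m, degrees = _modularity_terms(net)
    return sum(cluster_score(mod, g, m, degrees) for mod in modules)


def parse_modules(
    tree: TreeNode,
    net: DCNetwork | nx.Graph,
    min_size: int = 10,
    max_size: int = 100,
) -> ModulePartition:
    """Parse the clustering tree into modules maximising total modularity.

    Dynamic programming over the tree: at each node, either accept the
    node's gene set as a module (when min_size <= size <= max_size and its
    modularity contribution beats the best combination of its children) or
    recurse. Oversized clusters are therefore re-split; fragments below
    ``min_size`` remain unassigned. The result is the exact optimum over
    tree-consistent cuts.
    """
    g, m, degrees = _modularity_terms(net)
    if m == 0:
        warnings.warn("network has no edges; empty partition")
        return ModulePartition({}, {}, {})

    def best(node: TreeNode):
        size = len(node.genes)
        accept = (
            cluster_score(node.genes, g, m, degrees)
            if min_size <= size <= max_size
            else None
        )
        if node.is_leaf:
            return (accept, [node.genes]) if accept is not None and accept > 0 else (0.0, [])
        sl, ml = best(node.left)
        sr, mr = best(node.right)
        child_score, child_mods = sl + sr, ml + mr
        if accept is not None and accept > child_score:
            return accept, [node.genes]
        return child_score, child_mods

    total, chosen = best(tree)
    if not chosen:
        warnings.warn("no cluster satisfies the size bounds; empty partition")
        return ModulePartition({}, {}, {})
    scored = [
        (cluster_score(mod, g, m, degrees), mod) for mod in chosen
    ]
    # number by decreasing score; ties by (size desc, smallest member gene)
    scored.sort(key=lambda t: (-t[0], -len(t[1]), min(t[1])))
    assignment, module_scores, modules = {}, {}, {}
    for rank, (score, mod) in enumerate(scored, start=1):
        label = f"M{rank}"
        module_scores[label] = score
        modules[label] = frozenset(mod)
        for gene in mod:
            assignment[gene] = label
    return ModulePartition(assignment, module_scores, modules)


# ---------------------------------------------------------------------------
# module-level network
# ---------------------------------------------------------------------------


def module_graph(
    part: ModulePartition,
    dc: DCNetwork,
    shared: DCNetwork | None = None,
    min_edge_pairs: int = 20,
) -> ModuleGraph:
    """Aggregate DC pairs by module membership into a module-level graph.

    Self-loop weight counts intra-module pairs; an inter-module edge's
    weight counts the pairs interfacing the two modules. Edges aggregating
    fewer than ``min_edge_pairs`` pairs are flagged ``exported=False`` but
    retained, so the total weight always equals the number of DC pairs
    with both genes assigned. ``shared_fraction`` is the fraction of each
    edge's pairs that also occur in the ``shared`` network.
    """
    shared_keys = shared.pair_keys() if shared is not None else set()
    if shared is not None and not shared_keys <= dc.pair_keys():
        raise ValueError("shared network must be a subset of the DC network")
    weights: dict[tuple, list] = {}
    for row in dc.pairs.itertuples(index=False):
        ma = part.assignment.get(row.gene_i)
        mb = part.assignment.get(row.gene_j)
        if ma is None or mb is None:
            continue
        key = tuple(sorted((ma, mb)))
        rec = weights.setdefault(key, [0, 0])
        rec[0] += 1
        rec[1] += (row.gene_i, row.gene_j) in shared_keys
    edges = pd.DataFrame(
        [
            {
                "module_a": k[0],
                "module_b": k[1],
                "weight": w,
                "shared_fraction": s / w if w else 0.0,
                "exported": w >= min_edge_pairs,
            }
            for k, (w, s) in sorted(weights.items())
        ],
        columns=["module_a", "module_b", "weight", "shared_fraction", "exported"],
    )
    directions = annotate_direction(part, dc)
    overrep = (
        shared_overrep(part, dc, shared) if shared is not None else {}
    )
    nodes = pd.DataFrame(
        [
            {
                "module": label,
                "size": len(part.modules[label]),
                "direction": directions.get(label),
                "shared_overrep_p": overrep.get(label, (float("nan"), float("nan")))[1],
                "significant_shared": overrep.get(label, (1.0, 1.0))[1] < 0.05,
            }
            for label in sorted(part.modules, key=lambda s: int(s[1:]))
        ],
        columns=["module", "size", "direction", "shared_overrep_p", "significant_shared"],
    )
    return ModuleGraph(nodes=nodes, edges=edges)


def annotate_direction(part: ModulePartition, dc: DCNetwork) -> dict:
    """Majority GOC/LOC direction among each module's intra-module pairs.

    An exact tie (or a module with no intra-module pairs) falls to LOC
    with a warning.
    """
    counts = {label: {GOC: 0, LOC: 0} for label in part.modules}
    for row in dc.pairs.itertuples(index=False):
        ma = part.assignment.get(row.gene_i)
        if ma is not None and ma == part.assignment.get(row.gene_j):
            counts[ma][row.direction] += 1
    labels = {}
    for label, c in counts.items():
        if c[GOC] == c[LOC]:
            warnings.warn(f"module {label}: GOC/LOC tie ({c[GOC]}-{c[LOC]}); labelled LOC")
            labels[label] = LOC
        else:
            labels[label] = GOC if c[GOC] > c[LOC] else LOC
    return labels


def shared_overrep(
    part: ModulePartition, dc: DCNetwork, shared: DCNetwork
) -> dict:
    """Per-module overrepresentation of shared intra-module DC pairs.

    Universe: all intra-module DC pairs across modules. One-sided
    hypergeometric upper tail per module, Benjamini-Hochberg adjusted
    across modules. Returns label -> (raw p, adjusted p).
    """
    shared_keys = shared.pair_keys()
    intra: dict[str, list] = {label: [0, 0] for label in part.modules}
    total = 0
    total_shared = 0
    for row in dc.pairs.itertuples(index=False):
        ma = part.assignment.get(row.gene_i)
        if ma is None or ma != part.assignment.get(row.gene_j):
            continue
        total += 1
        hit = (row.gene_i, row.gene_j) in shared_keys
        total_shared += hit
        intra[ma][0] += 1
        intra[ma][1] += hit
    labels = sorted(part.modules, key=lambda s: int(s[1:]))
    raw = []
    for label in labels:
        n_mod, k_mod = intra[label]
        raw.append(
            float(sps.hypergeom.sf(k_mod - 1, total, total_shared, n_mod))
            if total
            else 1.0
        )
    adjusted = adjust_p(raw, method="BH")
    return {label: (raw[k], adjusted[k]) for k, label in enumerate(labels)}


def module_enrichment(
    part: ModulePartition,
    gene_sets: dict,
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each module in each gene set.

    Bonferroni correction over the number of gene sets tested. Gene sets
    are trimmed to the universe of measured genes; empty (post-trim) sets
    are skipped with a warning. Per module, rows are ordered by adjusted
    p, so the first significant row is "the best one" to report.
    """
    universe = set(universe)
    trimmed = {}
    for name, genes in gene_sets.items():
        inside = set(genes) & universe
        if not inside:
            warnings.warn(f"gene set {name!r} empty after restricting to universe; skipped")
            continue
        trimmed[name] = inside
    n_sets = len(trimmed)
    rows = []
    for label in sorted(part.modules, key=lambda s: int(s[1:])):
        members = set(part.modules[label]) & universe
        for name, genes in trimmed.items():
            k = len(members & genes)
            p = float(
                sps.hypergeom.sf(k - 1, len(universe), len(genes), len(members))
            )
            rows.append(
                {
                    "module": label,
                    "gene_set": name,
                    "overlap": k,
                    "module_size": len(members),
                    "set_size": len(genes),
                    "universe": len(universe),
                    "p": p,
                    "p_bonferroni": min(1.0, p * n_sets),
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "module", "gene_set", "overlap", "module_size", "set_size",
            "universe", "p", "p_bonferroni",
        ],
    )
    return frame.sort_values(["module", "p_bonferroni", "gene_set"]).reset_index(drop=True)
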