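"""DC network container: DC pair records, degrees, hubs, shared networks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GOC, LOC, PairStats

__all__ = [
    "DCPair",
    "DCNetwork",
    "build_dc_network",
    "hub_rank",
    "shared_network",
    "overlap_significance",
]

_COLUMNS = ["gene_i", "gene_j", "direction", "q", "r_case", "r_ctrl", "p_case", "p_ctrl"]


@dataclass(frozen=True)
class DCPair:
    """One differentially co-expressed gene pair with its direction."""

    gene_i: str
    gene_j: str
    direction: str  # GOC | LOC
    q: float
    stats: PairStats | None = None

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_i, self.gene_j)))


@dataclass
class DCNetwork:
    """A set of DC pairs with degree/hub views.

    ``pairs`` is a DataFrame with columns gene_i, gene_j, direction, q and
    the per-group correlation statistics. Unordered pairs are unique and
    self-loops are rejected.
    """

    pairs: pd.DataFrame
    q0: float = float("nan")
    fdr_target: float = float("nan")
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("gene_i", "gene_j", "direction", "q"):
            if col not in self.pairs.columns:
                raise ValueError(f"pairs table lacks column {col!r}")
        gi = self.pairs["gene_i"].astype(str)
        gj = self.pairs["gene_j"].astype(str)
        if (gi == gj).any():
            raise ValueError("self-loops are not allowed in a DC network")
        # canonical unordered orientation: gene_i < gene_j
        swap = gi > gj
        if swap.any():
            self.pairs = self.pairs.copy()
            self.pairs.loc[swap, ["gene_i", "gene_j"]] = self.pairs.loc[
                swap, ["gene_j", "gene_i"]
            ].to_numpy()
            if {"r_case", "r_ctrl"} <= set(self.pairs.columns):
                pass  # correlation statistics are symmetric under the swap
        keys = list(zip(self.pairs["gene_i"], self.pairs["gene_j"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate unordered pairs in DC network")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        a, b = sorted(map(str, pair))
        hit = (self.pairs["gene_i"] == a) & (self.pairs["gene_j"] == b)
        return bool(hit.any())

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["gene_i"], self.pairs["gene_j"]))

    def directions(self) -> dict[tuple[str, str], str]:
        return dict(zip(self.pair_keys_list(), self.pairs["direction"]))

    def pair_keys_list(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["gene_i"], self.pairs["gene_j"]))

    @property
    def genes(self) -> set[str]:
        return set(self.pairs["gene_i"]) | set(self.pairs["gene_j"])

    def degrees(self) -> pd.Series:
        """Number of unordered DC partners per gene, descending."""
        counts = pd.concat([self.pairs["gene_i"], self.pairs["gene_j"]]).value_counts()
        return counts.sort_values(ascending=False)

    def subset(self, mask) -> "DCNetwork":
        return DCNetwork(self.pairs.loc[mask].reset_index(drop=True), self.q0, self.fdr_target,
                         dict(self.attrs))

    def restrict_genes(self, genes) -> "DCNetwork":
        genes = set(genes)
        mask = self.pairs["gene_i"].isin(genes) & self.pairs["gene_j"].isin(genes)
        return self.subset(mask)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.pairs.itertuples(index=False):
            g.add_edge(row.gene_i, row.gene_j, direction=row.direction, q=row.q)
        return g

    def counts(self) -> dict[str, int]:
        d = self.pairs["direction"].value_counts().to_dict()
        return {GOC: int(d.get(GOC, 0)), LOC: int(d.get(LOC, 0))}

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        cols = [c for c in _COLUMNS if c in self.pairs.columns]
        self.pairs[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, q0: float = float("nan"),
                 fdr_target: float = float("nan")) -> "DCNetwork":
        return cls(pd.read_csv(path, sep="\t"), q0=q0, fdr_target=fdr_target)


def build_dc_network(dc_pairs, q0: float = float("nan"),
                     fdr_target: float = float("nan")) -> DCNetwork:
    """Assemble DC pairs (DCPair objects or a records DataFrame) into a network."""
    if isinstance(dc_pairs, pd.DataFrame):
        return DCNetwork(dc_pairs, q0=q0, fdr_target=fdr_target)
    rows = []
    for p in dc_pairs:
        rec = {"gene_i": p.gene_i, "gene_j": p.gene_j, "direction": p.direction, "q": p.q}
        if p.stats is not None:
            rec.update(
                r_case=p.stats.r_case, r_ctrl=p.stats.r_ctrl,
                p_case=p.stats.p_case, p_ctrl=p.stats.p_ctrl,
            )
        rows.append(rec)
    frame = pd.DataFrame(rows, columns=_COLUMNS if rows and "r_case" in rows[0] else None)
    if not rows:
        frame = pd.DataFrame(columns=["gene_i", "gene_j", "direction", "q"])
    return DCNetwork(frame, q0=q0, fdr_target=fdr_target)


def hub_rank(net: DCNetwork, min_pairs: int = 1) -> list[tuple[str, int]]:
    """Genes ordered by DC degree (hubs first); degree < min_pairs excluded.

    Ties are broken by gene name for determinism.
    """
    deg = net.degrees()
    items = [(g, int(d)) for g, d in deg.items() if d >= min_pairs]
    items.sort(key=lambda t: (-t[1], t[0]))
    return items


def shared_network(net_a: DCNetwork, net_b: DCNetwork) -> DCNetwork:
    """Intersection of two DC networks built against the same control group.

    The shared pairs keep net_a's statistics. Because the control group is
    common, an overlapping pair must carry the same GOC/LOC direction in
    both networks; a conflict is raised as an internal-consistency error.
    The result's ``attrs`` records the GOC/LOC fractions of the overlap.
    """
    keys_b = net_b.directions()
    mask = []
    for row in net_a.pairs.itertuples(index=False):
        key = (row.gene_i, row.gene_j)
        if key in keys_b:
            if keys_b[key] != row.direction:
                raise ValueError(
                    f"direction conflict for shared pair {key}: "
                    f"{row.direction} vs {keys_b[key]} under a shared control group"
                )
            mask.append(True)
        else:
            mask.append(False)
    shared = net_a.subset(np.asarray(mask, dtype=bool) if mask else slice(0, 0))
    n = len(shared)
    counts = shared.counts()
    shared.attrs["goc_fraction"] = counts[GOC] / n if n else float("nan")
    shared.attrs["loc_fraction"] = counts[LOC] / n if n else float("nan")
    return shared


def overlap_significance(n_shared: int, n_a: int, n_b: int, n_universe: int) -> float:
    """Hypergeometric upper-tail p for the overlap of two pair sets.

    ``n_universe`` is the number of testable unordered pairs; drawing
    ``n_b`` pairs at random, the p-value is P(overlap with the fixed
    ``n_a`` set >= ``n_shared``).
    """
    if not (0 <= n_shared <= min(n_a, n_b) and max(n_a, n_b) <= n_universe):
        raise ValueError("inconsistent overlap counts")
    return float(sps.hypergeom.sf(n_shared - 1, n_universe, n_a, n_b))
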