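"""Gene-set statistics: hypergeometric overlap, p adjustment, orthologs,
gene-trait correlation, and GMT I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_overlap",
    "adjust_p",
    "read_gmt",
    "write_gmt",
    "load_ortholog_table",
    "map_orthologs",
    "trait_correlation",
    "trait_correlated_gene_set",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with provenance."""

    name: str
    genes: frozenset
    source: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def of(cls, name: str, genes, source: str = "") -> "GeneSet":
        return cls(name=name, genes=frozenset(map(str, genes)), source=source)


@dataclass(frozen=True)
class EnrichmentResult:
    set_a: str
    set_b: str
    overlap: int
    universe: int
    p: float
    adjusted_p: float = float("nan")
    method: str = ""


def hypergeom_overlap(a: GeneSet, b: GeneSet, universe: GeneSet) -> EnrichmentResult:
    """One-sided upper-tail hypergeometric p for the overlap of two sets.

    Sets are trimmed to the universe (with a warning when genes fall
    outside it). With |a| white balls among N, drawing |b|, the p-value is
    P(X >= |a & b|).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    ga, gb = a.genes & universe.genes, b.genes & universe.genes
    if len(ga) < len(a) or len(gb) < len(b):
        warnings.warn(
            f"trimmed {len(a) - len(ga)} genes of {a.name!r} and "
            f"{len(b) - len(gb)} of {b.name!r} outside the universe"
        )
    k = len(ga & gb)
    p = float(sps.hypergeom.sf(k - 1, len(universe), len(ga), len(gb)))
    return EnrichmentResult(a.name, b.name, k, len(universe), p)


def adjust_p(p_values, method: str = "BH") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "Bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# GMT and ortholog tables
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file (set name, description, then gene symbols, tab-sep)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, source, genes = fields[0], fields[1], fields[2:]
        sets[name] = GeneSet.of(name, [g for g in genes if g], source=source)
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.source or "na", *sorted(s.genes)]) for s in sets.values()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Two-column tab-separated mouse-to-human symbol mapping."""
    table = pd.read_csv(path, sep="\t", header=None, names=["mouse", "human"],
                        dtype=str, comment="#")
    return table.dropna()


def map_orthologs(mouse_set: GeneSet, table: pd.DataFrame) -> tuple[GeneSet, set]:
    """Map a mouse gene set to the union of its human orthologs.

    Many-to-many mappings are allowed (a mouse gene with several human
    orthologs contributes them all). Returns the mapped set and the set of
    unmapped mouse genes. Deterministic and independent of input order.
    """
    lookup: dict[str, set] = {}
    for row in table.itertuples(index=False):
        lookup.setdefault(str(row.mouse), set()).add(str(row.human))
    mapped: set = set()
    unmapped: set = set()
    for gene in mouse_set.genes:
        if gene in lookup:
            mapped |= lookup[gene]
        else:
            unmapped.add(gene)
    return GeneSet.of(f"{mouse_set.name}_human", mapped, source=mouse_set.source), unmapped


# ---------------------------------------------------------------------------
# gene-trait correlation
# ---------------------------------------------------------------------------


def trait_correlation(expr_vector, trait_vector) -> tuple[float, float]:
    """Rank correlation of expression with an ordinal/continuous trait.

    Missing values are dropped pairwise; a constant input is undefined and
    returns (nan, nan). Needs >= 4 complete paired observations.
    """
    x = np.asarray(expr_vector, dtype=float)
    y = np.asarray(trait_vector, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 complete paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def trait_correlated_gene_set(
    expr_matrix: pd.DataFrame, trait, alpha: float = 0.05, name: str = "trait_correlated"
) -> GeneSet:
    """Genes whose trait correlation p is below ``alpha`` (uncorrected)."""
    members = []
    for gene, row in expr_matrix.iterrows():
        try:
            _, p = trait_correlation(row.to_numpy(float), trait)
        except ValueError:
            continue
        if not np.isnan(p) and p < alpha:
            members.append(gene)
    return GeneSet.of(name, members, source="trait correlation")
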