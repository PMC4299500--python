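"""Seeded synthetic case/control expression data with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: two-group expression with planted group-specific correlation
structure (GOC/LOC pairs organised in compound-symmetry modules), additive
covariate effects and shared latent confounders mirrored on control probes,
missing entries, and companion physical/DC networks containing a planted
subnetwork connected in both.

Planted correlations are realised as compound-symmetry blocks embedded in
an otherwise diagonal Gaussian covariance: a gain-of-co-expression (GOC)
block is correlated in the case group and independent in controls, a
loss-of-co-expression (LOC) block the reverse. Every within-block pair is a
planted DC pair, so the fraction of planted pairs is interpreted against
all C(n_genes, 2) pairs. Because the pipeline's statistic is the Spearman
correlation, the planted Gaussian correlation is by default calibrated so
the *population Spearman* correlation equals the requested effect size
(rho_pearson = 2 sin(pi rho_s / 6)); pass ``scale="pearson"`` for the raw
Gaussian reading.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .network import DCNetwork
from .stats import GOC, LOC

__all__ = [
    "SyntheticTruth",
    "generate_paired_groups",
    "inject_covariates_and_controls",
    "mask_entries",
    "generate_dual_networks",
    "planted_partition_network",
    "planted_dual_networks",
]


@dataclass
class SyntheticTruth:
    """Ground truth record accompanying a synthetic dataset."""

    planted_goc_pairs: set = field(default_factory=set)
    planted_loc_pairs: set = field(default_factory=set)
    planted_modules: list = field(default_factory=list)
    planted_aligned_genes: set = field(default_factory=set)
    covariate_effects: pd.DataFrame | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.planted_goc_pairs & self.planted_loc_pairs:
            raise ValueError("planted GOC and LOC pair sets must be disjoint")
        for m in self.planted_modules:
            if len(m) < 3:
                raise ValueError("every planted module must have >= 3 genes")

    @property
    def planted_pairs(self) -> set:
        return self.planted_goc_pairs | self.planted_loc_pairs

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_goc_pairs": sorted(map(list, self.planted_goc_pairs)),
            "planted_loc_pairs": sorted(map(list, self.planted_loc_pairs)),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "planted_aligned_genes": sorted(self.planted_aligned_genes),
            "covariate_effects": None
            if self.covariate_effects is None
            else self.covariate_effects.to_dict(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_goc_pairs={tuple(p) for p in d["planted_goc_pairs"]},
            planted_loc_pairs={tuple(p) for p in d["planted_loc_pairs"]},
            planted_modules=[set(m) for m in d["planted_modules"]],
            planted_aligned_genes=set(d["planted_aligned_genes"]),
            covariate_effects=None
            if d["covariate_effects"] is None
            else pd.DataFrame(d["covariate_effects"]),
            seed=d["seed"],
        )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _word(seed) -> int:
    """Fold an arbitrary seed into a non-negative 32-bit word."""
    if seed is None:
        return int(np.random.SeedSequence().entropy % (2**32))
    return int(seed) % (2**32)


def _block_sizes(target_pairs: int, module_size: int) -> list[int]:
    """Greedy block sizes whose within-block pair counts sum to ~target."""
    sizes = []
    remaining = target_pairs
    while remaining >= 1:
        if module_size * (module_size - 1) // 2 <= remaining:
            k = module_size
        else:
            k = int((1 + math.sqrt(1 + 8 * remaining)) / 2)  # C(k,2) <= remaining
        if k < 2:
            break
        sizes.append(k)
        remaining -= k * (k - 1) // 2
    return sizes


def _cs_chol(k: int, rho: float) -> np.ndarray:
    """Cholesky factor of a k x k compound-symmetry correlation matrix."""
    if not (-1.0 / (k - 1) < rho < 1.0):
        raise ValueError(
            f"correlation {rho:.3f} gives a non-positive-definite {k}-gene block"
        )
    c = np.full((k, k), rho)
    np.fill_diagonal(c, 1.0)
    return np.linalg.cholesky(c)


def generate_paired_groups(
    n_genes: int,
    n_case: int = 100,
    n_ctrl: int = 100,
    frac_goc: float = 0.0,
    frac_loc: float = 0.0,
    effect_delta_r: float = 0.6,
    seed: int | None = None,
    *,
    module_size: int = 40,
    scale: str = "spearman",
    structure_seed: int | None = None,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Two-group expression with planted GOC/LOC correlation structure.

    ``frac_goc``/``frac_loc`` are fractions of all C(n_genes, 2) gene pairs
    to plant in each direction; planted pairs live inside compound-symmetry
    blocks of up to ``module_size`` genes (blocks of >= 3 genes are also
    recorded as planted modules). GOC pairs have population correlation
    ~``effect_delta_r`` in cases and 0 in controls; LOC pairs the reverse;
    all other pairs are uncorrelated in both groups. Values are on a
    log-intensity-like scale (per-gene baseline ~ N(8, 1), unit noise).

    ``structure_seed`` pins the planted structure (which genes form which
    blocks, the per-gene baselines) separately from the sampling noise, so
    an independent cohort with the *same* ground truth can be drawn by
    keeping ``structure_seed`` and changing ``seed``. By default the
    structure follows ``seed``.
    """
    if not 0.0 <= frac_goc + frac_loc <= 1.0:
        raise ValueError("frac_goc + frac_loc must lie in [0, 1]")
    if not abs(effect_delta_r) < 1.0:
        raise ValueError("|effect_delta_r| must be < 1")
    if n_case < 10 or n_ctrl < 10:
        raise ValueError("need at least 10 samples per group")
    if scale not in ("spearman", "pearson"):
        raise ValueError("scale must be 'spearman' or 'pearson'")

    rho = (
        2.0 * math.sin(math.pi * effect_delta_r / 6.0)
        if scale == "spearman"
        else effect_delta_r
    )
    s_seed = seed if structure_seed is None else structure_seed
    # distinct second words keep the structure and noise streams disjoint
    # even when the two seeds coincide
    rng_structure = np.random.default_rng(np.random.SeedSequence([_word(s_seed), 1]))
    rng = np.random.default_rng(np.random.SeedSequence([_word(seed), 2]))
    genes = [f"R{k:05d}" for k in range(n_genes)]
    total_pairs = n_genes * (n_genes - 1) // 2
    sizes_goc = _block_sizes(round(frac_goc * total_pairs), module_size)
    sizes_loc = _block_sizes(round(frac_loc * total_pairs), module_size)
    if sum(sizes_goc) + sum(sizes_loc) > n_genes:
        raise ValueError(
            "planted fractions require more genes than available; "
            "increase n_genes or module_size"
        )

    order = rng_structure.permutation(n_genes)
    cursor = 0
    blocks: list[tuple[str, list[int]]] = []  # (direction, gene indices)
    for direction, sizes in ((GOC, sizes_goc), (LOC, sizes_loc)):
        for k in sizes:
            idx = sorted(order[cursor : cursor + k].tolist())
            cursor += k
            blocks.append((direction, idx))

    goc_pairs, loc_pairs, modules = set(), set(), []
    for direction, idx in blocks:
        names = [genes[i] for i in idx]
        pairs = {
            _pair_key(a, b) for p, a in enumerate(names) for b in names[p + 1 :]
        }
        (goc_pairs if direction == GOC else loc_pairs).update(pairs)
        if len(names) >= 3:
            modules.append(set(names))

    baseline = rng_structure.normal(8.0, 1.0, size=n_genes)

    def draw_group(n_samp: int, active: str) -> np.ndarray:
        x = rng.standard_normal((n_genes, n_samp))
        for direction, idx in blocks:
            if direction == active and len(idx) >= 2:
                chol = _cs_chol(len(idx), rho)
                x[idx, :] = chol @ rng.standard_normal((len(idx), n_samp))
        return x + baseline[:, None]

    case = draw_group(n_case, GOC)
    ctrl = draw_group(n_ctrl, LOC)

    samples = [f"case_{k:04d}" for k in range(n_case)] + [
        f"ctrl_{k:04d}" for k in range(n_ctrl)
    ]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    group = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples, name="group")
    covariates = pd.DataFrame(
        {
            "age": np.round(rng.normal(75.0, 8.0, size=len(samples))),
            "sex": rng.choice(["F", "M"], size=len(samples)),
            "batch": rng.choice(["b1", "b2", "b3"], size=len(samples)),
            "rin": rng.normal(6.8, 0.8, size=len(samples)),
        },
        index=samples,
    )
    ds = ExpressionDataset(values, group, covariates)
    truth = SyntheticTruth(
        planted_goc_pairs=goc_pairs,
        planted_loc_pairs=loc_pairs,
        planted_modules=modules,
        covariate_effects=pd.DataFrame(0.0, index=genes, columns=["age", "sex", "rin"]),
        seed=seed,
    )
    return ds, truth


def inject_covariates_and_controls(
    ds: ExpressionDataset,
    n_control_probes: int,
    effect_scale: float,
    seed: int | None = None,
    n_latent: int = 1,
    truth: SyntheticTruth | None = None,
) -> ExpressionDataset:
    """Add additive covariate effects, shared latent factors, control probes.

    Per-gene covariate coefficients are drawn N(0, effect_scale^2) on the
    standardized numeric covariates (age, sex as +-0.5, rin). When control
    probes are requested, ``n_latent`` latent confounders are drawn per
    sample and loaded on both the genes and the control probes, emulating
    technical factors the control-probe PC adjustment is meant to remove.
    The coefficients are recorded in the truth record (when given) and the
    latent factors stashed in ``attrs["latent_factors"]``.
    """
    if ds.n_missing():
        raise ValueError("dataset must be complete (no missing entries)")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    n_genes, n_samp = out.values.shape

    design = _numeric_covariates(out.covariates)
    coef = rng.normal(0.0, 1.0, size=(n_genes, design.shape[1])) * effect_scale
    out.values.iloc[:, :] = out.values.to_numpy() + coef @ design.T.to_numpy()
    if truth is not None:
        truth.covariate_effects = pd.DataFrame(
            coef, index=out.reporters, columns=design.columns
        )

    if n_control_probes > 0:
        factors = rng.standard_normal((n_latent, n_samp))
        gene_load = rng.normal(0.0, 1.0, size=(n_genes, n_latent)) * effect_scale
        out.values.iloc[:, :] = out.values.to_numpy() + gene_load @ factors
        probe_load = rng.normal(0.0, 1.0, size=(n_control_probes, n_latent)) * effect_scale
        probes = probe_load @ factors + 0.5 * rng.standard_normal(
            (n_control_probes, n_samp)
        )
        names = [f"CP{k:04d}" for k in range(n_control_probes)]
        n_r60 = max(1, n_control_probes // 5)
        n_pro = max(1, n_control_probes // 5) if n_control_probes >= 2 else 0
        classes = (
            ["r60"] * n_r60
            + ["Pro25G"] * n_pro
            + ["other"] * (n_control_probes - n_r60 - n_pro)
        )
        out.control_probes = pd.DataFrame(probes, index=names, columns=out.samples)
        out.control_classes = pd.Series(classes, index=names, name="probe_class")
        out.attrs["latent_factors"] = factors
    return out


def _numeric_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Standardized numeric design used for effect injection (no intercept)."""
    cols = {}
    if "age" in cov:
        age = cov["age"].astype(float)
        cols["age"] = (age - age.mean()) / (age.std() or 1.0)
    if "sex" in cov:
        cols["sex"] = (cov["sex"] == "M").astype(float) - 0.5
    if "rin" in cov:
        rin = cov["rin"].astype(float)
        cols["rin"] = (rin - rin.mean()) / (rin.std() or 1.0)
    return pd.DataFrame(cols, index=cov.index)


def mask_entries(
    ds: ExpressionDataset, frac_missing: float, seed: int | None = None
) -> ExpressionDataset:
    """Flag exactly round(frac_missing * cells) entries missing (MCAR).

    The pre-mask matrix is retained in ``attrs["masked_values"]`` so
    imputation accuracy can be scored against ground truth.
    """
    if not 0.0 <= frac_missing < 0.5:
        raise ValueError("frac_missing must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    n_cells = out.values.size
    n_mask = round(frac_missing * n_cells)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    out.attrs["masked_values"] = ds.values.copy()
    arr = out.values.to_numpy().copy()
    arr.flat[flat] = np.nan
    out.values.iloc[:, :] = arr
    out.attrs["mask_indices"] = flat
    return out


# ---------------------------------------------------------------------------
# companion networks
# ---------------------------------------------------------------------------


def generate_dual_networks(
    dc_truth: SyntheticTruth,
    n_extra_physical_edges: int,
    planted_size: int,
    seed: int | None = None,
    genes: list[str] | None = None,
) -> tuple[list[tuple[str, str]], set[str]]:
    """A physical edge list whose planted set is connected in both networks.

    The planted gene set is carved (by breadth-first growth) out of a
    connected component of the truth's planted DC pair network, so it is
    connected there; the physical network gets a random spanning connected
    subgraph on exactly those genes plus ``n_extra_physical_edges`` random
    edges elsewhere. The planted set is recorded in
    ``dc_truth.planted_aligned_genes``.
    """
    if planted_size < 2:
        raise ValueError("planted_size must be >= 2")
    rng = np.random.default_rng(seed)
    dcg = nx.Graph()
    dcg.add_edges_from(dc_truth.planted_pairs)
    comps = sorted(nx.connected_components(dcg), key=len, reverse=True)
    comp = next((c for c in comps if len(c) >= planted_size), None)
    if comp is None:
        raise ValueError(
            f"no DC-network component has >= {planted_size} genes to plant in"
        )
    start = min(comp)
    planted: list[str] = []
    for node in nx.bfs_tree(dcg.subgraph(comp), start):
        planted.append(node)
        if len(planted) == planted_size:
            break
    planted_set = set(planted)

    phys = _spanning_edges(planted, rng)
    if genes is None:
        genes = sorted({g for p in dc_truth.planted_pairs for g in p})
    outside_pool = [g for g in genes]
    existing = {frozenset(e) for e in phys}
    attempts = 0
    while len(phys) < len(planted) - 1 + n_extra_physical_edges and attempts < 10_000:
        a, b = rng.choice(outside_pool, size=2, replace=False)
        attempts += 1
        if a == b or (a in planted_set and b in planted_set):
            continue
        key = frozenset((a, b))
        if key in existing:
            continue
        existing.add(key)
        phys.append(_pair_key(a, b))
    dc_truth.planted_aligned_genes = planted_set
    return phys, planted_set


def _spanning_edges(nodes: list[str], rng) -> list[tuple[str, str]]:
    """Random spanning tree edges over ``nodes`` (random attachment order)."""
    order = list(nodes)
    rng.shuffle(order)
    return [
        _pair_key(order[k], order[int(rng.integers(0, k))]) for k in range(1, len(order))
    ]


def planted_partition_network(
    module_sizes: list[int],
    p_in: float = 0.3,
    p_out: float = 0.005,
    seed: int | None = None,
    goc_fraction: float = 0.5,
) -> tuple[DCNetwork, list[set[str]]]:
    """A DC network with planted modules (dense inside, sparse between).

    Each planted module is guaranteed connected (spanning tree plus
    Bernoulli(p_in) extra edges); inter-module edges are Bernoulli(p_out).
    Modules alternate GOC/LOC direction per ``goc_fraction``; edge Q values
    are drawn above the nominal chi^2 cutoff so the object is a plausible
    network of called DC pairs.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{k:05d}" for k in range(sum(module_sizes))]
    modules, cursor = [], 0
    for size in module_sizes:
        modules.append(genes[cursor : cursor + size])
        cursor += size
    edges: dict[tuple[str, str], str] = {}
    for m_idx, members in enumerate(modules):
        direction = GOC if rng.random() < goc_fraction else LOC
        for e in _spanning_edges(list(members), rng):
            edges[e] = direction
        arr = list(members)
        for a_i in range(len(arr)):
            for b_i in range(a_i + 1, len(arr)):
                if rng.random() < p_in:
                    edges[_pair_key(arr[a_i], arr[b_i])] = direction
    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            for a in modules[i]:
                for b in modules[j]:
                    if rng.random() < p_out:
                        edges[_pair_key(a, b)] = GOC if rng.random() < 0.5 else LOC
    frame = pd.DataFrame(
        {
            "gene_i": [e[0] for e in edges],
            "gene_j": [e[1] for e in edges],
            "direction": list(edges.values()),
            "q": 3.85 + rng.exponential(8.0, size=len(edges)),
        }
    )
    return DCNetwork(frame), [set(m) for m in modules]


def planted_dual_networks(
    planted_sizes: list[int],
    n_extra_physical_edges: int = 20,
    n_inter_dc_edges: int = 2,
    n_background_genes: int = 30,
    seed: int | None = None,
) -> tuple[DCNetwork, list[tuple[str, str]], list[set[str]]]:
    """Shared-DC and physical networks with several planted dual-connected sets.

    Each planted set is connected in both networks; ``n_inter_dc_edges``
    extra DC edges join consecutive planted sets (connected in DC only, so
    the aligner must split them apart), and background genes carry physical
    edges only.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{k:05d}" for k in range(sum(planted_sizes) + n_background_genes)]
    planted, cursor = [], 0
    for size in planted_sizes:
        planted.append(genes[cursor : cursor + size])
        cursor += size
    background = genes[cursor:]

    dc_edges: dict[tuple[str, str], str] = {}
    phys: set[tuple[str, str]] = set()
    for members in planted:
        direction = GOC if rng.random() < 0.5 else LOC
        for e in _spanning_edges(list(members), rng):
            dc_edges[e] = direction
        for e in _spanning_edges(list(members), rng):
            phys.add(e)
        extra = max(1, len(members) // 3)
        for _ in range(extra):
            a, b = rng.choice(members, size=2, replace=False)
            if a != b:
                dc_edges[_pair_key(a, b)] = direction
                phys.add(_pair_key(*rng.choice(members, size=2, replace=False)))
    for k in range(len(planted) - 1):
        for _ in range(n_inter_dc_edges):
            a = str(rng.choice(planted[k]))
            b = str(rng.choice(planted[k + 1]))
            dc_edges[_pair_key(a, b)] = GOC
    for _ in range(n_extra_physical_edges):
        if len(background) >= 2:
            a, b = rng.choice(background, size=2, replace=False)
            if a != b:
                phys.add(_pair_key(a, b))
    phys = {e for e in phys if e[0] != e[1]}
    frame = pd.DataFrame(
        {
            "gene_i": [e[0] for e in dc_edges],
            "gene_j": [e[1] for e in dc_edges],
            "direction": list(dc_edges.values()),
            "q": 3.85 + rng.exponential(8.0, size=len(dc_edges)),
        }
    )
    return DCNetwork(frame), sorted(phys), [set(m) for m in planted]
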