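"""End-to-end pipeline: simulate -> adjust -> dc -> replicate -> modules ->
align -> enrich, with a flat config, seeds, and tab-separated artifacts.

Each stage is a pure function of its inputs and the config; a skipped
stage's outputs are read from a previous run, and a missing upstream
artifact raises an error naming the stage that should have produced it.
Every stage writes a small ``<stage>.meta.json`` carrying the hash of the
fully resolved config, so artifacts can be traced to the run that made
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import align as al
from . import genesets as gs
from . import modules as md
from . import preprocess as pp
from . import replication as rep
from . import simulate as sim
from .datasets import ExpressionDataset
from .model import DifferentialCoexpression
from .network import DCNetwork, shared_network

log = logging.getLogger(__name__)

STAGES = ("simulate", "adjust", "dc", "replicate", "modules", "align", "enrich")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with the analysis-wide default thresholds."""

    # thresholds
    target_fdr: float = 0.01
    alpha_coexpr: float = 0.01
    q_rep: float = 3.84
    q_age: float = 2.71
    min_module: int = 10
    max_module: int = 100
    min_edge_pairs: int = 20
    min_align: int = 10
    k_impute: int = 10
    n_shuffles: int = 1000
    n_perm_fdr: int = 1
    psi_function: str = "huber"
    # synthetic-data study design
    n_genes: int = 300
    n_case: int = 100
    n_ctrl: int = 100
    n_indep_case: int = 40
    n_indep_ctrl: int = 40
    frac_goc: float = 0.025
    frac_loc: float = 0.025
    effect_delta_r: float = 0.6
    module_size: int = 40
    n_control_probes: int = 60
    effect_scale: float = 0.5
    frac_missing: float = 0.01
    n_perm_pcs: int = 2000
    # selection threshold for remaining-class control-probe PCs; the stage
    # floors it at 1.5/n_perm_pcs so it stays attainable at reduced n_perm
    p_thresh_pcs: float = 1e-4
    planted_align_size: int = 12
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_adjust: bool = True
    run_dc: bool = True
    run_replicate: bool = True
    run_modules: bool = True
    run_align: bool = True
    run_enrich: bool = True

    def __post_init__(self) -> None:
        checks = [
            0 < self.target_fdr < 1,
            0 < self.alpha_coexpr < 1,
            self.q_rep >= 0,
            self.q_age >= 0,
            2 <= self.min_module <= self.max_module,
            self.min_edge_pairs >= 0,
            self.min_align >= 2,
            self.k_impute >= 1,
            self.n_shuffles >= 1,
            0 <= self.frac_goc + self.frac_loc <= 1,
        ]
        if not all(checks):
            raise ValueError("pipeline configuration out of valid range")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name!r}: enable or rerun stage '{stage}'"
        )
    return path


def _write_meta(outdir: Path, stage: str, cfg: PipelineConfig, artifacts: list[str]) -> None:
    meta = {"stage": stage, "config_hash": cfg.hash(), "artifacts": sorted(artifacts)}
    (outdir / f"{stage}.meta.json").write_text(json.dumps(meta, indent=1))


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return a result map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("resolved config (hash %s): %s", config.hash(), config.resolved())
    results: dict = {}
    if config.run_simulate:
        results["simulate"] = stage_simulate(config, outdir)
    if config.run_adjust:
        results["adjust"] = stage_adjust(config, outdir)
    if config.run_dc:
        results["dc"] = stage_dc(config, outdir)
    if config.run_replicate:
        results["replicate"] = stage_replicate(config, outdir)
    if config.run_modules:
        results["modules"] = stage_modules(config, outdir)
    if config.run_align:
        results["align"] = stage_align(config, outdir)
    if config.run_enrich:
        results["enrich"] = stage_enrich(config, outdir)
    return results


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the discovery, second-disease, independent and aging cohorts."""
    base = cfg.seed
    common = dict(
        n_genes=cfg.n_genes,
        frac_goc=cfg.frac_goc,
        frac_loc=cfg.frac_loc,
        effect_delta_r=cfg.effect_delta_r,
        module_size=cfg.module_size,
        structure_seed=base,
    )
    ds_clean, truth = sim.generate_paired_groups(
        n_case=cfg.n_case, n_ctrl=cfg.n_ctrl, seed=base + 1, **common
    )
    ds_a = sim.inject_covariates_and_controls(
        ds_clean, cfg.n_control_probes, cfg.effect_scale, seed=base + 2, truth=truth
    )
    ds_a = sim.mask_entries(ds_a, cfg.frac_missing, seed=base + 3)
    # second disease: fresh case draws (same planted structure, no injected
    # nuisance) against the same control samples as the discovery comparison
    ds_b_src, _ = sim.generate_paired_groups(
        n_case=cfg.n_case, n_ctrl=cfg.n_ctrl, seed=base + 4, **common
    )
    ds_b = ExpressionDataset(
        values=pd.concat(
            [ds_b_src.group_matrix("case"), ds_clean.group_matrix("control")], axis=1
        ),
        groups=ds_clean.groups.copy(),
        covariates=ds_clean.covariates.copy(),
    )
    ds_indep, _ = sim.generate_paired_groups(
        n_case=cfg.n_indep_case, n_ctrl=cfg.n_indep_ctrl, seed=base + 5, **common
    )
    ds_aging, _ = sim.generate_paired_groups(
        n_genes=cfg.n_genes,
        n_case=56,
        n_ctrl=53,
        frac_goc=0.0,
        frac_loc=0.0,
        seed=base + 6,
    )
    phys, planted = sim.generate_dual_networks(
        truth,
        n_extra_physical_edges=30,
        planted_size=cfg.planted_align_size,
        seed=base + 7,
        genes=ds_a.reporters,
    )
    ds_a.to_dir(outdir / "dataset_discovery")
    ds_b.to_dir(outdir / "dataset_disease_b")
    ds_indep.to_dir(outdir / "dataset_independent")
    ds_aging.to_dir(outdir / "dataset_aging")
    truth.to_json(outdir / "truth.json")
    pd.DataFrame(phys, columns=["gene_i", "gene_j"]).to_csv(
        outdir / "physical_network.tsv", sep="\t", index=False
    )
    _write_meta(outdir, "simulate", cfg, [
        "dataset_discovery", "dataset_disease_b", "dataset_independent",
        "dataset_aging", "truth.json", "physical_network.tsv",
    ])
    return {"planted_aligned": sorted(planted), "n_planted_pairs": len(truth.planted_pairs)}


def stage_adjust(cfg: PipelineConfig, outdir: Path) -> dict:
    ds = ExpressionDataset.from_dir(_require(outdir / "dataset_discovery", "simulate"))
    if ds.n_missing():
        ds.values = pp.impute_knn(ds.values, k=cfg.k_impute)
    pcs = []
    if ds.control_probes is not None:
        pcs = pp.select_control_pcs(
            ds.control_probes, ds.control_classes,
            n_perm=cfg.n_perm_pcs, p_thresh=max(cfg.p_thresh_pcs, 1.5 / cfg.n_perm_pcs),
            seed=cfg.seed + 10,
        )
    model = pp.adjust_expression(ds, pcs, ["age", "sex", "rin"], psi=cfg.psi_function)
    model.residuals.rename_axis("reporter").to_csv(
        outdir / "adjusted_discovery.tsv", sep="\t"
    )
    _write_meta(outdir, "adjust", cfg, ["adjusted_discovery.tsv"])
    return {"n_pcs_selected": len(pcs)}


def _load_groups(outdir: Path, dirname: str, stage: str):
    ds = ExpressionDataset.from_dir(_require(outdir / dirname, stage))
    labels = ds.group_names
    a = "case" if "case" in labels else labels[0]
    b = "control" if "control" in labels else labels[-1]
    return ds.group_matrix(a), ds.group_matrix(b)


def stage_dc(cfg: PipelineConfig, outdir: Path) -> dict:
    adjusted = _require(outdir / "adjusted_discovery.tsv", "adjust")
    values = pd.read_csv(adjusted, sep="\t", index_col=0)
    ds = ExpressionDataset.from_dir(_require(outdir / "dataset_discovery", "simulate"))
    case = values.loc[:, ds.groups == "case"]
    ctrl = values.loc[:, ds.groups == "control"]
    res_a = DifferentialCoexpression(
        case, ctrl, alpha_coexpr=cfg.alpha_coexpr
    ).fit(target_fdr=cfg.target_fdr, n_perm=cfg.n_perm_fdr, seed=cfg.seed + 20)
    # disease B reuses the *identical* adjusted control matrix so shared
    # DC pairs are guaranteed direction consistent; the case matrix is
    # centred per gene so the label permutation pools matrices on a common
    # location (rank correlations are unaffected, the null is restored)
    case_b, _ = _load_groups(outdir, "dataset_disease_b", "simulate")
    case_b = case_b.sub(case_b.mean(axis=1), axis=0)
    res_b = DifferentialCoexpression(
        case_b, ctrl, alpha_coexpr=cfg.alpha_coexpr
    ).fit(target_fdr=cfg.target_fdr, n_perm=cfg.n_perm_fdr, seed=cfg.seed + 21)
    shared = shared_network(res_a.network, res_b.network)
    res_a.network.to_tsv(outdir / "dc_network_a.tsv")
    res_b.network.to_tsv(outdir / "dc_network_b.tsv")
    shared.to_tsv(outdir / "dc_network_shared.tsv")
    (outdir / "dc_summary.txt").write_text(
        res_a.summary() + "\n\n" + res_b.summary() + "\n"
    )
    _write_meta(outdir, "dc", cfg, [
        "dc_network_a.tsv", "dc_network_b.tsv", "dc_network_shared.tsv", "dc_summary.txt",
    ])
    log.info(
        "DC pairs: A=%d B=%d shared=%d (Q0=%.2f/%.2f)",
        len(res_a.network), len(res_b.network), len(shared), res_a.q0, res_b.q0,
    )
    return {
        "q0_a": res_a.q0,
        "q0_b": res_b.q0,
        "n_dc_a": len(res_a.network),
        "n_dc_b": len(res_b.network),
        "n_shared": len(shared),
        "estimated_fdr_a": res_a.estimated_fdr_at_q0,
    }


def stage_replicate(cfg: PipelineConfig, outdir: Path) -> dict:
    net = DCNetwork.from_tsv(_require(outdir / "dc_network_a.tsv", "dc"))
    indep_case, indep_ctrl = _load_groups(outdir, "dataset_independent", "simulate")
    result = rep.connectivity_preserving_null(
        net, indep_case, indep_ctrl,
        n_shuffles=cfg.n_shuffles, q_rep=cfg.q_rep, seed=cfg.seed + 30,
    )
    elder, adult = _load_groups(outdir, "dataset_aging", "simulate")
    filtered, removed = rep.exclude_age_associated(net, elder, adult, q_age=cfg.q_age)
    filtered.to_tsv(outdir / "dc_network_a_no_age.tsv")
    report = pd.DataFrame(
        [
            {
                "n_eligible": result.n_eligible,
                "n_replicated": result.n_replicated,
                "fraction": result.fraction,
                "empirical_p": result.empirical_p,
                "goc_fraction": result.by_direction["GOC"]["fraction"],
                "loc_fraction": result.by_direction["LOC"]["fraction"],
                "age_removed_fraction": removed,
            }
        ]
    )
    report.to_csv(outdir / "replication_report.tsv", sep="\t", index=False)
    _write_meta(outdir, "replicate", cfg, [
        "replication_report.tsv", "dc_network_a_no_age.tsv",
    ])
    return report.iloc[0].to_dict()


def stage_modules(cfg: PipelineConfig, outdir: Path) -> dict:
    net = DCNetwork.from_tsv(_require(outdir / "dc_network_a.tsv", "dc"))
    shared = DCNetwork.from_tsv(_require(outdir / "dc_network_shared.tsv", "dc"))
    if len(net) == 0:
        raise RuntimeError("DC network is empty; nothing to cluster")
    tree = md.build_clustering_tree(net)
    part = md.parse_modules(tree, net, min_size=cfg.min_module, max_size=cfg.max_module)
    graph = md.module_graph(part, net, shared, min_edge_pairs=cfg.min_edge_pairs)
    part.to_frame().to_csv(outdir / "module_partition.tsv", sep="\t", index=False)
    graph.edges.to_csv(outdir / "module_graph_edges.tsv", sep="\t", index=False)
    graph.nodes.to_csv(outdir / "module_graph_nodes.tsv", sep="\t", index=False)
    _write_meta(outdir, "modules", cfg, [
        "module_partition.tsv", "module_graph_edges.tsv", "module_graph_nodes.tsv",
    ])
    return {
        "n_modules": len(part.modules),
        "coverage": part.coverage(net.genes),
        "sizes": part.sizes(),
    }


def stage_align(cfg: PipelineConfig, outdir: Path) -> dict:
    shared = DCNetwork.from_tsv(_require(outdir / "dc_network_shared.tsv", "dc"))
    phys = pd.read_csv(
        _require(outdir / "physical_network.tsv", "simulate"), sep="\t"
    )
    subs = al.align_networks(
        shared, list(zip(phys["gene_i"], phys["gene_j"])), min_size=cfg.min_align
    )
    rows = []
    for k, sub in enumerate(subs):
        sub.dc_edges.assign(subnetwork=k).to_csv(
            outdir / f"aligned_{k}_dc_edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(sub.physical_edges, columns=["gene_i", "gene_j"]).to_csv(
            outdir / f"aligned_{k}_physical_edges.tsv", sep="\t", index=False
        )
        loc_genes, goc_genes, extra = al.label_direction_genes(sub)
        rows.append(
            {
                "subnetwork": k,
                "n_genes": len(sub),
                "n_dc_edges": len(sub.dc_edges),
                "n_physical_edges": len(sub.physical_edges),
                "n_loc_genes": len(loc_genes),
                "n_goc_genes": len(goc_genes),
                "n_overlap": len(extra["overlap"]),
                "cross_process_edges": extra["cross_process_edges"],
            }
        )
    frame = pd.DataFrame(rows, columns=[
        "subnetwork", "n_genes", "n_dc_edges", "n_physical_edges",
        "n_loc_genes", "n_goc_genes", "n_overlap", "cross_process_edges",
    ])
    frame.to_csv(outdir / "aligned_subnetworks.tsv", sep="\t", index=False)
    _write_meta(outdir, "align", cfg, ["aligned_subnetworks.tsv"])
    return {"n_subnetworks": len(subs), "sizes": [len(s) for s in subs]}


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    part_frame = pd.read_csv(
        _require(outdir / "module_partition.tsv", "modules"), sep="\t"
    )
    truth = sim.SyntheticTruth.from_json(_require(outdir / "truth.json", "simulate"))
    assignment = dict(zip(part_frame["gene"], part_frame["module"]))
    modules = {}
    for gene, label in assignment.items():
        modules.setdefault(label, set()).add(gene)
    part = md.ModulePartition(
        assignment=assignment,
        module_scores={m: float("nan") for m in modules},
        modules={m: frozenset(g) for m, g in modules.items()},
    )
    ds = ExpressionDataset.from_dir(_require(outdir / "dataset_discovery", "simulate"))
    universe = set(ds.reporters)
    gene_sets = {
        f"planted_module_{k}": mod for k, mod in enumerate(truth.planted_modules)
    }
    table = md.module_enrichment(part, gene_sets, universe)
    table.to_csv(outdir / "module_enrichment.tsv", sep="\t", index=False)
    _write_meta(outdir, "enrich", cfg, ["module_enrichment.tsv"])
    n_sig = int((table["p_bonferroni"] < 0.05).sum())
    return {"n_enrichments_tested": len(table), "n_significant": n_sig}
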