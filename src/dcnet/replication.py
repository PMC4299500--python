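"""Replication of a discovery DC network in an independent cohort.

A discovery pair replicates when both genes are measured in the
independent data, the independent-cohort heterogeneity Q exceeds a lenient
analytical cutoff (3.84, chi^2(1) P = 0.05 by default), and the relaxed
GOC/LOC direction — GOC iff the case-group Spearman p-value is smaller
than the control-group one — matches the discovery direction. Significance
of the replication fraction is assessed against a connectivity-preserving
null that shuffles gene labels over the network's gene universe, which
preserves the pair count and the entire degree sequence of the discovery
network on every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as st
from .datasets import as_matrix
from .network import DCNetwork

__all__ = [
    "ReplicationResult",
    "relaxed_direction",
    "replication_fraction",
    "connectivity_preserving_null",
    "control_correlation_replication",
    "exclude_age_associated",
]


@dataclass
class ReplicationResult:
    """Replication outcome, optionally with a shuffled-label null."""

    n_eligible: int
    n_replicated: int
    fraction: float
    null_fractions: np.ndarray | None = None
    empirical_p: float | None = None
    by_direction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0 <= self.n_replicated <= self.n_eligible
        assert 0.0 <= self.fraction <= 1.0


def relaxed_direction(p_case: float, p_ctrl: float) -> str:
    """GOC iff the case correlation p-value is lower, else (ties) LOC."""
    if np.isnan(p_case) or np.isnan(p_ctrl):
        raise ValueError("both p-values must be defined")
    return st.GOC if p_case < p_ctrl else st.LOC


class _IndependentCohort:
    """Precomputed all-pairs statistics over a restricted gene universe."""

    def __init__(self, genes, indep_case: pd.DataFrame, indep_ctrl: pd.DataFrame):
        self.genes = [g for g in genes if g in indep_case.index and g in indep_ctrl.index]
        self.pos = {g: k for k, g in enumerate(self.genes)}
        case = as_matrix(indep_case.loc[self.genes])
        ctrl = as_matrix(indep_ctrl.loc[self.genes])
        self.n_case, self.n_ctrl = case.shape[1], ctrl.shape[1]
        r1, p1 = st.pairwise_spearman(case)
        r2, p2 = st.pairwise_spearman(ctrl)
        with np.errstate(invalid="ignore"):
            self.q = st.q_from_z(
                st.fisher_z(r1), self.n_case, st.fisher_z(r2), self.n_ctrl
            )
        self.p_case, self.p_ctrl = p1, p2

    def replicates(self, gi: str, gj: str, direction: str, q_rep: float) -> bool:
        a, b = self.pos[gi], self.pos[gj]
        q = self.q[a, b]
        if not np.isfinite(q) or q <= q_rep:
            return False
        return relaxed_direction(self.p_case[a, b], self.p_ctrl[a, b]) == direction


def replication_fraction(
    discovery: DCNetwork,
    indep_case: pd.DataFrame,
    indep_ctrl: pd.DataFrame,
    q_rep: float = 3.84,
) -> ReplicationResult:
    """Fraction of discovery DC pairs replicating in an independent cohort."""
    cohort = _IndependentCohort(sorted(discovery.genes), indep_case, indep_ctrl)
    present = set(cohort.genes)
    eligible = discovery.pairs[
        discovery.pairs["gene_i"].isin(present) & discovery.pairs["gene_j"].isin(present)
    ]
    if len(eligible) == 0:
        raise ValueError("no discovery pairs have both genes in the independent data")
    hits = {
        d: 0 for d in (st.GOC, st.LOC)
    }
    totals = {st.GOC: 0, st.LOC: 0}
    n_rep = 0
    for row in eligible.itertuples(index=False):
        totals[row.direction] += 1
        if cohort.replicates(row.gene_i, row.gene_j, row.direction, q_rep):
            hits[row.direction] += 1
            n_rep += 1
    by_dir = {
        d: (hits[d] / totals[d] if totals[d] else float("nan")) for d in totals
    }
    return ReplicationResult(
        n_eligible=len(eligible),
        n_replicated=n_rep,
        fraction=n_rep / len(eligible),
        by_direction=by_dir,
    )


def connectivity_preserving_null(
    discovery: DCNetwork,
    indep_case: pd.DataFrame,
    indep_ctrl: pd.DataFrame,
    n_shuffles: int = 1000,
    q_rep: float = 3.84,
    seed=None,
) -> ReplicationResult:
    """Gene-label-shuffling null for the replication fraction.

    Each shuffle permutes node identities over the discovery network's
    genes (restricted to those present in the independent data), keeping
    the topology — pair count and full degree sequence — fixed, and
    recomputes the replication fraction. The empirical p is
    (1 + #{null >= observed}) / (1 + n_shuffles), reported overall and for
    GOC-only / LOC-only pair sets.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    restricted = discovery.restrict_genes(
        set(indep_case.index) & set(indep_ctrl.index)
    )
    observed = replication_fraction(restricted, indep_case, indep_ctrl, q_rep)
    cohort = _IndependentCohort(sorted(restricted.genes), indep_case, indep_ctrl)
    universe = list(cohort.genes)
    pairs = restricted.pairs
    null_all = np.empty(n_shuffles)
    null_dir = {st.GOC: np.empty(n_shuffles), st.LOC: np.empty(n_shuffles)}
    for s in range(n_shuffles):
        perm = rng.permutation(len(universe))
        relabel = {universe[k]: universe[perm[k]] for k in range(len(universe))}
        n_hit = 0
        hit_dir = {st.GOC: 0, st.LOC: 0}
        tot_dir = {st.GOC: 0, st.LOC: 0}
        for row in pairs.itertuples(index=False):
            a, b = relabel[row.gene_i], relabel[row.gene_j]
            tot_dir[row.direction] += 1
            if cohort.replicates(a, b, row.direction, q_rep):
                n_hit += 1
                hit_dir[row.direction] += 1
        null_all[s] = n_hit / len(pairs)
        for d in null_dir:
            null_dir[d][s] = hit_dir[d] / tot_dir[d] if tot_dir[d] else np.nan
    emp_p = (1 + int((null_all >= observed.fraction).sum())) / (1 + n_shuffles)
    by_direction = {}
    for d in (st.GOC, st.LOC):
        obs_d = observed.by_direction.get(d, float("nan"))
        vals = null_dir[d][~np.isnan(null_dir[d])]
        p_d = (
            (1 + int((vals >= obs_d).sum())) / (1 + vals.size)
            if vals.size and not np.isnan(obs_d)
            else float("nan")
        )
        by_direction[d] = {"fraction": obs_d, "empirical_p": p_d}
    return ReplicationResult(
        n_eligible=observed.n_eligible,
        n_replicated=observed.n_replicated,
        fraction=observed.fraction,
        null_fractions=null_all,
        empirical_p=emp_p,
        by_direction=by_direction,
    )


def control_correlation_replication(
    loc_pairs: DCNetwork | pd.DataFrame,
    indep_ctrl: pd.DataFrame,
    alpha: float = 0.05,
    n_shuffles: int = 100,
    seed=None,
) -> dict:
    """Do LOC pairs stay correlated in independent control samples?

    Tests each LOC pair's Pearson correlation in the independent controls
    and reports the fractions with p < ``alpha`` nominally and after
    Bonferroni correction over the tested pairs, contrasted against
    equally sized gene-label-shuffled pair sets via a two-proportion
    z-test with continuity correction.
    """
    pairs = loc_pairs.pairs if isinstance(loc_pairs, DCNetwork) else loc_pairs
    present = set(indep_ctrl.index)
    pairs = pairs[pairs["gene_i"].isin(present) & pairs["gene_j"].isin(present)]
    if len(pairs) == 0:
        raise ValueError("no pairs with both genes in the independent controls")
    rng = np.random.default_rng(seed)
    genes = sorted(set(pairs["gene_i"]) | set(pairs["gene_j"]))
    pos = {g: k for k, g in enumerate(genes)}
    x = as_matrix(indep_ctrl.loc[genes])
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ xc.T) / np.outer(sd, sd)
    r = np.clip(corr, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    pmat = 2.0 * sps.t.sf(np.abs(t), n - 2)

    def fractions(pair_idx):
        pv = np.array([pmat[a, b] for a, b in pair_idx])
        nominal = float(np.mean(pv < alpha))
        bonf = float(np.mean(pv * len(pv) < alpha))
        return nominal, bonf

    idx = [(pos[r_.gene_i], pos[r_.gene_j]) for r_ in pairs.itertuples(index=False)]
    frac_nominal, frac_bonf = fractions(idx)
    null_nominal = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(genes))
        idx_s = [(perm[a], perm[b]) for a, b in idx]
        null_nominal.append(fractions(idx_s)[0])
    null_mean = float(np.mean(null_nominal))
    z, p2 = _two_proportion_test(
        frac_nominal, null_mean, len(idx), len(idx) * max(1, n_shuffles)
    )
    return {
        "n_tested": len(idx),
        "frac_nominal": frac_nominal,
        "frac_bonferroni": frac_bonf,
        "null_frac_nominal": null_mean,
        "two_proportion_z": z,
        "two_proportion_p": p2,
    }


def _two_proportion_test(p1: float, p2: float, n1: int, n2: int):
    """Two-proportion z-test with continuity correction (two-sided)."""
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    cc = 0.5 * (1 / n1 + 1 / n2)
    z = (abs(p1 - p2) - cc) / se
    z = max(z, 0.0)
    return float(np.sign(p1 - p2) * z), float(2 * sps.norm.sf(z))


def exclude_age_associated(
    discovery: DCNetwork,
    elder_expr: pd.DataFrame,
    adult_expr: pd.DataFrame,
    q_age: float = 2.71,
) -> tuple[DCNetwork, float]:
    """Drop discovery pairs that are differentially co-expressed with age.

    Only pairs whose genes are measured in both aging matrices are
    considered (the rest are excluded from the returned network as
    untestable). A pair is age-associated when its elder-vs-adult Q
    exceeds ``q_age`` (lenient chi^2(1) P = 0.1 cutoff by default).
    Returns the filtered network and the removed fraction among testable
    pairs.
    """
    present = set(elder_expr.index) & set(adult_expr.index)
    testable = discovery.restrict_genes(present)
    if len(testable) == 0:
        return testable, 0.0
    cohort = _IndependentCohort(sorted(testable.genes), elder_expr, adult_expr)
    keep = []
    for row in testable.pairs.itertuples(index=False):
        a, b = cohort.pos[row.gene_i], cohort.pos[row.gene_j]
        q = cohort.q[a, b]
        keep.append(not (np.isfinite(q) and q > q_age))
    keep = np.asarray(keep, dtype=bool)
    removed_fraction = float(1.0 - keep.mean())
    return testable.subset(keep), removed_fraction
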