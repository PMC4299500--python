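"""Case/control differential co-expression model and its fitted results.

The modelling surface follows the fitted-model convention: build a
:class:`DifferentialCoexpression` model from case and control expression
matrices, call :meth:`~DifferentialCoexpression.fit`, and receive a
:class:`DCResults` object carrying the selected Q cutoff, the permutation
FDR curve, the assembled DC network and a summary table.

The false-discovery-rate calibration is global and permutation based:
sample labels are shuffled across the pooled groups (group sizes
preserved), the all-pairs Q statistics are recomputed on the shuffled data,
and for any cutoff Q0 the estimated FDR is the ratio of permuted to
original pair counts exceeding Q0. The selected cutoff is the smallest
observed Q whose (monotone-enforced) estimate meets the target.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as st
from .datasets import ExpressionDataset, as_matrix
from .network import DCNetwork

__all__ = ["DifferentialCoexpression", "DCResults", "estimate_fdr_cutoff"]


def estimate_fdr_cutoff(case_expr, ctrl_expr, target_fdr: float = 0.01,
                        n_perm: int = 1, seed=None):
    """Select the Q cutoff meeting a target global permutation FDR.

    Parameters
    ----------
    case_expr, ctrl_expr : array-like
        Genes x samples matrices over an identical gene set.
    target_fdr : float
        Target global FDR in (0, 1); default 1%.
    n_perm : int
        Number of label permutations; the permuted pair counts are
        averaged in the numerator when > 1. One permutation is the default.
    seed : int, optional
        Seed for the label shuffles.

    Returns
    -------
    q0 : float
        Smallest observed Q at which the monotone-enforced FDR estimate is
        <= ``target_fdr``; ``inf`` (with a warning) if no cutoff achieves
        the target, in which case no DC pairs would be called.
    fdr_curve : pandas.DataFrame
        Candidate cutoffs (the observed Q values, descending) with original
        and mean permuted exceedance counts, the raw ratio estimate, and
        the monotone (running-maximum, descending in Q) estimate.
    """
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target_fdr must be in (0, 1)")
    case = as_matrix(case_expr)
    ctrl = as_matrix(ctrl_expr)
    q_obs = st.pair_statistics(case, ctrl)["q"]
    q_obs = q_obs[np.isfinite(q_obs)]
    q_perm = _permuted_q(case, ctrl, n_perm, seed)
    return fdr_curve_from_q(q_obs, q_perm, n_perm, target_fdr)


def fdr_curve_from_q(q_obs, q_perm, n_perm: int, target_fdr: float):
    """Build the FDR curve from observed and pooled permuted Q values."""
    qs = np.sort(q_obs)[::-1]  # candidate cutoffs, descending
    # cutting "at" an observed value calls that pair, so exceedance counts are
    # taken as Q >= q for both the original and the permuted data (cumulative
    # counts make the curve well defined at the top of the range)
    n_orig = np.arange(1, qs.size + 1, dtype=float)
    qp = np.sort(q_perm)
    n_perm_mean = (qp.size - np.searchsorted(qp, qs, side="left")) / max(n_perm, 1)
    raw = n_perm_mean / n_orig
    mono = np.maximum.accumulate(raw)  # non-decreasing as q0 decreases
    curve = pd.DataFrame(
        {"q": qs, "n_orig": n_orig, "n_perm_mean": n_perm_mean, "fdr_raw": raw, "fdr": mono}
    )
    ok = mono <= target_fdr
    if not ok.any():
        warnings.warn(
            f"no cutoff achieves target FDR {target_fdr}; returning +inf (zero DC calls)"
        )
        return float("inf"), curve
    q0 = float(qs[ok][-1])  # smallest observed Q meeting the target
    return q0, curve


def _permuted_q(case, ctrl, n_perm, seed):
    """Pool samples, shuffle labels preserving group sizes, recompute Q."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    pooled = np.hstack([case, ctrl])
    n1 = case.shape[1]
    out = []
    for _ in range(n_perm):
        order = rng.permutation(pooled.shape[1])
        pc, pt = pooled[:, order[:n1]], pooled[:, order[n1:]]
        qp = st.pair_statistics(pc, pt)["q"]
        out.append(qp[np.isfinite(qp)])
    return np.concatenate(out)


class DifferentialCoexpression:
    """Differential co-expression model for a case/control comparison.

    Parameters
    ----------
    case, ctrl : pandas.DataFrame or array-like
        Genes x samples expression matrices over the same reporters (rows
        aligned; DataFrames are checked by index).
    reporters : sequence of str, optional
        Reporter IDs when plain arrays are passed.
    alpha_coexpr : float
        Per-group co-expression significance level after Bonferroni
        correction over all reporter-reporter tests (default 0.01).
    max_genes : int
        Guard on the all-pairs computation; raise above this many genes.
    """

    def __init__(self, case, ctrl, reporters=None, alpha_coexpr: float = 0.01,
                 max_genes: int = 3000):
        if isinstance(case, pd.DataFrame) and isinstance(ctrl, pd.DataFrame):
            if list(case.index) != list(ctrl.index):
                raise ValueError("case and control matrices must share reporters")
            reporters = list(case.index)
        self.case = as_matrix(case)
        self.ctrl = as_matrix(ctrl)
        if self.case.shape[0] != self.ctrl.shape[0]:
            raise ValueError("case and control matrices must share the gene axis")
        n_genes = self.case.shape[0]
        if n_genes > max_genes:
            raise ValueError(
                f"{n_genes} genes exceeds max_genes={max_genes}; the all-pairs "
                "computation is quadratic - raise max_genes deliberately"
            )
        self.reporters = list(reporters) if reporters is not None else [
            f"g{k}" for k in range(n_genes)
        ]
        self.alpha_coexpr = alpha_coexpr

    @classmethod
    def from_dataset(cls, ds: ExpressionDataset, case_label: str = "case",
                     ctrl_label: str = "control", **kwargs) -> "DifferentialCoexpression":
        return cls(ds.group_matrix(case_label), ds.group_matrix(ctrl_label), **kwargs)

    def fit(self, target_fdr: float = 0.01, n_perm: int = 1, seed=None) -> "DCResults":
        """Run the full DC analysis and return the fitted results."""
        pair = st.pair_statistics(self.case, self.ctrl)
        finite = np.isfinite(pair["q"])
        n_dropped = int((~finite).sum())
        if n_dropped:
            warnings.warn(f"excluding {n_dropped} pairs with undefined correlation")
        q0, curve = fdr_curve_from_q(
            pair["q"][finite],
            _permuted_q(self.case, self.ctrl, n_perm, seed),
            n_perm,
            target_fdr,
        )
        network = self._call_network(pair, finite, q0, target_fdr)
        return DCResults(self, pair, q0, curve, network, target_fdr, n_dropped)

    def _call_network(self, pair, finite, q0, target_fdr) -> DCNetwork:
        n_rep = len(self.reporters)
        q = pair["q"]
        sig1 = st.coexpression_significant(pair["p_case"], n_rep, self.alpha_coexpr)
        sig2 = st.coexpression_significant(pair["p_ctrl"], n_rep, self.alpha_coexpr)
        above = finite & (q > q0)
        goc = above & sig1 & ~sig2
        loc = above & ~sig1 & sig2
        keep = goc | loc
        rep = np.asarray(self.reporters, dtype=object)
        frame = pd.DataFrame(
            {
                "gene_i": rep[pair["i"][keep]],
                "gene_j": rep[pair["j"][keep]],
                "direction": np.where(goc[keep], st.GOC, st.LOC),
                "q": q[keep],
                "r_case": pair["r_case"][keep],
                "r_ctrl": pair["r_ctrl"][keep],
                "p_case": pair["p_case"][keep],
                "p_ctrl": pair["p_ctrl"][keep],
            }
        )
        return DCNetwork(frame, q0=q0, fdr_target=target_fdr)


class DCResults:
    """Fitted differential co-expression results.

    Attributes
    ----------
    q0 : float
        Selected heterogeneity cutoff (smallest observed Q meeting the
        FDR target).
    fdr_curve : pandas.DataFrame
        Estimated global FDR across candidate cutoffs.
    network : DCNetwork
        The called DC pairs (Q gate plus one-group co-expression gate).
    """

    def __init__(self, model, pair, q0, fdr_curve, network, target_fdr, n_dropped):
        self.model = model
        self._pair = pair
        self.q0 = q0
        self.fdr_curve = fdr_curve
        self.network = network
        self.target_fdr = target_fdr
        self.n_dropped_pairs = n_dropped

    @property
    def estimated_fdr_at_q0(self) -> float:
        """Monotone permutation-FDR estimate at the selected cutoff."""
        if not np.isfinite(self.q0):
            return float("nan")
        row = self.fdr_curve.loc[self.fdr_curve["q"] == self.q0]
        return float(row["fdr"].iloc[0])

    @property
    def n_pairs_tested(self) -> int:
        return int(self._pair["q"].size)

    def pair_stats(self) -> pd.DataFrame:
        """All tested pairs as a DataFrame (large: O(genes^2) rows)."""
        rep = np.asarray(self.model.reporters, dtype=object)
        p = self._pair
        return pd.DataFrame(
            {
                "gene_i": rep[p["i"]],
                "gene_j": rep[p["j"]],
                "r_case": p["r_case"],
                "r_ctrl": p["r_ctrl"],
                "p_case": p["p_case"],
                "p_ctrl": p["p_ctrl"],
                "q": p["q"],
            }
        )

    def summary(self) -> str:
        counts = self.network.counts()
        n = len(self.network)
        lines = [
            "Differential co-expression results",
            "==================================",
            f"reporters:            {len(self.model.reporters)}",
            f"pairs tested:         {self.n_pairs_tested}",
            f"pairs excluded (NaN): {self.n_dropped_pairs}",
            f"FDR target:           {self.target_fdr:g}",
            f"selected Q0:          {self.q0:.4g}",
            f"estimated FDR at Q0:  {self.estimated_fdr_at_q0:.4g}",
            f"DC pairs called:      {n}",
        ]
        if n:
            lines += [
                f"  GOC: {counts[st.GOC]} ({100 * counts[st.GOC] / n:.1f}%)",
                f"  LOC: {counts[st.LOC]} ({100 * counts[st.LOC] / n:.1f}%)",
            ]
        return "\n".join(lines)

    def plot_fdr_curve(self, ax=None):
        """Estimated FDR versus candidate Q cutoff, with the selection marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fdr_curve["q"], self.fdr_curve["fdr"], lw=1)
        if np.isfinite(self.q0):
            ax.axvline(self.q0, color="crimson", ls="--", lw=1,
                       label=f"Q0 = {self.q0:.2f}")
            ax.legend()
        ax.axhline(self.target_fdr, color="grey", ls=":", lw=1)
        ax.set_xlabel("Q cutoff")
        ax.set_ylabel("estimated global FDR")
        ax.set_yscale("log")
        return ax
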