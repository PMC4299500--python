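"""Expression adjustment: control-probe PCs, robust regression, imputation.

Adjustment proceeds in three steps. (1) Principal components are derived
from the control-probe block: PC1 of each of the two dedicated probe
classes ("r60", "Pro25G") enters unconditionally, and the PCs of the
remaining control probes enter only when their variance explained beats a
permutation null (each probe permuted independently) at a stringent
threshold. (2) Each gene is regressed, separately per sample group, on the
sample covariates plus the selected PC score vectors with a robust
M-estimator, and the residuals become the adjusted expression. (3) Missing
values are imputed by k-nearest neighbours in the space of genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import ExpressionDataset

__all__ = ["AdjustmentModel", "select_control_pcs", "adjust_expression", "impute_knn"]

log = logging.getLogger(__name__)

SPECIAL_CLASSES = ("r60", "Pro25G")


@dataclass
class AdjustmentModel:
    """Fitted adjustment: selected PCs, per-group coefficients, residuals."""

    selected_pcs: list  # (probe-class label, PC index, unit-norm score vector)
    coefficients: dict  # group -> DataFrame (genes x design columns)
    residuals: pd.DataFrame  # same shape and ordering as the input matrix


def _row_centered_pcs(block: np.ndarray):
    """PC score vectors (right singular vectors) and variance-explained
    fractions of a row-centred probes-x-samples block."""
    centered = block - block.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    ve = var / total if total > 0 else var
    return vt, ve


def select_control_pcs(
    control_probes: pd.DataFrame,
    classes: pd.Series,
    n_perm: int = 10_000,
    p_thresh: float = 1e-4,
    seed=None,
    special_classes=SPECIAL_CLASSES,
) -> list[tuple[str, int, np.ndarray]]:
    """Select control-probe PCs to use as adjustment covariates.

    PC1 of each special class is always included. Each PC of the pooled
    remaining probes is kept when its variance-explained fraction exceeds
    the permutation null of the *largest* permuted variance explained at
    ``p_thresh``, with p = (1 + #{perm max VE >= observed}) / (1 + n_perm).
    An absent class contributes nothing (logged). PC score vectors are unit
    norm over samples.
    """
    if control_probes.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute control-probe PCs")
    if n_perm < 1.0 / p_thresh:
        warnings.warn(
            f"n_perm={n_perm} cannot reach p_thresh={p_thresh}: "
            "the smallest attainable p is 1/(1+n_perm)"
        )
    rng = np.random.default_rng(seed)
    selected: list[tuple[str, int, np.ndarray]] = []
    for cls in special_classes:
        members = classes.index[classes == cls]
        if len(members) == 0:
            log.info("control-probe class %r absent; contributes no PC", cls)
            continue
        vt, _ = _row_centered_pcs(control_probes.loc[members].to_numpy(float))
        selected.append((cls, 1, vt[0]))

    rest = classes.index[~classes.isin(special_classes)]
    if len(rest) == 0:
        log.info("no remaining-class control probes; permutation step skipped")
        return selected
    block = control_probes.loc[rest].to_numpy(float)
    vt, ve = _row_centered_pcs(block)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.array([rng.permutation(row) for row in block])
        _, ve_perm = _row_centered_pcs(perm)
        null_max[b] = ve_perm[0]
    for k, ve_k in enumerate(ve):
        p = (1 + int((null_max >= ve_k).sum())) / (1 + n_perm)
        if p <= p_thresh:
            selected.append(("remaining", k + 1, vt[k]))
        else:
            break  # variance explained is decreasing; later PCs cannot pass
    return selected


def _design_matrix(
    covariates: pd.DataFrame, covariate_names, pcs, samples
) -> pd.DataFrame:
    cols = {"const": np.ones(len(samples))}
    for name in covariate_names:
        col = covariates.loc[samples, name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[name] = col.to_numpy(float)
    for label, idx, score in pcs:
        full = pd.Series(score, index=covariates.index)
        cols[f"pc_{label}_{idx}"] = full.loc[samples].to_numpy(float)
    return pd.DataFrame(cols, index=samples)


def _drop_collinear(design: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing collinear columns (QR pivot-free greedy check)."""
    x = design.to_numpy(float)
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    if len(keep) < x.shape[1]:
        dropped = [design.columns[j] for j in range(x.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear design columns: {dropped}")
    return design.iloc[:, keep]


def adjust_expression(
    ds: ExpressionDataset,
    pcs: list,
    covariate_names: list[str],
    psi: str = "huber",
    maxiter: int = 50,
    tol: float = 1e-8,
) -> AdjustmentModel:
    """Residualize each gene on covariates + PCs, separately per group.

    The fit is a robust M-estimator via iteratively reweighted least
    squares: Huber psi (tuning constant 1.345) by default, Tukey bisquare
    (c = 4.685) with ``psi="bisquare"``. Residuals from the per-group fits
    are the adjusted expression; groups never share samples, so permuting
    one group's samples cannot change another group's residuals.
    Zero-variance genes yield zero residuals.
    """
    if ds.covariates[covariate_names].isna().any().any():
        raise ValueError("covariates must be complete for all samples")
    norm = {
        "huber": sm.robust.norms.HuberT(t=1.345),
        "bisquare": sm.robust.norms.TukeyBiweight(c=4.685),
    }[psi]
    residuals = pd.DataFrame(
        np.nan, index=ds.values.index, columns=ds.values.columns
    )
    coefficients: dict[str, pd.DataFrame] = {}
    for label in ds.group_names:
        samples = list(ds.groups.index[ds.groups == label])
        design = _drop_collinear(_design_matrix(ds.covariates, covariate_names, pcs, samples))
        x = design.to_numpy(float)
        block = ds.values.loc[:, samples].to_numpy(float)
        coefs = np.zeros((block.shape[0], x.shape[1]))
        res = np.zeros_like(block)
        for g in range(block.shape[0]):
            y = block[g]
            if np.ptp(y) == 0:
                continue  # zero-variance gene -> zero residual vector
            fit = sm.RLM(y, x, M=norm).fit(maxiter=maxiter, tol=tol)
            coefs[g] = fit.params
            res[g] = fit.resid
        residuals.loc[:, samples] = res
        coefficients[label] = pd.DataFrame(
            coefs, index=ds.values.index, columns=design.columns
        )
    return AdjustmentModel(selected_pcs=list(pcs), coefficients=coefficients,
                           residuals=residuals)


def impute_knn(values: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """k-nearest-neighbour imputation in the space of genes.

    Distance between genes is the Euclidean distance over their mutually
    observed samples; a missing cell is filled with the 1/distance-weighted
    mean of the k nearest genes observed at that sample. Observed cells are
    returned unchanged. A gene with no observed value is an error; fewer
    than k eligible neighbours triggers a warning and uses all eligible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = values.to_numpy(float)
    missing = np.isnan(x)
    if not missing.any():
        return values.copy()
    all_missing = missing.all(axis=1)
    if all_missing.any():
        name = values.index[int(np.nonzero(all_missing)[0][0])]
        raise ValueError(f"gene {name!r} has no observed values; cannot impute")

    out = x.copy()
    n_genes = x.shape[0]
    warned = False
    for g in np.nonzero(missing.any(axis=1))[0]:
        obs_g = ~missing[g]
        # squared Euclidean distance to every other gene over mutual samples
        mutual = obs_g[None, :] & ~missing
        diff = np.where(mutual, x - x[g], 0.0)
        n_mutual = mutual.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1))
        dist[g] = np.inf
        dist[n_mutual == 0] = np.inf
        for s in np.nonzero(missing[g])[0]:
            donors = np.nonzero(~missing[:, s] & np.isfinite(dist))[0]
            if donors.size == 0:
                raise ValueError(
                    f"no eligible neighbours for gene {values.index[g]!r} "
                    f"at sample {values.columns[s]!r}"
                )
            if donors.size < k and not warned:
                warnings.warn(
                    f"fewer than k={k} eligible neighbours for some cells; "
                    "using all eligible"
                )
                warned = True
            order = donors[np.argsort(dist[donors], kind="stable")][:k]
            d = dist[order]
            if np.any(d == 0):
                out[g, s] = x[order[d == 0], s].mean()
            else:
                w = 1.0 / d
                out[g, s] = np.average(x[order, s], weights=w)
    assert not (n_genes and np.isnan(out).any())
    return pd.DataFrame(out, index=values.index, columns=values.columns)
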