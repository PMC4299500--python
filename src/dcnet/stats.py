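"""Pair-level differential co-expression statistics.

The core statistic is a meta-analytic heterogeneity test on Fisher-z
transformed Spearman correlations. For a gene pair with correlation r_t and
sample size n_t in group t (t = 1 case, t = 2 control),

    z_t = arctanh(r_t),   w_t = n_t - 3,
    zbar = (w_1 z_1 + w_2 z_2) / (w_1 + w_2),
    Q = sum_t w_t (z_t - zbar)^2,

and Q ~ chi^2 with 1 d.f. under homogeneity of the two correlations (and
bivariate normality). Large Q means the pair's co-expression differs between
groups. The classical n-3 variance is exact for Pearson z; applying it to
Spearman correlations (as done here throughout) is a deliberate,
field-standard approximation whose mild miscalibration is quantified in the
test suite's null-calibration checks.

Differential co-expression (DC) calls additionally require the pair to be
significantly co-expressed in exactly one of the two groups (Spearman test
p <= alpha after Bonferroni correction over all reporter-reporter tests):
gain of co-expression (GOC) if only the case group is significant, loss
(LOC) if only the control group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairStats",
    "spearman_with_p",
    "fisher_z",
    "q_statistic",
    "chi2_cutoff",
    "chi2_p",
    "coexpression_significant",
    "classify_dc",
    "pairwise_spearman",
    "pair_statistics",
    "de_ttest",
    "dc_de_overlap",
    "bootstrap_dc_p",
]

GOC = "GOC"
LOC = "LOC"

_CLAMP = 1.0 - 1e-15  # |r| = 1 clamped before arctanh; keeps z finite and ordered


@dataclass(frozen=True)
class PairStats:
    """Per-pair, per-group correlation statistics plus the Q statistic."""

    gene_i: str
    gene_j: str
    r_case: float
    r_ctrl: float
    n_case: int
    n_ctrl: int
    p_case: float
    p_ctrl: float
    q: float

    @property
    def z_case(self) -> float:
        return fisher_z(self.r_case, self.n_case)

    @property
    def z_ctrl(self) -> float:
        return fisher_z(self.r_ctrl, self.n_ctrl)


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman correlation with a two-sided p from the t approximation.

    Ties get average ranks. A zero-variance input yields ``(nan, nan)``;
    such pairs are excluded downstream rather than imputed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, _spearman_p(r, x.size)


def _spearman_p(r, n):
    """Two-sided p for a Spearman r via the t approximation on ranks."""
    r = np.clip(r, -_CLAMP, _CLAMP)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * sps.t.sf(np.abs(t), n - 2)


def fisher_z(r, n: int | None = None):
    """Fisher z transform, z = arctanh(r).

    Under bivariate normality z is approximately normal with sd
    1/sqrt(n - 3); ``n`` (when given) is validated so the weight n - 3 is
    positive. ``|r| = 1`` is clamped to keep z finite.
    """
    if n is not None and n < 4:
        raise ValueError(f"sample size {n} < 4: Fisher weight n - 3 is non-positive")
    r = np.clip(np.asarray(r, dtype=float), -_CLAMP, _CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def q_statistic(r1, n1: int, r2, n2: int):
    """Heterogeneity Q for two correlations with weights w_t = n_t - 3."""
    z1 = fisher_z(r1, n1)
    z2 = fisher_z(r2, n2)
    return q_from_z(z1, n1, z2, n2)


def q_from_z(z1, n1: int, z2, n2: int):
    """Q from precomputed Fisher z values (vectorized).

    Algebraically Q = w1 w2 / (w1 + w2) * (z1 - z2)^2, identical to the
    weighted-deviation form around zbar.
    """
    w1, w2 = n1 - 3.0, n2 - 3.0
    if w1 <= 0 or w2 <= 0:
        raise ValueError("both sample sizes must be >= 4")
    zbar = (w1 * np.asarray(z1) + w2 * np.asarray(z2)) / (w1 + w2)
    q = w1 * (z1 - zbar) ** 2 + w2 * (z2 - zbar) ** 2
    return float(q) if np.ndim(q) == 0 else q


def chi2_cutoff(alpha: float) -> float:
    """Upper-``alpha`` quantile of chi^2(1): the analytical Q cutoff."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.chi2.isf(alpha, df=1))


def chi2_p(q) -> float:
    """Upper-tail chi^2(1) probability of a Q value."""
    return sps.chi2.sf(q, df=1)


def coexpression_significant(p_raw, n_reporters: int, alpha: float = 0.01):
    """Bonferroni-corrected significance of a correlation test.

    True iff ``p_raw * N(N-1)/2 <= alpha`` where N is the number of
    reporters in the dataset at hand (all reporter-reporter tests).
    """
    if n_reporters < 2:
        raise ValueError("need at least 2 reporters")
    n_tests = n_reporters * (n_reporters - 1) / 2.0
    return np.asarray(p_raw) * n_tests <= alpha


def classify_dc(stats: PairStats, q0: float, n_reporters: int, alpha: float = 0.01) -> str | None:
    """Classify a pair as GOC, LOC, or neither.

    GOC: Q > q0 and significantly co-expressed in the case group only.
    LOC: Q > q0 and significantly co-expressed in the control group only.
    Significant in both, in neither, or Q <= q0 -> not a DC pair.
    """
    if not np.isfinite(stats.q) or stats.q <= q0:
        return None
    sig_case = bool(coexpression_significant(stats.p_case, n_reporters, alpha))
    sig_ctrl = bool(coexpression_significant(stats.p_ctrl, n_reporters, alpha))
    if sig_case and not sig_ctrl:
        return GOC
    if sig_ctrl and not sig_case:
        return LOC
    return None


# ---------------------------------------------------------------------------
# vectorized all-pairs machinery
# ---------------------------------------------------------------------------


def pairwise_spearman(matrix) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman correlations and two-sided p-values.

    ``matrix`` is genes x samples; returns the (genes x genes) correlation
    and p matrices. Zero-variance genes yield NaN rows/columns.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[1]
    ranks = sps.rankdata(x, axis=1)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    with np.errstate(invalid="ignore"):
        p = _spearman_p(r, n)
    return r, p


def pair_statistics(case, ctrl):
    """Upper-triangle pair statistics for two aligned expression matrices.

    Returns a dict of flat arrays (index pairs ``i``, ``j`` plus r/p per
    group and Q) over the strict upper triangle of the gene x gene grid.
    Pairs with undefined correlation in either group carry NaN Q.
    """
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if case.shape[0] != ctrl.shape[0]:
        raise ValueError("case and control matrices must share the gene axis")
    n1, n2 = case.shape[1], ctrl.shape[1]
    r1m, p1m = pairwise_spearman(case)
    r2m, p2m = pairwise_spearman(ctrl)
    iu, ju = np.triu_indices(case.shape[0], k=1)
    r1, r2 = r1m[iu, ju], r2m[iu, ju]
    p1, p2 = p1m[iu, ju], p2m[iu, ju]
    with np.errstate(invalid="ignore"):
        q = q_from_z(fisher_z(r1), n1, fisher_z(r2), n2)
    return {
        "i": iu,
        "j": ju,
        "r_case": r1,
        "r_ctrl": r2,
        "p_case": p1,
        "p_ctrl": p2,
        "n_case": n1,
        "n_ctrl": n2,
        "q": q,
    }


# ---------------------------------------------------------------------------
# differential expression comparator
# ---------------------------------------------------------------------------


def de_ttest(case, ctrl, alpha: float = 0.05, reporters=None) -> set:
    """Differentially expressed reporters by a lenient two-sample t-test.

    Two-sided, uncorrected p < ``alpha`` per reporter. Reporters with zero
    variance in both groups are skipped with a warning.
    """
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if reporters is None:
        reporters = list(range(case.shape[0]))
    flat = (case.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
    if flat.any():
        warnings.warn(f"skipping {int(flat.sum())} zero-variance reporters in DE test")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(case, ctrl, axis=1)
    keep = ~flat & (res.pvalue < alpha)
    return {reporters[k] for k in np.nonzero(keep)[0]}


def dc_de_overlap(dc_reporters: set, de_reporters: set) -> float:
    """Fraction of DC reporters that are also DE: |DC ∩ DE| / |DC|."""
    if not dc_reporters:
        raise ValueError("empty DC reporter set")
    return len(set(dc_reporters) & set(de_reporters)) / len(dc_reporters)


# ---------------------------------------------------------------------------
# bootstrap verification oracle
# ---------------------------------------------------------------------------


def bootstrap_dc_p(x_case, y_case, x_ctrl, y_ctrl, n_boot: int = 1000, seed=None) -> float:
    """Bootstrap p for a difference of Spearman correlations.

    Observation pairs are resampled with replacement *within* each group
    on the original rank scores (a score bootstrap: the ranks are computed
    once and the resampled correlation is the Pearson correlation of the
    resampled scores). Re-ranking each resample instead would inflate the
    bootstrap variance through resampling ties; the score form reproduces
    the true sampling sd of the Fisher z to ~1% in direct simulation. The
    bootstrap distribution of the z difference d* = z_case* - z_ctrl*,
    centred at the observed d, estimates the sampling distribution of d,
    and the two-sided p tests the null of equal correlation with a
    pseudocount:

        p = (1 + #{|d* - d| >= |d|}) / (1 + n_boot)

    This is the assumption-free comparator for the parametric chi^2 test;
    it is used as a verification oracle, never as the primary statistic.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x1, y1 = np.asarray(x_case, float), np.asarray(y_case, float)
    x2, y2 = np.asarray(x_ctrl, float), np.asarray(y_ctrl, float)
    d_obs = _z_of(x1, y1) - _z_of(x2, y2)
    d_boot = _boot_z(x1, y1, n_boot, rng) - _boot_z(x2, y2, n_boot, rng)
    exceed = np.abs(d_boot - d_obs) >= abs(d_obs)
    return (1 + int(exceed.sum())) / (1 + n_boot)


def _z_of(x, y):
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    return fisher_z(np.corrcoef(rx, ry)[0, 1])


def _boot_z(x, y, n_boot, rng):
    n = x.size
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    rxb, ryb = rx[idx], ry[idx]
    rxb = rxb - rxb.mean(axis=1, keepdims=True)
    ryb = ryb - ryb.mean(axis=1, keepdims=True)
    num = (rxb * ryb).sum(axis=1)
    den = np.sqrt((rxb**2).sum(axis=1) * (ryb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return fisher_z(r)
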