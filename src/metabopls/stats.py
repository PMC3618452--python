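"""Per-bucket univariate statistics: Student's t and Storey q-values.

Each bucket is compared between the two groups with a two-sided
pooled-variance (Student's) t-test on the constant-sum-normalized,
unscaled values.  The resulting p-values are mapped to Storey-Tibshirani
q-values: pi0, the proportion of true nulls, is estimated from the
right tail of the p-value distribution and the step-up rule

    q_(i) = min_{j >= i}  pi0 * m * p_(j) / j

(capped at 1) converts each p-value to the estimated false discovery
rate incurred when calling it significant.  With pi0 = 1 this reduces to
the Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

from .bucketing import BucketTable

__all__ = [
    "BinStat",
    "QvalueResult",
    "student_t_per_bin",
    "storey_qvalues",
    "attach_qvalues",
]

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass
class BinStat:
    """Per-bucket differential statistics (one output-table row)."""

    bin_center_ppm: float
    mean_treated: float
    mean_control: float
    t_stat: float
    p_value: float
    q_value: float = np.nan
    vip: float = np.nan
    fold_change: float = np.nan
    direction: str = ""
    selected: bool = False
    degenerate: bool = False


@dataclass
class QvalueResult:
    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    method: str = "smoother"


def student_t_per_bin(
    table: BucketTable,
    treated_label: str = "treated",
    control_label: str = "control",
) -> list[BinStat]:
    """Two-sided pooled-variance t-test per bucket, treated vs control.

    Means and fold changes are computed on the normalized (unscaled)
    bucket values; fold change is treated mean over control mean.
    """
    tmask = table.group_mask(treated_label)
    cmask = table.group_mask(control_label)
    n1, n2 = int(tmask.sum()), int(cmask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >=2 samples (treated={n1}, control={n2})"
        )
    xt = table.matrix[tmask]
    xc = table.matrix[cmask]
    mt = xt.mean(axis=0)
    mc = xc.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        # zero-variance bins trigger a precision warning; they are handled
        # explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(xt, xc, axis=0, equal_var=True)
    tvals = np.asarray(res.statistic, dtype=float)
    pvals = np.asarray(res.pvalue, dtype=float)

    # zero pooled variance: t undefined in scipy; define by the means
    ss = xt.var(axis=0, ddof=1) * (n1 - 1) + xc.var(axis=0, ddof=1) * (n2 - 1)
    degenerate_mask = ss == 0
    out: list[BinStat] = []
    for j, center in enumerate(table.bin_centers_ppm):
        t_j, p_j, dg = tvals[j], pvals[j], False
        if degenerate_mask[j]:
            if mt[j] == mc[j]:
                t_j, p_j = 0.0, 1.0
            else:
                t_j = np.inf if mt[j] > mc[j] else -np.inf
                p_j, dg = 0.0, True
        fc = mt[j] / mc[j] if mc[j] > 0 and mt[j] > 0 else np.nan
        out.append(
            BinStat(
                bin_center_ppm=float(center),
                mean_treated=float(mt[j]),
                mean_control=float(mc[j]),
                t_stat=float(t_j),
                p_value=float(p_j),
                fold_change=float(fc) if np.isfinite(fc) else np.nan,
                direction="up" if mt[j] > mc[j] else "down",
                degenerate=dg,
            )
        )
    return out


def _pi0_fixed(p: np.ndarray, lam: float) -> float:
    m = p.size
    return float(np.sum(p > lam)) / (m * (1.0 - lam))


def _pi0_smoother(p: np.ndarray, lambda_grid: np.ndarray) -> float:
    pi0s = np.array([_pi0_fixed(p, lam) for lam in lambda_grid])
    # cubic smoothing spline over the lambda grid, evaluated at max lambda
    spline = UnivariateSpline(lambda_grid, pi0s, k=3)
    return float(spline(lambda_grid.max()))


def storey_qvalues(
    pvalues,
    method: str = "smoother",
    lam: float | None = None,
    lambda_grid: np.ndarray | None = None,
) -> QvalueResult:
    """Map p-values to Storey-Tibshirani q-values.

    ``method="smoother"`` (default) estimates pi0 by fitting a cubic
    smoothing spline to pi0(lambda) over lambda in 0.05..0.95 and
    evaluating at the largest lambda; ``method="fixed"`` uses the plug-in
    estimate at a single ``lam``.  pi0 is clamped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID.copy()

    if method == "fixed":
        if lam is None:
            lam = 0.5
        pi0 = _pi0_fixed(p, lam)
        lambda_grid = np.array([lam])
    elif method == "smoother":
        if m < lambda_grid.size:
            # too few tests for the spline; fall back to the median lambda
            pi0 = _pi0_fixed(p, 0.5)
        else:
            pi0 = _pi0_smoother(p, lambda_grid)
    else:
        raise ValueError(f"unknown q-value method {method!r}")
    pi0 = float(np.clip(pi0, 1e-8, 1.0))

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return QvalueResult(
        pvalues=p, qvalues=q, pi0=pi0, lambda_grid=np.asarray(lambda_grid), method=method
    )


def attach_qvalues(stats: list[BinStat], method: str = "smoother") -> QvalueResult:
    """Compute q-values for a list of BinStat and fill them in place."""
    res = storey_qvalues([s.p_value for s in stats], method=method)
    for s, q in zip(stats, res.qvalues):
        s.q_value = float(q)
    return res
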