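"""Asymptotic moments of the ROI-level correlation-stack metric.

The stack metric is Manhattan over the p(p-1) standardized Fisher-z rows, so
under an entrywise-independence assumption its mean and variance would be
p(p-1) times the standard normal L1 projection moments:

    mean  = 2 p (p-1) / sqrt(pi)
    var   = 2 (pi-2) p (p-1) / pi          (independence assumption)

The independence assumption is wrong for the variance — each ROI appears in
p-1 of the stack rows (and each unordered ROI pair appears twice), so the
cross-covariances between ROI diffs do not vanish.  Empirically the
within-dataset sample variance of stack distances exceeds the independence
formula by a quadratic-in-p discrepancy ``beta1 p^2 + beta0 p`` with
beta1 ~ 0.08; folding that in gives the corrected variance

    var   = 9 p (pi-2) (p-1) / (4 pi)      (corrected; the default)

whose correction term is exactly p(pi-2)(p-1)/(4 pi), i.e. an algebraic
beta1 of (pi-2)/(4 pi) ~ 0.0908.  :func:`fit_variance_correction` re-runs the
simulation fit that motivates the correction.

The single-ROI diff keeps the independence variance (the cross-covariances a
single fixed ROI sees are negligible), and the max-min normalized metric uses
the normal extreme-value machinery with effective extreme-sample size
m(p-1) — the total number of values in an ROI's block, which is the sample
the block's range is taken over in practice.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from ._types import CorrectionFit, DiffMoments, MomentSummary
from .extreme_values import normal_max_stats

__all__ = [
    "fmri_distance_moments",
    "fmri_diff_moments",
    "fmri_maxmin_moments",
    "fit_variance_correction",
]

_PI = math.pi


def _check_p(p: int) -> int:
    p = int(p)
    if p < 2:
        raise ValueError("need at least p=2 ROIs")
    return p


def fmri_distance_moments(p: int, corrected: bool = True) -> MomentSummary:
    """Mean/variance of the stack distance for p ROIs on null data."""
    p = _check_p(p)
    mean = 2.0 * p * (p - 1) / math.sqrt(_PI)
    if corrected:
        variance = 9.0 * p * (_PI - 2.0) * (p - 1) / (4.0 * _PI)
    else:
        variance = 2.0 * (_PI - 2.0) * p * (p - 1) / _PI
    return MomentSummary(
        mean=mean,
        variance=variance,
        family="normal",
        params={"metric": "fmri", "p": p, "corrected": bool(corrected)},
    )


def fmri_diff_moments(p: int, alternative: bool = False) -> DiffMoments:
    """Mean/variance of a single ROI's diff (sum of p-1 absolute differences).

    The default variance ``2(pi-2)(p-1)/pi`` treats the p-1 terms as
    independent and tracks simulated diffs closely; ``alternative=True``
    scales down the corrected distance variance instead
    (``9(pi-2)(p-1)/(4 pi)``), which overstates the single-ROI
    cross-covariance.
    """
    p = _check_p(p)
    mean = 2.0 * (p - 1) / math.sqrt(_PI)
    if alternative:
        var = 9.0 * (_PI - 2.0) * (p - 1) / (4.0 * _PI)
    else:
        var = 2.0 * (_PI - 2.0) * (p - 1) / _PI
    return DiffMoments(mu_z=mean, sigma2_z=var, q=1, data_model="fmri")


def fmri_maxmin_moments(m: int, p: int) -> MomentSummary:
    """Moments of the range-normalized stack distance.

    Each ROI's range is taken over its block's m(p-1) approximately standard
    normal values, so the normal extreme-value formulas apply with effective
    sample size n = m(p-1):

        mean = mu_D / (2 mu~max(n))
        var  = 6 sigma2_D log n / (pi^2 + 24 mu~max(n)^2 log n)

    with (mu_D, sigma2_D) the corrected un-normalized moments.
    """
    p = _check_p(p)
    n = int(m) * (p - 1)
    if n < 2:
        raise ValueError("need m(p-1) >= 2")
    base = fmri_distance_moments(p, corrected=True)
    _, mu_max, _ = normal_max_stats(n)
    logn = math.log(n)
    mean = base.mean / (2.0 * mu_max)
    variance = 6.0 * base.variance * logn / (_PI**2 + 24.0 * mu_max**2 * logn)
    return MomentSummary(
        mean=mean,
        variance=variance,
        family="normal",
        params={"metric": "fmri_maxmin", "p": p, "m": int(m)},
    )


def fit_variance_correction(
    p_grid: Sequence[int],
    m: int = 100,
    replicates: int = 20,
    seed: Optional[int] = None,
    T_factor: int = 4,
) -> CorrectionFit:
    """Refit the variance-discrepancy coefficients on simulated null stacks.

    For each p in ``p_grid``, generates ``replicates`` null stacks
    (independent Gaussian time series of length ``T_factor * p`` per
    subject), computes the within-dataset sample variance of the m(m-1)/2
    pairwise stack distances, averages over replicates, subtracts the
    independence-assumption variance 2p(pi-2)(p-1)/pi, and regresses the
    discrepancy on (p^2, p) without intercept.
    """
    from .distances import fmri_distance_matrix
    from .synthetic_data import gen_fmri_stack

    p_grid = np.asarray(sorted(int(p) for p in p_grid))
    if p_grid.size < 3:
        raise ValueError("need at least 3 grid points to fit two coefficients")
    if replicates < 5:
        raise ValueError("need at least 5 replicates per grid point")
    rng = np.random.default_rng(seed)
    disc = np.empty(p_grid.size)
    for idx, p in enumerate(p_grid):
        variances = []
        for _ in range(replicates):
            stack = gen_fmri_stack(m, int(p), T=T_factor * int(p),
                                   seed=int(rng.integers(2**31)))
            d = fmri_distance_matrix(stack).condensed()
            variances.append(d.var(ddof=1))
        naive = 2.0 * (_PI - 2.0) * p * (p - 1) / _PI
        disc[idx] = float(np.mean(variances)) - naive
    design = np.column_stack([p_grid.astype(float) ** 2, p_grid.astype(float)])
    if np.linalg.matrix_rank(design) < 2:
        raise np.linalg.LinAlgError("singular design matrix")
    beta, res, *_ = np.linalg.lstsq(design, disc, rcond=None)
    residual = float(res[0]) if res.size else 0.0
    return CorrectionFit(
        beta0=float(beta[1]),
        beta1=float(beta[0]),
        p_grid=p_grid,
        discrepancies=disc,
        replicates=int(replicates),
        m=int(m),
        seed=seed,
        residual=residual,
    )
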