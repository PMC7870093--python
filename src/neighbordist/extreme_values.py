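"""Sample-extreme distributions and moments of range-normalized L_q distances.

Range (max-min) normalization divides every attribute diff by that
attribute's observed range over the m instances, so the moments of the
normalized distance involve the moments of sample extremes.  For a sample of
size m with cdf F and density f:

    F_max(x) = F(x)^m            f_max(x) = m F(x)^(m-1) f(x)
    F_min(x) = 1 - (1-F(x))^m    f_min(x) = m (1-F(x))^(m-1) f(x)

For standard normal data the sample maximum is asymptotically Gumbel; the
median of that limit, ``log(log 2)/Phi^-1(1/m) - Phi^-1(1/m)``, estimates the
expected maximum more accurately than the Gumbel mean and is the default
here.  For standard uniform data the extreme moments are exact beta moments.

The normalized-distance moments then follow by treating the attribute range
as approximately independent of the numerator distance:

    normal:  mean = mu_D / (2 mu~max),
             var  = 6 sigma2_D log m / (pi^2 + 24 mu~max^2 log m)
    uniform: mean = (m+1) mu_D / (m-1),
             var  = (m+2)(m+1)^2 sigma2_D / (m^3 - m + 2)

where (mu_D, sigma2_D) are the un-normalized L_q moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy import integrate
from scipy.stats import norm

from ._types import ExtremeMoments, MomentSummary
from .continuous_moments import lq_distance_moments

__all__ = [
    "ExtremeDistributions",
    "extreme_distributions",
    "extreme_moments_numeric",
    "normal_max_stats",
    "normal_range_moments",
    "uniform_extreme_moments",
    "maxmin_lq_moments",
]

#: Euler-Mascheroni constant (double precision, from numpy).
EULER_GAMMA = float(np.euler_gamma)


@dataclass
class ExtremeDistributions:
    """cdf/pdf callables for the maximum and minimum of an iid sample."""

    cdf_max: Callable[[np.ndarray], np.ndarray]
    pdf_max: Callable[[np.ndarray], np.ndarray]
    cdf_min: Callable[[np.ndarray], np.ndarray]
    pdf_min: Callable[[np.ndarray], np.ndarray]
    m: int


def extreme_distributions(
    FX: Callable, fX: Callable, m: int
) -> ExtremeDistributions:
    """Exact distributions of the max and min of an iid sample of size m."""
    m = int(m)
    if m < 1:
        raise ValueError("m must be >= 1")

    def cdf_max(x):
        return np.asarray(FX(x)) ** m

    def pdf_max(x):
        return m * np.asarray(FX(x)) ** (m - 1) * np.asarray(fX(x))

    def cdf_min(x):
        return 1.0 - (1.0 - np.asarray(FX(x))) ** m

    def pdf_min(x):
        return m * (1.0 - np.asarray(FX(x))) ** (m - 1) * np.asarray(fX(x))

    return ExtremeDistributions(cdf_max, pdf_max, cdf_min, pdf_min, m)


def extreme_moments_numeric(
    FX: Callable,
    fX: Callable,
    m: int,
    support: Tuple[float, float] = (-np.inf, np.inf),
    data_model: str = "custom",
) -> ExtremeMoments:
    """First two raw moments of the sample max and min by adaptive quadrature."""
    dists = extreme_distributions(FX, fX, m)

    def moment(pdf, k):
        val, err = integrate.quad(
            lambda x: x**k * pdf(x), support[0], support[1], epsabs=1e-10, limit=200
        )
        if not np.isfinite(val):
            raise RuntimeError(f"quadrature failed for extreme moment k={k}")
        return val

    return ExtremeMoments(
        mu_max1=moment(dists.pdf_max, 1),
        mu_max2=moment(dists.pdf_max, 2),
        mu_min1=moment(dists.pdf_min, 1),
        mu_min2=moment(dists.pdf_min, 2),
        m=int(m),
        data_model=data_model,
    )


def normal_max_stats(m: int) -> Tuple[float, float, float]:
    """Gumbel-limit (mean, median, variance) of the max of m standard normals.

    mean   = -Phi^-1(1/m) - gamma/Phi^-1(1/m)   (gamma = Euler-Mascheroni)
    median = log(log 2)/Phi^-1(1/m) - Phi^-1(1/m)
    var    = pi^2 / (12 log m)

    The median is the empirically more accurate estimate of the expected
    sample maximum and is what the range-normalized moment formulas use.
    """
    m = int(m)
    if m < 2:
        raise ValueError("m must be >= 2")
    c = norm.ppf(1.0 / m)  # negative
    mean = -c - EULER_GAMMA / c
    median = math.log(math.log(2.0)) / c - c
    variance = math.pi**2 / (12.0 * math.log(m))
    return mean, median, variance


def normal_range_moments(m: int, use_gumbel_mean: bool = False) -> Tuple[float, float]:
    """(mean, variance) of the range of m iid standard normals.

    By symmetry the expected range is twice the expected maximum; the
    default estimates the expected maximum by the Gumbel-limit median (see
    :func:`normal_max_stats`), with the Gumbel mean available by flag.  The
    variance uses the large-m independence of the two extremes:
    ``pi^2/(6 log m)``.
    """
    mean_g, median, _ = normal_max_stats(m)
    mu_max = mean_g if use_gumbel_mean else median
    return 2.0 * mu_max, math.pi**2 / (6.0 * math.log(m))


def uniform_extreme_moments(m: int) -> Tuple[ExtremeMoments, float]:
    """Closed-form extreme moments for standard uniform data, plus E[range^2].

    E max = m/(m+1), E min = 1/(m+1), E[max^2] = m/(m+2),
    E[min^2] = 2/((m+1)(m+2)), and

        E[(max - min)^2] = (m^3 - m + 2) / ((m+2)(m+1)^2)

    The E[range^2] form embeds the approximation E[max*min] ~ E[max]E[min],
    which is only accurate for m not too small (exact value at m=2 differs);
    hence the m >= 2 requirement.
    """
    m = int(m)
    if m < 2:
        raise ValueError("m must be >= 2")
    em = ExtremeMoments(
        mu_max1=m / (m + 1.0),
        mu_max2=m / (m + 2.0),
        mu_min1=1.0 / (m + 1.0),
        mu_min2=2.0 / ((m + 1.0) * (m + 2.0)),
        m=m,
        data_model="uniform",
    )
    range2 = (m**3 - m + 2.0) / ((m + 2.0) * (m + 1.0) ** 2)
    return em, range2


def maxmin_lq_moments(
    p: int,
    q: int,
    m: int,
    data_model: str,
    improved: bool | None = None,
) -> MomentSummary:
    """Asymptotic moments of the range-normalized L_q distance.

    Combines the un-normalized L_q moments (:func:`lq_distance_moments`) with
    the extreme-value range moments for the given data model.  As m grows the
    uniform-model moments converge to the un-normalized ones (the range tends
    to 1), while for normal data the variance vanishes like 1/log m.
    """
    m = int(m)
    if m < 2:
        raise ValueError("m must be >= 2")
    base = lq_distance_moments(p, q, data_model, improved)
    mu_d, var_d = base.mean, base.variance
    if data_model == "normal":
        _, mu_max, _ = normal_max_stats(m)
        logm = math.log(m)
        mean = mu_d / (2.0 * mu_max)
        variance = 6.0 * var_d * logm / (math.pi**2 + 24.0 * mu_max**2 * logm)
    elif data_model == "uniform":
        mean = (m + 1.0) * mu_d / (m - 1.0)
        variance = (m + 2.0) * (m + 1.0) ** 2 * var_d / (m**3 - m + 2.0)
    else:
        raise ValueError(f"unknown data model: {data_model!r}")
    params = dict(base.params)
    params.update({"normalized": True, "m": m})
    return MomentSummary(mean=mean, variance=variance, family="normal", params=params)
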