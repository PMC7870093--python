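"""Analytic moments and diff pmfs for the GM, AM and TiTv genotype metrics.

Genotypes are modeled as minor-allele counts ``X ~ Binomial(2, f_a)`` with
independent loci, so every diff metric has a finite pmf in the minor allele
frequency f_a — and, for TiTv, in the locus-encoding probabilities
``gamma0 = P(PuPu)``, ``gamma1 = P(PuPy)``, ``gamma2 = P(PyPy)`` constrained
by the transition/transversion ratio eta = P(Ti)/P(Tv):

    gamma1 = 1/(eta+1),   gamma0 + gamma2 = eta/(eta+1).

Two polynomial building blocks recur throughout (writing f for f_a):

    F_TiTv(f) = (1-f)^3 f + f^3 (1-f)      # prob weight of |diff| = 1 pairs
    G_TiTv(f) = f^2 (1-f)^2                # prob weight of |diff| = 2 pairs

Distance moments over p independent loci are the per-locus sums.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ._types import DiffMoments, EncodingModel, GenotypeData, GwasDiffPmf, MomentSummary

__all__ = [
    "estimate_maf",
    "encoding_gammas",
    "expected_gammas",
    "gwas_diff_pmf",
    "gwas_diff_moments",
    "gwas_distance_moments",
    "titv_mean_curve",
]


def estimate_maf(G: GenotypeData | np.ndarray) -> np.ndarray:
    """Per-locus minor allele frequency estimate: allele count over 2m."""
    X = G.genotypes if isinstance(G, GenotypeData) else np.asarray(G)
    return X.sum(axis=0) / (2.0 * X.shape[0])


def encoding_gammas(
    eta: float, epsilon: float = 0.01, seed: Optional[int] = None
) -> EncodingModel:
    """Sample an encoding model consistent with Ti/Tv ratio ``eta``.

    gamma1 is pinned at 1/(eta+1); gamma0 is drawn uniformly on
    (epsilon, eta/(eta+1) - epsilon) and gamma2 takes the remainder, so the
    PuPu/PyPy split is arbitrary while P(Ti) = eta/(eta+1) is exact.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    p_ti = eta / (eta + 1.0)
    if not 0 < epsilon < p_ti / 2.0:
        raise ValueError(
            f"epsilon must lie in (0, {p_ti / 2.0}) for eta={eta}"
        )
    rng = np.random.default_rng(seed)
    gamma0 = float(rng.uniform(epsilon, p_ti - epsilon))
    return EncodingModel(
        eta=float(eta),
        gamma0=gamma0,
        gamma1=1.0 / (eta + 1.0),
        gamma2=p_ti - gamma0,
        epsilon=float(epsilon),
    )


def expected_gammas(eta: float) -> EncodingModel:
    """The expected encoding model: the transition mass split evenly.

    Every moment formula below depends on the gammas only through gamma1 and
    gamma0 + gamma2, so the even split is a canonical representative for
    theoretical curves.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    p_ti = eta / (eta + 1.0)
    return EncodingModel(
        eta=float(eta), gamma0=p_ti / 2.0, gamma1=1.0 / (eta + 1.0), gamma2=p_ti / 2.0
    )


def _f_titv(f: np.ndarray) -> np.ndarray:
    return (1 - f) ** 3 * f + f**3 * (1 - f)


def _g_titv(f: np.ndarray) -> np.ndarray:
    return f**2 * (1 - f) ** 2


def _check_f(f: float) -> float:
    f = float(f)
    if not 0 < f < 1:
        raise ValueError("minor allele frequency must lie in (0, 1)")
    return f


def gwas_diff_pmf(
    metric: str, f: float, enc: Optional[EncodingModel] = None
) -> GwasDiffPmf:
    """Exact pmf of a single-locus diff under Binomial(2, f) genotypes.

    GM has support {0, 1}; AM {0, 1/2, 1}; TiTv {0, 1/4, 1/2, 3/4, 1} with
    the mismatch mass split between transition and transversion values
    according to the encoding probabilities.
    """
    f = _check_f(f)
    p0 = (1 - f) ** 4 + 4 * f**2 * (1 - f) ** 2 + f**4  # P(equal genotypes)
    ft, gt = _f_titv(f), _g_titv(f)
    if metric == "gm":
        support = [0.0, 1.0]
        probs = [p0, 4 * ft + 2 * gt]
    elif metric == "am":
        support = [0.0, 0.5, 1.0]
        probs = [p0, 4 * ft, 2 * gt]
    elif metric == "titv":
        if enc is None:
            raise ValueError("titv pmf requires an EncodingModel")
        ti, tv = enc.p_transition, enc.p_transversion
        support = [0.0, 0.25, 0.5, 0.75, 1.0]
        probs = [p0, 4 * ti * ft, 4 * tv * ft, 2 * ti * gt, 2 * tv * gt]
    else:
        raise ValueError(f"unknown GWAS metric: {metric!r}")
    return GwasDiffPmf(
        support=np.array(support), probabilities=np.array(probs), metric=metric, f=f
    )


def gwas_diff_moments(
    metric: str, f: float, enc: Optional[EncodingModel] = None
) -> DiffMoments:
    """Closed-form mean/variance of a single-locus diff.

    GM:   mean 2F_GM, var 2F_GM(1 - 2F_GM) with F_GM = 2F_TiTv + G_TiTv.
    AM:   mean 2F_AM, var G_AM - 4F_AM^2 with F_AM = F_TiTv + G_TiTv and
          G_AM = F_TiTv + 2G_TiTv.
    TiTv: mean (ti + 2 tv)F_TiTv + (3ti/2 + 2tv)G_TiTv and the matching
          second-moment form, with ti = gamma0+gamma2, tv = gamma1.
    """
    f = _check_f(f)
    ft, gt = _f_titv(f), _g_titv(f)
    if metric == "gm":
        F = 2 * ft + gt
        mean = 2 * F
        var = 2 * F * (1 - 2 * F)
    elif metric == "am":
        F = ft + gt
        Gm2 = ft + 2 * gt
        mean = 2 * F
        var = Gm2 - 4 * F**2
    elif metric == "titv":
        if enc is None:
            raise ValueError("titv moments require an EncodingModel")
        ti, tv = enc.p_transition, enc.p_transversion
        mean = (ti + 2 * tv) * ft + (1.5 * ti + 2 * tv) * gt
        second = (0.25 * ti + tv) * ft + (1.125 * ti + 2 * tv) * gt
        var = second - mean**2
    else:
        raise ValueError(f"unknown GWAS metric: {metric!r}")
    return DiffMoments(mu_z=float(mean), sigma2_z=float(var), q=1, data_model="gwas")


def gwas_distance_moments(
    metric: str,
    maf: np.ndarray,
    enc: Optional[EncodingModel] = None,
) -> MomentSummary:
    """Asymptotic (normal-limit) moments of a GWAS distance over independent loci.

    Mean and variance are the sums of the per-locus diff moments; the
    cross-locus covariance terms cancel exactly under independence.
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if maf.size < 1:
        raise ValueError("need at least one locus")
    mean = 0.0
    var = 0.0
    for f in maf:
        dm = gwas_diff_moments(metric, f, enc)
        mean += dm.mu_z
        var += dm.sigma2_z
    params = {"metric": metric, "p": int(maf.size)}
    if enc is not None:
        params["eta"] = enc.eta
    return MomentSummary(mean=mean, variance=var, family="normal", params=params)


def titv_mean_curve(
    fbar_grid: np.ndarray, eta: float, p: int = 100
) -> Tuple[np.ndarray, float]:
    """Predicted mean TiTv distance versus average minor allele frequency.

    Evaluates the closed-form expected TiTv distance with all p per-locus
    MAFs set to the common value f-bar, using the expected encoding model for
    ``eta``.  Returns the curve and the grid argmax.  The curve is symmetric
    about f-bar = 0.5 (the point where minor and major allele are equally
    frequent), vanishes at both ends, and decreases in eta at fixed f-bar
    because transversions carry larger diff values than transitions.
    """
    grid = np.asarray(fbar_grid, dtype=float)
    if ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("fbar grid values must lie in (0, 1)")
    enc = expected_gammas(eta)
    ti, tv = enc.p_transition, enc.p_transversion
    curve = p * (
        (ti + 2 * tv) * _f_titv(grid) + (1.5 * ti + 2 * tv) * _g_titv(grid)
    )
    return curve, float(grid[int(np.argmax(curve))])
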