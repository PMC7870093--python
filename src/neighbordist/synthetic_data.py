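"""Seeded generators for the null and correlated data models the theory assumes.

Null models
-----------
* continuous: iid N(0,1) or U(0,1) matrices;
* GWAS: Binomial(2, f_a) minor-allele counts with f_a ~ U(l, u) and per-locus
  PuPu/PuPy/PyPy encodings drawn under a Ti/Tv-ratio constraint;
* correlation stacks: per-subject correlation matrices of independent
  Gaussian time series, Fisher r-to-z transformed, column-standardized, and
  stacked so each ROI's block holds its correlations with every other ROI.

Correlated variants impose a target correlation structure built from a
random (Erdős–Rényi) graph through a Cholesky factor; the GWAS variant pushes
the correlated Gaussians through the normal cdf and inverse binomial cdf so
the genotype margins are preserved while rank correlation carries over.

All generators are deterministic functions of (seed, parameters).
"""

from __future__ import annotations

from typing import Optional, Tuple

import networkx as nx
import numpy as np
from scipy import linalg
from scipy.stats import binom, norm

from ._types import (
    VALID_ENCODINGS,
    ContinuousMatrix,
    CorrelationStack,
    CorrelationTarget,
    EncodingModel,
    GenotypeData,
)
from .gwas_moments import encoding_gammas

__all__ = [
    "gen_continuous",
    "gen_gwas",
    "gen_fmri_stack",
    "build_stack",
    "random_structured_correlation",
    "impose_correlation",
    "gaussian_to_binomial",
    "mean_abs_correlation",
    "gen_feature_selection_benchmark",
]

#: Fisher z of correlations with |r| at or above this bound is clamped; only
#: reachable for degenerate inputs since stacks exclude the diagonal.
FISHER_Z_CLAMP = 0.999999


def gen_continuous(
    m: int, p: int, data_model: str = "normal", seed: Optional[int] = None
) -> ContinuousMatrix:
    """iid data matrix of shape (m, p) from the standard normal or uniform model."""
    rng = np.random.default_rng(seed)
    if data_model == "normal":
        values = rng.standard_normal((m, p))
    elif data_model == "uniform":
        values = rng.random((m, p))
    else:
        raise ValueError(f"unknown data model: {data_model!r}")
    return ContinuousMatrix(values)


def gen_gwas(
    m: int,
    p: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    eta: float = 2.0,
    epsilon: float = 0.01,
    seed: Optional[int] = None,
) -> GenotypeData:
    """Null GWAS data: Binomial(2, f_a) genotypes with annotated loci.

    Per-locus minor allele frequencies are iid U(maf_low, maf_high); locus
    encodings are iid over {PuPu, PuPy, PyPy} with probabilities
    (gamma0, gamma1, gamma2) sampled once per call under the Ti/Tv ratio
    ``eta`` (so the expected fraction of transversion loci is 1/(eta+1)).
    """
    if not 0 < maf_low < maf_high < 1:
        raise ValueError("need 0 < maf_low < maf_high < 1")
    rng = np.random.default_rng(seed)
    enc_model = encoding_gammas(eta, epsilon, seed=rng.integers(2**31))
    maf = rng.uniform(maf_low, maf_high, size=p)
    genotypes = rng.binomial(2, maf, size=(m, p))
    probs = [enc_model.gamma0, enc_model.gamma1, enc_model.gamma2]
    encoding = rng.choice(np.array(VALID_ENCODINGS, dtype=object), size=p, p=probs)
    return GenotypeData(
        genotypes=genotypes,
        maf=maf,
        encoding=encoding,
        encoding_model=enc_model,
        maf_source="sampled",
    )


def build_stack(matrices: np.ndarray, standardize: bool = True) -> CorrelationStack:
    """Assemble a stack from m per-subject p x p symmetric correlation matrices.

    Off-diagonal entries are Fisher r-to-z transformed and laid out so ROI
    ``a``'s block (rows a(p-1)..(a+1)(p-1)-1, 0-based) holds its correlations
    with every other ROI; symmetry of the input means each unordered ROI pair
    appears twice per column.  Columns are then standardized to zero mean and
    unit variance.
    """
    matrices = np.asarray(matrices, dtype=float)
    if matrices.ndim != 3 or matrices.shape[1] != matrices.shape[2]:
        raise ValueError("expected an (m, p, p) array of correlation matrices")
    m, p, _ = matrices.shape
    mask = ~np.eye(p, dtype=bool)
    # row-major masked read == ROI-block layout: row a contributes its p-1
    # off-diagonal correlations as block a
    flat = matrices[:, mask].T  # (p(p-1), m)
    flat = np.clip(flat, -FISHER_Z_CLAMP, FISHER_Z_CLAMP)
    z = np.arctanh(flat)
    if standardize:
        z = (z - z.mean(axis=0)) / z.std(axis=0)
    return CorrelationStack(values=z, p=p, standardized=standardize)


def gen_fmri_stack(
    m: int, p: int, T: Optional[int] = None, seed: Optional[int] = None
) -> CorrelationStack:
    """Null correlation stack from independent Gaussian time series.

    Each subject gets p independent time series of length T (default 4p);
    their sample correlation matrix feeds :func:`build_stack`.  The Fisher-z
    entries are then approximately normal and column standardization makes
    them approximately standard normal, which is the regime the stack-metric
    moment formulas assume.
    """
    if p < 2 or m < 2:
        raise ValueError("need m >= 2 subjects and p >= 2 ROIs")
    if T is None:
        T = 4 * p
    rng = np.random.default_rng(seed)
    mats = np.empty((m, p, p))
    for i in range(m):
        ts = rng.standard_normal((T, p))
        mats[i] = np.corrcoef(ts, rowvar=False)
    return build_stack(mats)


def _repair_positive_definite(A: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at a small floor and renormalize to unit diagonal."""
    w, V = np.linalg.eigh(A)
    w = np.clip(w, floor, None)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    B = B / np.outer(d, d)
    np.fill_diagonal(B, 1.0)
    return (B + B.T) / 2.0


def random_structured_correlation(
    p: int,
    connection_prob: float,
    hi: float = 0.8,
    lo: float = 0.0,
    seed: Optional[int] = None,
) -> CorrelationTarget:
    """Random-graph correlation target: ``hi`` on edges, ``lo`` elsewhere.

    Vertices are attributes; an Erdős–Rényi graph with the given connection
    probability decides which pairs get the high correlation.  The raw
    matrix is generally indefinite, so it is repaired to a nearby
    positive-definite correlation matrix by eigenvalue clipping followed by
    unit-diagonal renormalization — dense high-correlation targets are
    therefore attenuated, and the achieved mean absolute correlation should
    be measured on the output rather than assumed.
    """
    if not (abs(hi) < 1 and abs(lo) < 1):
        raise ValueError("|hi| and |lo| must be < 1")
    rng = np.random.default_rng(seed)
    A = np.full((p, p), float(lo))
    graph = nx.fast_gnp_random_graph(p, connection_prob, seed=int(rng.integers(2**31)))
    for u, v in graph.edges():
        A[u, v] = A[v, u] = hi
    np.fill_diagonal(A, 1.0)
    R = _repair_positive_definite(A)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise RuntimeError("positive-definiteness repair failed")
    return CorrelationTarget(
        matrix=R,
        source="random_graph",
        connection_prob=float(connection_prob),
        hi_value=float(hi),
        lo_value=float(lo),
    )


def impose_correlation(
    X: ContinuousMatrix | np.ndarray, R: CorrelationTarget | np.ndarray
) -> ContinuousMatrix:
    """Impose a target correlation on iid standard normal columns.

    Multiplies by the upper-triangular Cholesky factor U with U'U = R, so the
    output rows have covariance R and sample attribute correlations approach
    the target for large m.
    """
    if isinstance(X, np.ndarray):
        X = ContinuousMatrix(X)
    Rm = R.matrix if isinstance(R, CorrelationTarget) else np.asarray(R, dtype=float)
    if Rm.shape != (X.p, X.p):
        raise ValueError(f"target is {Rm.shape}, data has p={X.p} attributes")
    U = linalg.cholesky(Rm, lower=False)  # U'U = R
    return ContinuousMatrix(X.values @ U)


def gaussian_to_binomial(
    Xcorr: ContinuousMatrix | np.ndarray,
    maf: np.ndarray,
    enc_model: Optional[EncodingModel] = None,
    seed: Optional[int] = None,
) -> GenotypeData:
    """Map (possibly correlated) standard normal margins to Binomial(2, f) genotypes.

    Applies the standard normal cdf then the inverse binomial cdf with two
    trials per attribute, preserving rank correlation structure while giving
    each locus the requested minor allele frequency margin.  When an
    encoding model is supplied, per-locus encodings are drawn from it so the
    result supports the TiTv metric.
    """
    if isinstance(Xcorr, np.ndarray):
        Xcorr = ContinuousMatrix(Xcorr)
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (Xcorr.p,):
        raise ValueError("need one minor allele frequency per attribute")
    u = norm.cdf(Xcorr.values)
    genotypes = binom.ppf(u, 2, maf).astype(int)
    encoding = None
    if enc_model is not None:
        rng = np.random.default_rng(seed)
        probs = [enc_model.gamma0, enc_model.gamma1, enc_model.gamma2]
        encoding = rng.choice(
            np.array(VALID_ENCODINGS, dtype=object), size=Xcorr.p, p=probs
        )
    return GenotypeData(
        genotypes=genotypes,
        maf=maf,
        encoding=encoding,
        encoding_model=enc_model,
        maf_source="supplied",
    )


def mean_abs_correlation(X: ContinuousMatrix | np.ndarray) -> float:
    """Average absolute pairwise attribute correlation, r-bar-abs.

    The package's dial for how far a dataset departs from the independent-
    attribute null.  Constant attributes (undefined correlation) are excluded
    with a warning.
    """
    values = X.values if isinstance(X, ContinuousMatrix) else np.asarray(X, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least two attributes")
    sd = values.std(axis=0)
    if (sd == 0).any():
        import warnings

        warnings.warn(
            f"excluding {int((sd == 0).sum())} constant attribute(s) from "
            "mean absolute correlation",
            stacklevel=2,
        )
        values = values[:, sd > 0]
        if values.shape[1] < 2:
            raise ValueError("fewer than two non-constant attributes")
    C = np.corrcoef(values, rowvar=False)
    iu = np.triu_indices(C.shape[0], 1)
    return float(np.abs(C[iu]).mean())


def gen_feature_selection_benchmark(
    m: int = 100,
    p: int = 1000,
    n_functional: int = 100,
    effect: str = "mixed",
    seed: Optional[int] = None,
    main_shift: float = 0.8,
    interaction_corr: float = 0.75,
) -> Tuple[ContinuousMatrix, np.ndarray, np.ndarray]:
    """Synthetic case/control benchmark for nearest-neighbor feature selection.

    A documented surrogate for interaction-network simulators: functional
    attributes carry either a between-group mean shift (``main``), a
    group-differential pairwise correlation with zero marginal mean shift
    (``interaction``), or an even split (``mixed``).  Null attributes are iid
    N(0,1).  Returns (data, binary outcome, functional-attribute mask) with
    balanced classes.
    """
    if n_functional >= p:
        raise ValueError("n_functional must be smaller than p")
    if m % 2:
        raise ValueError("m must be even for balanced classes")
    if effect not in ("main", "interaction", "mixed"):
        raise ValueError(f"unknown effect type: {effect!r}")
    rng = np.random.default_rng(seed)
    half = m // 2
    y = np.repeat([0, 1], half)
    X = rng.standard_normal((m, p))
    mask = np.zeros(p, dtype=bool)
    functional = np.arange(n_functional)
    mask[functional] = True

    if effect == "main":
        n_main, n_int = n_functional, 0
    elif effect == "interaction":
        n_main, n_int = 0, n_functional
    else:
        n_main = n_functional // 2
        n_int = n_functional - n_main
    main_idx = functional[:n_main]
    int_idx = functional[n_main:]

    if n_main:
        X[y == 1][:, main_idx]  # noqa: B018 — readability anchor for the shift below
        X[np.ix_(y == 1, main_idx)] += main_shift
    if n_int:
        # equicorrelated block in cases only; controls keep iid columns, so
        # the marginal group means are equal but the pairwise correlation
        # differs between groups
        R = np.full((n_int, n_int), interaction_corr)
        np.fill_diagonal(R, 1.0)
        U = linalg.cholesky(R, lower=False)
        X[np.ix_(y == 1, int_idx)] = rng.standard_normal((half, n_int)) @ U
    return ContinuousMatrix(X), y, mask
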