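"""Pairwise-distance metrics and their one-attribute projections (diffs).

Every metric here decomposes as a sum (or q-th-root of a sum) of per-attribute
"diff" terms ``d_ij(a)``, the one-dimensional projection of the distance onto
attribute ``a``.  Nearest-neighbor feature selection methods (Relief, NPDR)
score attributes through these projections, so both the full matrices and the
projections are exposed.

Metrics
-------
* L_q on continuous data, optionally range (max-min) normalized per attribute
  — the Relief convention that bounds attribute scores.
* GM / AM / TiTv on genotype data: genotype mismatch, allele mismatch, and a
  transition/transversion-weighted mismatch with support {0, 1/4, 1/2, 3/4, 1}.
* An ROI-level metric for stacked correlation data (e.g. resting-state fMRI
  connectivity): the Manhattan distance over each ROI's block of Fisher-z
  correlations with every other ROI.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._types import (
    TRANSITION_ENCODINGS,
    ContinuousMatrix,
    CorrelationStack,
    DistanceMatrix,
    GenotypeData,
    MetricSpec,
)

__all__ = [
    "lq_distance_matrix",
    "attribute_diff",
    "gwas_diff",
    "gwas_distance_matrix",
    "fmri_roi_diff",
    "fmri_distance_matrix",
    "roi_block_indices",
]


def _range_normalize(values: np.ndarray, on_degenerate: str) -> np.ndarray:
    """Divide each column by its observed range, handling zero-range columns.

    ``on_degenerate`` is "error" (default policy) or "drop" (remove the
    offending attributes with a warning).
    """
    rng = values.max(axis=0) - values.min(axis=0)
    degenerate = rng == 0
    if degenerate.any():
        if on_degenerate == "drop":
            warnings.warn(
                f"dropping {int(degenerate.sum())} constant attribute(s) "
                "under range normalization",
                stacklevel=3,
            )
            values = values[:, ~degenerate]
            rng = rng[~degenerate]
            if values.shape[1] == 0:
                raise ValueError("all attributes are constant; nothing to normalize")
        else:
            idx = np.flatnonzero(degenerate)
            raise ValueError(
                f"constant attribute(s) {idx.tolist()} have zero range; "
                "range normalization undefined (pass on_degenerate='drop' to skip them)"
            )
    return values / rng


def lq_distance_matrix(
    X: ContinuousMatrix | np.ndarray,
    q: int = 1,
    normalized: bool = False,
    on_degenerate: str = "error",
) -> DistanceMatrix:
    """All-pairs L_q distance ``(sum_a |X_ia - X_ja|^q)^(1/q)``.

    With ``normalized=True`` each attribute difference is divided by that
    attribute's observed max - min before summation (Relief's range
    normalization).

    Parameters
    ----------
    X
        Data with m >= 2 instances as rows.
    q
        Metric order; 1 is Manhattan, 2 Euclidean.
    normalized
        Apply per-attribute range normalization.
    on_degenerate
        Policy for zero-range attributes under normalization: "error" or
        "drop".
    """
    if isinstance(X, np.ndarray):
        X = ContinuousMatrix(X)
    q = int(q)
    if q < 1:
        raise ValueError("q must be a positive integer")
    values = X.values
    if normalized:
        values = _range_normalize(values, on_degenerate)
    if q == 1:
        d = pdist(values, metric="cityblock")
    elif q == 2:
        d = pdist(values, metric="euclidean")
    else:
        d = pdist(values, metric="minkowski", p=q)
    family = "lq_maxmin" if normalized else "lq"
    return DistanceMatrix(squareform(d), MetricSpec(family, q=q))


def attribute_diff(
    X: ContinuousMatrix | np.ndarray,
    a: int,
    normalized: bool = False,
) -> np.ndarray:
    """Projection ``|X_ia - X_ja|`` over all m(m-1)/2 unordered pairs.

    Returned in scipy condensed (pdist) pair order.  When ``normalized`` the
    values are divided by the attribute's range and hence lie in [0, 1].
    """
    if isinstance(X, np.ndarray):
        X = ContinuousMatrix(X)
    if not 0 <= a < X.p:
        raise IndexError(f"attribute index {a} out of range for p={X.p}")
    col = X.values[:, a : a + 1]
    d = pdist(col, metric="cityblock")
    if normalized:
        rng = col.max() - col.min()
        if rng == 0:
            raise ValueError(f"attribute {a} is constant; range normalization undefined")
        d = d / rng
    return d


# TiTv diff table: |genotype difference| -> value, split by substitution type.
_TITV_TI = {0: 0.0, 1: 0.25, 2: 0.75}
_TITV_TV = {0: 0.0, 1: 0.5, 2: 1.0}


def gwas_diff(
    gi: int,
    gj: int,
    metric: str,
    locus_encoding: Optional[str] = None,
) -> float:
    """Single-locus genotype diff for the GM, AM or TiTv metric.

    GM scores any genotype mismatch as 1.  AM is half the absolute
    minor-allele-count difference (support {0, 1/2, 1}).  TiTv weights the
    mismatch by whether the locus substitution is a transition (PuPu/PyPy
    encodings) or the more disruptive transversion (PuPy):
    {1/4, 3/4} for Ti and {1/2, 1} for Tv at |diff| 1 and 2.
    """
    if gi not in (0, 1, 2) or gj not in (0, 1, 2):
        raise ValueError("genotype values must be in {0, 1, 2}")
    delta = abs(int(gi) - int(gj))
    if metric == "gm":
        return float(delta != 0)
    if metric == "am":
        return delta / 2.0
    if metric == "titv":
        if locus_encoding is None:
            raise ValueError("titv metric requires a locus encoding")
        if locus_encoding in TRANSITION_ENCODINGS:
            return _TITV_TI[delta]
        if locus_encoding == "PuPy":
            return _TITV_TV[delta]
        raise ValueError(f"invalid locus encoding: {locus_encoding!r}")
    raise ValueError(f"unknown GWAS metric: {metric!r}")


def gwas_distance_matrix(G: GenotypeData, metric: str) -> DistanceMatrix:
    """All-pairs genotype distance: the per-locus diffs summed over loci.

    The TiTv sum is computed as ``sum_a |delta_a|/2 - (1/4) * #{mismatching
    transition loci}``, which reproduces the diff table exactly (Ti values sit
    1/4 below the Tv values at both mismatch levels).
    """
    X = G.genotypes.astype(float)
    m = G.m
    if metric == "gm":
        # hamming gives the *fraction* of mismatching loci
        d = pdist(X, metric="hamming") * G.p
    elif metric == "am":
        d = pdist(X, metric="cityblock") / 2.0
    elif metric == "titv":
        if G.encoding is None:
            raise ValueError("titv metric requires locus encodings")
        is_ti = np.fromiter(
            (e in TRANSITION_ENCODINGS for e in G.encoding), bool, count=G.p
        )
        d = pdist(X, metric="cityblock") / 2.0
        if is_ti.any():
            n_ti = int(is_ti.sum())
            d -= 0.25 * pdist(X[:, is_ti], metric="hamming") * n_ti
    else:
        raise ValueError(f"unknown GWAS metric: {metric!r}")
    return DistanceMatrix(squareform(d), MetricSpec(metric))


def roi_block_indices(k: int, p: int) -> Tuple[int, int]:
    """1-based inclusive row range (start, end) of ROI ``k``'s stack block.

    ROI ``k`` of ``p`` occupies rows ``(k-1)(p-1)+1`` through ``k(p-1)`` of
    the p(p-1)-row stack layout.  Both ``k`` and the returned indices follow
    the documented 1-based convention; see :func:`_roi_block_slice` for the
    0-based internal form.
    """
    if not 1 <= k <= p:
        raise IndexError(f"ROI index {k} out of range 1..{p}")
    return (k - 1) * (p - 1) + 1, k * (p - 1)


def _roi_block_slice(a: int, p: int) -> slice:
    """0-based half-open row slice of ROI ``a`` (0-based) in the stack."""
    if not 0 <= a < p:
        raise IndexError(f"ROI index {a} out of range 0..{p - 1}")
    return slice(a * (p - 1), (a + 1) * (p - 1))


def fmri_roi_diff(S: CorrelationStack, i: int, j: int, a: int) -> float:
    """ROI-level projection: L1 difference of subjects i, j over ROI a's block.

    This is the sum over the p-1 rows of ROI ``a``'s block of the absolute
    difference between subject columns ``i`` and ``j`` (0-based indices).
    """
    if not 0 <= i < S.m or not 0 <= j < S.m:
        raise IndexError("subject index out of bounds")
    block = S.values[_roi_block_slice(a, S.p)]
    return float(np.abs(block[:, i] - block[:, j]).sum())


def fmri_distance_matrix(
    S: CorrelationStack,
    normalized: bool = False,
    on_degenerate: str = "error",
) -> DistanceMatrix:
    """All-pairs stack distance: the ROI diffs summed over ROIs.

    Unnormalized this is exactly the Manhattan distance between subject
    columns.  With ``normalized=True`` each ROI block's diffs are divided by
    that ROI's max - min taken over the block's full m*(p-1) values before
    summation.
    """
    values = S.values
    if normalized:
        scaled = np.empty_like(values)
        for a in range(S.p):
            sl = _roi_block_slice(a, S.p)
            block = values[sl]
            rng = block.max() - block.min()
            if rng == 0:
                if on_degenerate == "drop":
                    warnings.warn(f"dropping zero-range ROI {a}", stacklevel=2)
                    scaled[sl] = 0.0
                    continue
                raise ValueError(f"ROI {a} has zero range; normalization undefined")
            scaled[sl] = block / rng
        values = scaled
    d = pdist(values.T, metric="cityblock")
    family = "fmri_maxmin" if normalized else "fmri"
    return DistanceMatrix(squareform(d), MetricSpec(family))
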