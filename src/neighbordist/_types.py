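"""Core container types shared across the package.

The containers are thin, validated wrappers around numpy arrays.  They exist
so that functions can state their contracts (shape, value ranges, provenance
of a distance matrix) once, at construction time, instead of re-validating in
every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ContinuousMatrix",
    "GenotypeData",
    "CorrelationStack",
    "MetricSpec",
    "DistanceMatrix",
    "DiffMoments",
    "MomentSummary",
    "ExtremeMoments",
    "EncodingModel",
    "GwasDiffPmf",
    "CorrectionFit",
    "CorrelationTarget",
    "NeighborhoodSpec",
]

MetricFamily = Literal["lq", "lq_maxmin", "gm", "am", "titv", "fmri", "fmri_maxmin"]
DataModel = Literal["normal", "uniform", "custom"]
Encoding = Literal["PuPu", "PuPy", "PyPy"]

#: encodings whose allele substitution is a transition (purine<->purine or
#: pyrimidine<->pyrimidine); "PuPy" is a transversion.
TRANSITION_ENCODINGS = frozenset({"PuPu", "PyPy"})
VALID_ENCODINGS = ("PuPu", "PuPy", "PyPy")


@dataclass
class ContinuousMatrix:
    """An instances x attributes real-valued data table.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, p)``; all entries must be finite.
    attribute_names
        Optional attribute labels (length ``p``).
    """

    values: np.ndarray
    attribute_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] < 2:
            raise ValueError("need at least m=2 instances")
        if self.values.shape[1] < 1:
            raise ValueError("need at least p=1 attributes")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite entries in data matrix")
        if self.attribute_names is not None and len(self.attribute_names) != self.p:
            raise ValueError("attribute_names length does not match p")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class EncodingModel:
    """Locus-encoding probability model under a fixed Ti/Tv ratio.

    ``eta`` is the transition/transversion ratio P(Ti)/P(Tv).  ``gamma0``,
    ``gamma1`` and ``gamma2`` are the probabilities of a locus being PuPu,
    PuPy and PyPy respectively; they satisfy ``gamma1 = 1/(eta+1)`` and
    ``gamma0 + gamma2 = eta/(eta+1)``.
    """

    eta: float
    gamma0: float
    gamma1: float
    gamma2: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        g = np.array([self.gamma0, self.gamma1, self.gamma2])
        if (g < -1e-12).any():
            raise ValueError("gamma probabilities must be nonnegative")
        if abs(g.sum() - 1.0) > 1e-9:
            raise ValueError("gamma probabilities must sum to 1")
        if abs(self.gamma1 - 1.0 / (self.eta + 1.0)) > 1e-9:
            raise ValueError("gamma1 must equal 1/(eta+1)")

    @property
    def p_transition(self) -> float:
        return self.gamma0 + self.gamma2

    @property
    def p_transversion(self) -> float:
        return self.gamma1


@dataclass
class GenotypeData:
    """Genotype matrix (minor-allele counts in {0,1,2}) with locus annotation.

    ``maf`` holds per-locus minor allele frequencies f_a in (0,1);
    ``encoding`` holds per-locus nucleotide-pair labels used by the TiTv
    metric.  ``encoding_model`` records the Ti/Tv sampling model when the
    data were simulated.
    """

    genotypes: np.ndarray
    maf: Optional[np.ndarray] = None
    encoding: Optional[np.ndarray] = None
    encoding_model: Optional[EncodingModel] = None
    maf_source: str = "unknown"  # one of: supplied, estimated, sampled, unknown

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype entries must be in {0, 1, 2}")
        self.genotypes = self.genotypes.astype(np.int8)
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (self.p,):
                raise ValueError("maf must have one entry per locus")
            if ((self.maf <= 0) | (self.maf >= 1)).any():
                raise ValueError("maf entries must lie strictly inside (0, 1)")
        if self.encoding is not None:
            self.encoding = np.asarray(self.encoding, dtype=object)
            if self.encoding.shape != (self.p,):
                raise ValueError("encoding must have one entry per locus")
            bad = set(self.encoding) - set(VALID_ENCODINGS)
            if bad:
                raise ValueError(f"invalid locus encodings: {sorted(bad)}")

    @property
    def m(self) -> int:
        return self.genotypes.shape[0]

    @property
    def p(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class CorrelationStack:
    """Stacked Fisher-z ROI-ROI correlations, one column per subject.

    The layout has ``p*(p-1)`` rows: ROI ``k`` (1-based) occupies rows
    ``(k-1)*(p-1)+1`` through ``k*(p-1)`` and holds that ROI's transformed
    correlations with every other ROI.  Because correlation matrices are
    symmetric, each unordered ROI pair appears exactly twice per column.
    """

    values: np.ndarray
    p: int
    standardized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("stack must be a 2-D matrix")
        if self.p < 2:
            raise ValueError("need at least p=2 ROIs")
        if self.values.shape[0] != self.p * (self.p - 1):
            raise ValueError(
                f"stack must have p(p-1)={self.p * (self.p - 1)} rows, "
                f"got {self.values.shape[0]}"
            )

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MetricSpec:
    """Which metric produced (or should produce) a distance matrix."""

    family: MetricFamily
    q: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family in ("lq", "lq_maxmin"):
            if self.q is None or self.q < 1:
                raise ValueError("lq families require integer q >= 1")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix with metric provenance."""

    values: np.ndarray
    metric: MetricSpec
    ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed (pdist) order."""
        iu = np.triu_indices(self.m, 1)
        return self.values[iu]


@dataclass
class DiffMoments:
    """Mean/variance of a single-attribute projection Z = |diff|^q."""

    mu_z: float
    sigma2_z: float
    q: int
    data_model: str

    def __post_init__(self) -> None:
        if self.sigma2_z < 0:
            raise ValueError("variance must be nonnegative")


@dataclass
class MomentSummary:
    """Predicted mean/variance of a distance distribution.

    ``family`` labels the limiting distribution (asymptotically normal for
    every metric in this package).  ``params`` records the metric/data-model
    combination the prediction is for.
    """

    mean: float
    variance: float
    family: str = "normal"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class ExtremeMoments:
    """Raw moments of the sample maximum and minimum for sample size m."""

    mu_max1: float
    mu_max2: float
    mu_min1: float
    mu_min2: float
    m: int
    data_model: str = "custom"

    @property
    def var_max(self) -> float:
        return self.mu_max2 - self.mu_max1**2

    @property
    def var_min(self) -> float:
        return self.mu_min2 - self.mu_min1**2

    @property
    def mean_range(self) -> float:
        return self.mu_max1 - self.mu_min1


@dataclass
class GwasDiffPmf:
    """Finite probability mass function of a genotype diff metric."""

    support: np.ndarray
    probabilities: np.ndarray
    metric: str
    f: float

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.support.shape != self.probabilities.shape:
            raise ValueError("support and probabilities must align")
        if (self.probabilities < -1e-15).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def mean(self) -> float:
        return float(self.support @ self.probabilities)

    def var(self) -> float:
        mu = self.mean()
        return float((self.support**2) @ self.probabilities - mu**2)


@dataclass
class CorrectionFit:
    """Least-squares fit of the correlation-stack variance discrepancy.

    The discrepancy (sample distance variance minus the independence-
    assumption variance) is regressed on ``beta1*p**2 + beta0*p`` without
    intercept across a grid of ROI counts.
    """

    beta0: float
    beta1: float
    p_grid: np.ndarray
    discrepancies: np.ndarray
    replicates: int
    m: int
    seed: Optional[int]
    residual: float


@dataclass
class CorrelationTarget:
    """A p x p positive-definite target correlation matrix."""

    matrix: np.ndarray
    source: str = "user"
    connection_prob: Optional[float] = None
    hi_value: Optional[float] = None
    lo_value: Optional[float] = None

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation target must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation target must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("correlation target must have unit diagonal")
        self.matrix = R

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NeighborhoodSpec:
    """How to build per-instance neighborhoods from a distance matrix."""

    kind: Literal["fixed_k", "multisurf_radius"]
    k: Optional[int] = None
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.kind == "fixed_k":
            if self.k is None or self.k < 1:
                raise ValueError("fixed_k requires integer k >= 1")
        elif self.kind != "multisurf_radius":
            raise ValueError(f"unknown neighborhood kind: {self.kind}")
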