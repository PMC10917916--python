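"""Gaussian-kernel CCA with entropy-based feature fusion.

Two deep-feature views of the same samples are compared in a kernel-induced
feature space: with centered Gaussian kernel matrices ``Ku`` and ``Kv``, the
first canonical pair (xi, eta) maximizes

    xi' Ku Kv eta   subject to   xi' Ku Ku xi = eta' Kv Kv eta = 1,

solved as a generalized eigenproblem with ridge-regularized blocks (the
unregularized blocks are rank-deficient because both are N x N Grams built
from N samples). The leading canonical correlation ``rho`` is retained as a
fusion-quality diagnostic.

The fused matrix itself is the horizontal concatenation of the two views
with each column scaled by its normalized Shannon entropy, which
down-weights near-constant (low-information) columns; kernel-space
projections live in N-dimensional coefficient space and cannot span the
p1+p2 output columns, so weighting-by-entropy is the transformation applied
to the concatenated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .features import FeatureMatrix


@dataclass
class KernelMatrix:
    """Symmetric PSD Gram matrix with its bandwidth and provenance."""

    values: np.ndarray
    sigma: float | None = None
    source: str = ""
    centered: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kernel matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class KccaSolution:
    """Leading canonical pair in kernel coefficient space."""

    xi: np.ndarray
    eta: np.ndarray
    rho: float
    reg: float


@dataclass
class FusedFeatures:
    """Entropy-weighted concatenation of two feature views."""

    values: np.ndarray
    weights: np.ndarray
    provenance: list[tuple[str, int]]
    kcca: KccaSolution | None = None
    sigma: tuple[float, float] | None = None
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.values, sample_ids=list(self.sample_ids),
                             feature_ids=list(self.feature_ids))


def median_bandwidth(F: np.ndarray) -> float:
    """Median pairwise Euclidean distance (parameter-free sigma heuristic)."""
    from scipy.spatial.distance import pdist

    d = pdist(np.asarray(F, dtype=np.float64))
    med = float(np.median(d))
    return med if med > 0 else 1.0


def gaussian_kernel(F, sigma: float) -> KernelMatrix:
    """K[i, j] = exp(-||f_i - f_j||^2 / (2 sigma^2)); unit diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    values = np.asarray(getattr(F, "values", F), dtype=np.float64)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    sq = (values ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * values @ values.T
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / (2.0 * sigma ** 2))
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, sigma=float(sigma))


def linear_kernel(F) -> KernelMatrix:
    """Test hook: plain Gram matrix, making kernel CCA coincide with
    classical linear CCA on the same data."""
    values = np.asarray(getattr(F, "values", F), dtype=np.float64)
    return KernelMatrix(values @ values.T, sigma=None)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Double centering K' = H K H with H = I - (1/N) 11'. Idempotent."""
    values = K.values
    row = values.mean(axis=0)
    total = values.mean()
    centered = values - row[None, :] - row[:, None] + total
    centered = 0.5 * (centered + centered.T)
    return KernelMatrix(centered, sigma=K.sigma, source=K.source, centered=True)


def solve_kcca(Ku: KernelMatrix, Kv: KernelMatrix, reg: float = 1e-3) -> KccaSolution:
    """Leading canonical pair of two centered kernels.

    Solves the symmetric-block generalized eigenproblem

        [0      KuKv] [xi ]       [KuKu + reg*I      0      ] [xi ]
        [KvKu   0   ] [eta] = lam [0           KvKv + reg*I ] [eta]

    equivalently reduced to the half-size problem
    A^-1 KuKv B^-1 KvKu xi = lam^2 xi with A = KuKu + reg*I,
    B = KvKv + reg*I. Returns (xi, eta, rho) normalized so
    xi' KuKu xi = eta' KvKv eta = 1 and rho clipped into [0, 1].

    Kernels are scaled by 1/N internally so their squared spectrum is O(1)
    and ``reg`` has a sample-size-independent meaning; rho is invariant to
    any common rescaling of the constraint and objective, so only the
    effective ridge strength is affected.
    """
    if Ku.n != Kv.n:
        raise ValueError("kernels must have equal size")
    if reg < 0:
        raise ValueError("reg must be nonnegative")
    n = Ku.n
    ku, kv = Ku.values / n, Kv.values / n
    A = ku @ ku + reg * np.eye(n)
    B = kv @ kv + reg * np.eye(n)
    cross = ku @ kv
    try:
        m = scipy.linalg.solve(A, cross, assume_a="sym") @ \
            scipy.linalg.solve(B, cross.T, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular KCCA system; use reg > 0 (the Gram blocks are "
            "rank-deficient)"
        ) from exc
    eigvals, eigvecs = scipy.linalg.eig(m)
    order = np.argsort(-eigvals.real)
    lam = float(np.clip(eigvals.real[order[0]], 0.0, None))
    xi = eigvecs[:, order[0]].real
    # sign convention: largest-magnitude entry of xi positive
    k = int(np.argmax(np.abs(xi)))
    if xi[k] < 0:
        xi = -xi
    eta = scipy.linalg.solve(B, cross.T @ xi, assume_a="sym")
    nx = float(xi @ (ku @ ku) @ xi)
    ne = float(eta @ (kv @ kv) @ eta)
    if nx > 0:
        xi = xi / np.sqrt(nx)
    if ne > 0:
        eta = eta / np.sqrt(ne)
    rho = float(xi @ cross @ eta)
    rho = float(np.clip(abs(rho), 0.0, 1.0))
    if not np.isfinite(np.sqrt(lam)):
        raise np.linalg.LinAlgError("KCCA eigen-solve failed; increase reg")
    return KccaSolution(xi=xi, eta=eta, rho=rho, reg=float(reg))


def shannon_entropy(column: np.ndarray, bins: int = 256) -> float:
    """Histogram Shannon entropy in bits over equal-width bins.

    A constant column has a single occupied bin and entropy 0.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    column = np.asarray(column, dtype=np.float64)
    lo, hi = float(column.min()), float(column.max())
    if hi - lo < 1e-300:
        return 0.0
    counts, _ = np.histogram(column, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def fuse(F1: FeatureMatrix, F2: FeatureMatrix, sigma: float | None = None,
         reg: float = 1e-3, bins: int = 256) -> FusedFeatures:
    """Kernel-CCA + entropy fusion of two aligned feature views.

    Output width is p1 + p2 (two N x 2,048 views fuse to N x 4,096). When
    ``sigma`` is None, each view uses its own median-distance bandwidth.
    """
    if F1.n != F2.n:
        raise ValueError("feature matrices must have equal row counts")
    if F1.sample_ids != F2.sample_ids:
        raise ValueError("feature matrices must share row order (sample_ids)")
    s1 = sigma if sigma is not None else median_bandwidth(F1.values)
    s2 = sigma if sigma is not None else median_bandwidth(F2.values)
    Ku = center_kernel(gaussian_kernel(F1, s1))
    Kv = center_kernel(gaussian_kernel(F2, s2))
    sol = solve_kcca(Ku, Kv, reg=reg)
    concat = np.hstack([F1.values, F2.values])
    entropies = np.array([shannon_entropy(concat[:, j], bins=bins)
                          for j in range(concat.shape[1])])
    top = entropies.max()
    weights = entropies / top if top > 0 else np.zeros_like(entropies)
    provenance = [("F1", j) for j in range(F1.p)] + [("F2", j) for j in range(F2.p)]
    feature_ids = ([f"F1.{fid}" for fid in F1.feature_ids]
                   + [f"F2.{fid}" for fid in F2.feature_ids])
    return FusedFeatures(values=concat * weights, weights=weights,
                         provenance=provenance, kcca=sol, sigma=(s1, s2),
                         feature_ids=feature_ids, sample_ids=list(F1.sample_ids))
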