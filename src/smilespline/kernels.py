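"""Reproducing kernels for smoothing-spline ANOVA on [0,1] and finite level sets.

Every penalized term in the rating models is built from one of three marginal
reproducing kernels — cubic (continuous covariates such as age, drinks and
delay, affinely rescaled to [0,1]), nominal (unordered levels, e.g. gender) and
ordinal (ordered levels, e.g. the three spatial smile factors) — or from
tensor products of them.  All kernels are centered so that each effect function
averages to zero over its domain and is therefore identifiable against the
model intercept; interactions built as tensor products of centered kernels are
identifiable against their own marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "MarginalDomain",
    "KernelMatrix",
    "cubic_kernel",
    "nominal_kernel",
    "ordinal_kernel",
    "tensor_kernel",
    "cubic_gram",
    "nominal_gram",
    "ordinal_gram",
    "rescale_unit",
]

#: relative tolerance for positive-semi-definiteness checks
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class MarginalDomain:
    """Domain of one covariate: a rescaled interval or an ordered level set.

    Parameters
    ----------
    kind : {"continuous", "nominal", "ordinal"}
    lo, hi : float, optional
        Endpoints of the original interval for continuous domains (e.g. age
        18..82); the kernel operates on the affine rescaling to [0, 1].
    levels : sequence, optional
        Ordered level labels for discrete domains (K >= 2).
    """

    kind: str
    lo: float | None = None
    hi: float | None = None
    levels: tuple = field(default=None)

    def __post_init__(self):
        if self.kind not in ("continuous", "nominal", "ordinal"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "continuous":
            if self.lo is None or self.hi is None or not self.hi > self.lo:
                raise ValueError("continuous domain needs positive width (lo < hi)")
        else:
            if self.levels is None or len(self.levels) < 2:
                raise ValueError("discrete domain needs at least 2 levels")
            object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        if self.kind == "continuous":
            raise ValueError("continuous domain has no level count")
        return len(self.levels)

    def rescale(self, x):
        """Map raw continuous values into [0, 1]."""
        return rescale_unit(x, self.lo, self.hi)

    def level_index(self, x):
        """Map level labels to 0-based indices (vectorized)."""
        lut = {lv: i for i, lv in enumerate(self.levels)}
        arr = np.asarray(x, dtype=object).ravel()
        try:
            idx = np.array([lut[v] for v in arr])
        except KeyError as e:
            raise ValueError(f"level {e.args[0]!r} not in domain {self.levels}") from None
        return idx.reshape(np.shape(x))


@dataclass
class KernelMatrix:
    """A Gram matrix of kernel evaluations over a point set."""

    values: np.ndarray
    domain: object = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        self.values = v

    def check_psd(self, rtol: float = PSD_RTOL) -> bool:
        v = 0.5 * (self.values + self.values.T)
        w = np.linalg.eigvalsh(v)
        return w.min() >= -rtol * max(w.max(), 1.0)


# ---------------------------------------------------------------------------
# scaled Bernoulli polynomials k_r(u) = B_r(u)/r!
# ---------------------------------------------------------------------------

def _k1(u):
    return u - 0.5


def _k2(u):
    return (_k1(u) ** 2 - 1.0 / 12.0) / 2.0


def _k4(u):
    return (_k1(u) ** 4 - _k1(u) ** 2 / 2.0 + 7.0 / 240.0) / 24.0


def cubic_kernel(x, z):
    """Cubic smoothing-spline reproducing kernel on [0, 1].

    k(x, z) = k1(x)k1(z) + k2(x)k2(z) - k4(|x - z|) with k_r the scaled
    Bernoulli polynomials.  Symmetric and positive semi-definite; its penalty
    null space is spanned by {1, x}, so straight lines are never shrunk.
    Accepts scalars or broadcastable arrays.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(x < 0) or np.any(x > 1) or np.any(z < 0) or np.any(z > 1):
        raise ValueError("cubic kernel inputs must lie in [0, 1]")
    out = _k1(x) * _k1(z) + _k2(x) * _k2(z) - _k4(np.abs(x - z))
    return out if out.ndim else float(out)


def nominal_kernel(x, z, K: int):
    """Shrinkage kernel for an unordered factor: I(x = z) - 1/K.

    Centered (rows sum to zero over the K levels), so the estimated factor
    effect sums to zero across levels.
    """
    if K < 2:
        raise ValueError("nominal kernel needs K >= 2 levels")
    x = np.asarray(x)
    z = np.asarray(z)
    out = (x == z).astype(float) - 1.0 / K
    return out if out.ndim else float(out)


@lru_cache(maxsize=None)
def _ordinal_gram_cached(K: int) -> np.ndarray:
    # Moore-Penrose inverse of the first-difference penalty D'D on level
    # scores; its range is the centered subspace, so rows sum to zero, and
    # the induced penalty grows with squared level differences.
    D = np.diff(np.eye(K), axis=0)
    P = D.T @ D
    G = np.linalg.pinv(P)
    return 0.5 * (G + G.T)


def ordinal_kernel(x, z, K: int):
    """Ordinal smoothing-spline kernel on levels 1..K.

    Defined constructively as the Moore-Penrose inverse of the discrete
    first-difference penalty matrix, restricted to the centered subspace:
    symmetric, PSD, zero row sums, and penalizing squared level differences.
    ``x``/``z`` are 1-based level indices (scalar or array).
    """
    if K < 2:
        raise ValueError("ordinal kernel needs K >= 2 levels")
    G = _ordinal_gram_cached(K)
    xi = np.asarray(x, dtype=int) - 1
    zi = np.asarray(z, dtype=int) - 1
    if np.any(xi < 0) or np.any(xi >= K) or np.any(zi < 0) or np.any(zi >= K):
        raise ValueError(f"ordinal kernel indices must be in 1..{K}")
    out = G[xi, zi]
    return out if np.ndim(out) else float(out)


def tensor_kernel(kA, kB):
    """Tensor-product (elementwise/Schur) kernel of two Gram matrices.

    The reproducing kernel of an interaction space is the product of the
    marginal kernels; over a shared observation index this is the elementwise
    product, which preserves symmetry and positive semi-definiteness.
    """
    a = kA.values if isinstance(kA, KernelMatrix) else np.asarray(kA, dtype=float)
    b = kB.values if isinstance(kB, KernelMatrix) else np.asarray(kB, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    out = a * b
    if isinstance(kA, KernelMatrix) or isinstance(kB, KernelMatrix):
        return KernelMatrix(out)
    return out


# ---------------------------------------------------------------------------
# Gram-matrix helpers (rows = evaluation points, cols = knots)
# ---------------------------------------------------------------------------

def cubic_gram(x: Sequence[float], knots: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)[:, None]
    u = np.asarray(knots, dtype=float)[None, :]
    return cubic_kernel(x, u)


def nominal_gram(idx: Sequence[int], K: int) -> np.ndarray:
    """Rows: 0-based observed level indices; columns: the K levels."""
    idx = np.asarray(idx, dtype=int)[:, None]
    lv = np.arange(K)[None, :]
    return nominal_kernel(idx, lv, K)


def ordinal_gram(idx: Sequence[int], K: int) -> np.ndarray:
    """Rows: 0-based observed level indices; columns: the K levels."""
    idx = np.asarray(idx, dtype=int)
    return _ordinal_gram_cached(K)[idx, :]


def rescale_unit(x, lo: float, hi: float):
    """Affine map [lo, hi] -> [0, 1]; errors on out-of-range input."""
    if not hi > lo:
        raise ValueError("degenerate interval")
    x = np.asarray(x, dtype=float)
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError(f"values outside declared domain [{lo}, {hi}]")
    out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return out if out.ndim else float(out)
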