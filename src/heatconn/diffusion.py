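"""Graph Laplacians and heat-kernel diffusion.

For an undirected weighted graph with adjacency A and degree matrix
D (D_ii = sum_j A_ij), the combinatorial Laplacian L = D - A generates the
graph heat equation; its fundamental solution at diffusion time t is the
heat kernel

    K_t = exp(-t L),

computed here by full eigendecomposition K_t = U exp(-t Lambda) U^T.  Small
t emphasizes local connectivity; large t approaches the projection onto the
constant vector within each connected component.  Diffusing node signals,
X_t = K_t X, smooths them along the graph and lowers their Dirichlet energy
x^T L x.  A truncated Chebyshev (or Taylor) approximation is provided as a
scalability path; the eigendecomposition is the exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "GraphLaplacian", "HeatKernel", "graph_laplacian", "heat_kernel_exact",
    "heat_kernel_poly", "diffuse", "dirichlet_energy",
]

_ASYM_TOL = 1e-10
_DUST = 1e-12  # entries below this are numerical dust from eigen-reconstruction


class DiffusionError(ValueError):
    pass


@dataclass
class GraphLaplacian:
    values: np.ndarray
    variant: str  # "combinatorial" | "symmetric_normalized"
    adjacency: np.ndarray

    def __post_init__(self):
        v = self.values
        if np.max(np.abs(v - v.T)) > 1e-8:
            raise DiffusionError("Laplacian is not symmetric")
        if self.variant == "combinatorial":
            rs = np.abs(v.sum(axis=1)).max()
            if rs > 1e-8:
                raise DiffusionError(f"combinatorial Laplacian row sums |{rs}| > 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and orthonormal eigenvectors, cached."""
        if not hasattr(self, "_eig"):
            lam, u = linalg.eigh(self.values)
            if not (np.all(np.isfinite(lam)) and np.all(np.isfinite(u))):
                raise DiffusionError("non-finite eigenvalues in Laplacian")
            if lam.min() < -1e-8:
                raise DiffusionError(f"Laplacian not PSD: min eigenvalue {lam.min()}")
            self._eig = (lam, u)
        return self._eig


@dataclass
class HeatKernel:
    values: np.ndarray
    time: float
    variant: str

    def __post_init__(self):
        if self.time < 0:
            raise DiffusionError("diffusion time must be >= 0")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def graph_laplacian(adjacency: np.ndarray,
                    variant: str = "combinatorial") -> GraphLaplacian:
    """L = D - A (combinatorial) or I - D^{-1/2} A D^{-1/2} (normalized).

    The adjacency must be symmetric, nonnegative, and hollow (zero diagonal).
    Isolated nodes get an all-zero row in the normalized variant.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DiffusionError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > _ASYM_TOL:
        raise DiffusionError("adjacency asymmetry beyond tolerance")
    if a.min() < 0:
        raise DiffusionError("negative edge weight")
    if np.abs(np.diag(a)).max() > 0:
        raise DiffusionError("adjacency diagonal must be zero")
    deg = a.sum(axis=1)
    if variant == "combinatorial":
        lap = np.diag(deg) - a
    elif variant == "symmetric_normalized":
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        lap = np.diag((deg > 0).astype(float)) - dinv[:, None] * a * dinv[None, :]
    else:
        raise DiffusionError(f"unknown Laplacian variant {variant!r}")
    lap = (lap + lap.T) / 2.0
    return GraphLaplacian(lap, variant, a)


def _finalize(values: np.ndarray, t: float, variant: str) -> HeatKernel:
    k = (values + values.T) / 2.0
    k[np.abs(k) < _DUST] = 0.0
    return HeatKernel(k, float(t), variant)


def heat_kernel_exact(lap: GraphLaplacian, t: float) -> HeatKernel:
    """K_t = U exp(-t Lambda) U^T via the Laplacian's eigendecomposition."""
    if t < 0:
        raise DiffusionError("diffusion time must be >= 0")
    if t == 0:
        return HeatKernel(np.eye(lap.n), 0.0, lap.variant)
    lam, u = lap.eigendecomposition()
    w = np.exp(-t * np.clip(lam, 0.0, None))
    return _finalize((u * w) @ u.T, t, lap.variant)


def heat_kernel_poly(lap: GraphLaplacian, t: float, order: int,
                     method: str = "chebyshev") -> HeatKernel:
    """Truncated polynomial approximation of exp(-t L).

    ``chebyshev`` interpolates exp(-t x) on [0, lambda_max] with a degree-
    ``order`` Chebyshev series and evaluates it at L by the Clenshaw
    recurrence; ``taylor`` sums the plain exponential series (may diverge
    for large t * lambda_max).  For N <= 512 the max-abs deviation from the
    exact kernel is recorded on the result as ``max_abs_error``.
    """
    if order < 1:
        raise DiffusionError("order must be >= 1")
    if t < 0:
        raise DiffusionError("diffusion time must be >= 0")
    n = lap.n
    L = lap.values
    if t == 0:
        out = _finalize(np.eye(n), 0.0, lap.variant)
        out.max_abs_error = 0.0
        return out
    if method == "taylor":
        k = np.eye(n)
        term = np.eye(n)
        for j in range(1, order + 1):
            term = term @ (-t / j * L)
            k = k + term
    elif method == "chebyshev":
        # spectral bound via Gershgorin; cheap and safe
        lmax = float(np.max(np.abs(L).sum(axis=1)))
        if lmax == 0.0:
            lmax = 1.0
        cheb = np.polynomial.chebyshev.Chebyshev.interpolate(
            lambda x: np.exp(-t * x), order, domain=[0.0, lmax])
        c = cheb.coef
        # Clenshaw recurrence on the rescaled operator Ls in [-1, 1]
        Ls = (2.0 / lmax) * L - np.eye(n)
        b1 = np.zeros((n, n))
        b2 = np.zeros((n, n))
        for cj in c[:0:-1]:
            b1, b2 = 2.0 * (Ls @ b1) - b2 + cj * np.eye(n), b1
        k = Ls @ b1 - b2 + c[0] * np.eye(n)
    else:
        raise DiffusionError(f"unknown polynomial method {method!r}")
    if not np.all(np.isfinite(k)):
        raise DiffusionError(
            "polynomial kernel diverged; use smaller t or higher order")
    out = _finalize(k, t, lap.variant)
    if n <= 512:
        out.max_abs_error = float(
            np.max(np.abs(out.values - heat_kernel_exact(lap, t).values)))
    return out


def diffuse(kernel: HeatKernel | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Diffused signals X_t = K_t X (each column smoothed along the graph)."""
    k = kernel.values if isinstance(kernel, HeatKernel) else np.asarray(kernel)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
        squeeze = True
    else:
        squeeze = False
    if k.shape[1] != x.shape[0]:
        raise DiffusionError(f"shape mismatch: kernel {k.shape}, signal {x.shape}")
    out = k @ x
    return out[:, 0] if squeeze else out


def dirichlet_energy(lap: GraphLaplacian | np.ndarray, x: np.ndarray) -> float:
    """Signal roughness x^T L x (summed over signal columns)."""
    L = lap.values if isinstance(lap, GraphLaplacian) else np.asarray(lap)
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    return float(np.sum(x * (L @ x)))
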