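"""Robust PCA denoising of coherence stacks (inexact ALM solver).

The lag images of a :class:`~slscbf.beamform.CoherenceStack` are
vectorized into a pixels-by-lags matrix D, decomposed into a low-rank
part A and a sparse part E by minimizing

    ||A||_* + lambda * ||E||_1   s.t.   D = A + E

via the inexact augmented Lagrange multiplier method (alternating
singular-value thresholding and entry-wise soft thresholding).  Summing
the denoised A over lags gives the r-SLSC image; applying the linearly
decreasing lag weights to the per-lag denoised images gives R-SLSC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .beamform import BeamformedImage, CoherenceStack, m_slsc_weights


@dataclass(frozen=True)
class RpcaConfig:
    """Inexact-ALM solver parameters.

    ``sparsity_lambda`` defaults to 1 (used literally, not the generic
    1/sqrt(max dim) convention).  ``mu`` starts at 1.25 / ||D||_2 and
    grows geometrically by ``mu_growth`` each iteration.
    """

    sparsity_lambda: float = 1.0
    mu_growth: float = 1.5
    tolerance: float = 1e-7
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.sparsity_lambda <= 0:
            raise ValueError("sparsity_lambda must be positive")
        if self.mu_growth <= 1.0:
            raise ValueError("mu_growth must be > 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LagMatrix:
    """Vectorized coherence stack: column m holds the flattened lag-m image."""

    D: np.ndarray  # (pixels, lags)
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.D.ndim != 2:
            raise ValueError("lag matrix must be 2-D (pixels, lags)")
        if self.D.shape[0] != self.image_shape[0] * self.image_shape[1]:
            raise ValueError(
                f"row count {self.D.shape[0]} does not match image shape {self.image_shape}"
            )


@dataclass
class RpcaResult:
    A: np.ndarray
    E: np.ndarray
    iterations: int
    converged: bool
    residual: float
    rank: int


def vectorize_stack(stack: CoherenceStack) -> LagMatrix:
    """Flatten each lag image (row-major) into a column of D."""
    n_ax, n_lat, M = stack.lag_images.shape
    return LagMatrix(stack.lag_images.reshape(n_ax * n_lat, M), (n_ax, n_lat))


def unvectorize(matrix: LagMatrix) -> np.ndarray:
    """Reverse :func:`vectorize_stack`; exact for any matrix contents.

    Returns the raw (axial, lateral, lag) array rather than a
    :class:`CoherenceStack` because denoised values may stray slightly
    outside [-1, 1].
    """
    n_ax, n_lat = matrix.image_shape
    return matrix.D.reshape(n_ax, n_lat, matrix.D.shape[1])


def _soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def inexact_alm_rpca(D, config: RpcaConfig = RpcaConfig()) -> RpcaResult:
    """Low-rank + sparse decomposition of D by the inexact ALM method."""
    if isinstance(D, LagMatrix):
        D = D.D
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2:
        raise ValueError("D must be a 2-D matrix")
    if not np.all(np.isfinite(D)):
        raise ValueError("D contains non-finite values")

    norm_fro = linalg.norm(D, "fro")
    if norm_fro == 0.0:
        return RpcaResult(np.zeros_like(D), np.zeros_like(D), 0, True, 0.0, 0)

    lam = config.sparsity_lambda
    # spectral norm via the same SVD machinery used in the iterations
    norm_two = linalg.svdvals(D)[0]
    norm_inf = np.abs(D).max() / lam
    Y = D / max(norm_two, norm_inf)  # standard dual-feasible start
    mu = 1.25 / norm_two
    mu_max = mu * 1e7

    A = np.zeros_like(D)
    E = np.zeros_like(D)
    residual = np.inf
    converged = False
    rank = 0
    it = 0
    for it in range(1, config.max_iterations + 1):
        # E-step: soft thresholding
        E = _soft_threshold(D - A + Y / mu, lam / mu)
        # A-step: singular value thresholding
        U, s, Vt = linalg.svd(D - E + Y / mu, full_matrices=False)
        s_shrunk = np.maximum(s - 1.0 / mu, 0.0)
        rank = int(np.count_nonzero(s_shrunk))
        A = (U[:, :rank] * s_shrunk[:rank]) @ Vt[:rank]
        Z = D - A - E
        Y = Y + mu * Z
        mu = min(mu * config.mu_growth, mu_max)
        residual = linalg.norm(Z, "fro") / norm_fro
        if residual < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RPCA did not converge in {config.max_iterations} iterations "
            f"(residual {residual:.3e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return RpcaResult(A, E, it, converged, float(residual), rank)


def denoise_stack(stack: CoherenceStack, config: RpcaConfig = RpcaConfig()) -> tuple[np.ndarray, RpcaResult]:
    """RPCA on the vectorized stack; returns per-lag denoised images."""
    matrix = vectorize_stack(stack)
    result = inexact_alm_rpca(matrix.D, config)
    denoised = unvectorize(LagMatrix(result.A, matrix.image_shape))
    return denoised, result


def r_slsc_image(
    stack: CoherenceStack,
    config: RpcaConfig = RpcaConfig(),
    denoised: np.ndarray | None = None,
) -> BeamformedImage:
    """r-SLSC: denoised lag images summed, negatives zeroed afterwards."""
    if denoised is None:
        denoised, _ = denoise_stack(stack, config)
    values = denoised.sum(axis=2)
    np.maximum(values, 0.0, out=values)
    return BeamformedImage(values, "r-SLSC", stack.band, "linear", stack.geometry)


def robust_slsc_image(
    stack: CoherenceStack,
    config: RpcaConfig = RpcaConfig(),
    M: int | None = None,
    denoised: np.ndarray | None = None,
) -> BeamformedImage:
    """R-SLSC: per-lag denoised images zeroed, then lag-weighted sum.

    Mirrors the M-SLSC rule: negatives are zeroed per lag before the
    linearly decreasing weights are applied.
    """
    if denoised is None:
        denoised, _ = denoise_stack(stack, config)
    if M is None:
        M = stack.M
    if not (1 <= M <= stack.M):
        raise ValueError(f"M must satisfy 1 <= M <= stack.M = {stack.M}, got {M}")
    positive = np.maximum(denoised[:, :, :M], 0.0)
    values = np.tensordot(positive, m_slsc_weights(M), axes=([2], [0]))
    return BeamformedImage(values, "R-SLSC", stack.band, "linear", stack.geometry)
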