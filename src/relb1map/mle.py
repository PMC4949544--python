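"""Voxelwise maximum-likelihood combination of multi-drive SPGR measurements.

Each voxel/channel yields N complex measurements S_j at ascending RF drives
d_j. Dividing by the drive gives normalized signals S'_j = S_j/d_j which all
share the mean rho*f while unsaturated, with noise sigma'_j = sigma/d_j. The
reconstruction assumes the first k measurements are unsaturated and the rest
are depressed by saturation; for each k it computes the ML estimate

    gamma_k = sum_{j<=k} d_j^2 S'_j / sum_{j<=k} d_j^2

(the inverse-variance weighted mean) and the 2D-Normal log-likelihood

    L_k = -k ln(2pi) - sum_{j<=k} [2 ln(sigma'_j) + |S'_j - gamma_k|^2 / (2 sigma'_j^2)],

then keeps the k maximizing L_k. Saturated high-drive measurements pull
gamma_k away from the low-drive data and pay a large residual penalty, so
they are rejected automatically; unsaturated measurements are rewarded both
by the residual fit and by their small sigma'_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_model import DriveScheme

__all__ = [
    "VoxelSeries",
    "NormalizedSeries",
    "ReconEstimate",
    "normalize",
    "loglikelihood_k",
    "estimate_gamma_k",
    "select_kmax",
    "reconstruct_stack",
    "estimate_sigma",
]

_LN2PI = float(np.log(2 * np.pi))
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class VoxelSeries:
    """N complex raw measurements of one voxel/channel plus the noise level.

    ``sigma`` is the noise standard deviation per real/imaginary component,
    in the same units as the signals.
    """

    signals: tuple
    drives: DriveScheme
    sigma: float

    def __post_init__(self) -> None:
        s = np.asarray(self.signals, dtype=complex)
        if s.ndim != 1 or s.size != len(self.drives):
            raise ValueError(
                f"expected {len(self.drives)} signals, got {s.size}"
            )
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        object.__setattr__(self, "signals", tuple(complex(x) for x in s))


@dataclass(frozen=True)
class NormalizedSeries:
    """Drive-normalized signals S'_j = S_j/d_j with noise sigma'_j = sigma/d_j."""

    normalized: tuple
    sigmas: tuple
    drives: DriveScheme


@dataclass(frozen=True)
class ReconEstimate:
    """MLE result for one voxel/channel: the complex signal estimate, the
    number of drive levels deemed unsaturated, and the per-k log-likelihoods."""

    gamma_hat: complex
    k_max: int
    loglik: tuple


def normalize(series: VoxelSeries) -> NormalizedSeries:
    """Divide raw signals by their RF drives; noise scales as sigma/d_j."""
    d = series.drives.as_array()
    s = np.asarray(series.signals, dtype=complex)
    return NormalizedSeries(
        normalized=tuple(s / d),
        sigmas=tuple(series.sigma / d),
        drives=series.drives,
    )


def estimate_gamma_k(norm: NormalizedSeries, k: int) -> complex:
    """ML estimate of the common mean using the first ``k`` measurements.

    The inverse-variance weights 1/sigma'_j^2 are proportional to d_j^2, so
    the estimate is the d_j^2-weighted mean of S'_1..S'_k.
    """
    N = len(norm.normalized)
    if not (1 <= k <= N):
        raise ValueError(f"k must lie in [1, {N}], got {k}")
    d2 = norm.drives.as_array()[:k] ** 2
    s = np.asarray(norm.normalized[:k], dtype=complex)
    return complex(np.sum(d2 * s) / np.sum(d2))


def loglikelihood_k(norm: NormalizedSeries, gamma: complex, k: int) -> float:
    """Log-likelihood that ``gamma`` is the common mean of the first ``k``
    normalized measurements, under the 2D Normal noise model.

    The sigma'-dependent constants are kept: they differ across k and are
    what rewards the inclusion of additional low-noise measurements.
    """
    N = len(norm.normalized)
    if not (1 <= k <= N):
        raise ValueError(f"k must lie in [1, {N}], got {k}")
    s = np.asarray(norm.normalized[:k], dtype=complex)
    sig = np.asarray(norm.sigmas[:k], dtype=float)
    resid = np.abs(s - gamma) ** 2 / (2 * sig**2)
    return float(-k * _LN2PI - np.sum(2 * np.log(sig) + resid))


def _mle_core(sprime: np.ndarray, drives: np.ndarray, sigma: float):
    """Vectorized MLE over the last axis (the drive axis).

    Parameters
    ----------
    sprime : complex array, shape (..., N)
        Normalized signals.
    drives : float array, shape (N,)
    sigma : float
        Raw-signal noise standard deviation (before normalization).

    Returns
    -------
    gamma_hat : complex array, shape (...)
    k_max : int array, shape (...)
    loglik : float array, shape (..., N)

    Notes
    -----
    For each k the residual sum with gamma = gamma_k collapses to
    ``A_k - |B_k|^2 / C_k`` where A, B, C are cumulative sums of
    w_j |S'_j|^2, w_j S'_j and w_j with w_j = d_j^2/(2 sigma^2), so the whole
    sweep over k is three cumulative sums. Ties in L_k within 1e-12 resolve
    to the larger k (more data).
    """
    d = np.asarray(drives, dtype=float)
    sprime = np.asarray(sprime, dtype=complex)
    sig_norm = sigma / d  # sigma'_j
    w = d**2 / (2 * sigma**2)  # 1 / (2 sigma'_j^2)

    # center on the first measurement: the residual sum is translation
    # invariant, and working with deviations avoids catastrophic cancellation
    # in A - |B|^2/C when sigma is many orders below the signal scale
    shift = sprime[..., :1]
    dev = sprime - shift
    A = np.cumsum(w * np.abs(dev) ** 2, axis=-1)
    B = np.cumsum(w * dev, axis=-1)
    C = np.cumsum(w)
    gamma_k = B / C + shift
    resid = A - np.abs(B) ** 2 / C
    # guard tiny negative values from cancellation
    resid = np.maximum(resid, 0.0)

    k = np.arange(1, d.size + 1)
    const = -k * _LN2PI - np.cumsum(2 * np.log(sig_norm))
    loglik = const - resid

    best = np.max(loglik, axis=-1, keepdims=True)
    # largest k within tie tolerance of the maximum
    near = loglik >= best - _TIE_TOL
    k_max = d.size - 1 - np.argmax(near[..., ::-1], axis=-1)
    gamma_hat = np.take_along_axis(gamma_k, k_max[..., None], axis=-1)[..., 0]
    return gamma_hat, k_max + 1, loglik


def select_kmax(norm: NormalizedSeries) -> ReconEstimate:
    """Evaluate gamma_k and L_k for k = 1..N and keep the most likely model order."""
    sprime = np.asarray(norm.normalized, dtype=complex)
    d = norm.drives.as_array()
    sigma = float(norm.sigmas[0] * d[0])
    gamma_hat, k_max, loglik = _mle_core(sprime, d, sigma)
    return ReconEstimate(
        gamma_hat=complex(gamma_hat),
        k_max=int(k_max),
        loglik=tuple(float(x) for x in loglik),
    )


def reconstruct_voxel(series: VoxelSeries) -> ReconEstimate:
    """Convenience: normalize a raw series and run the model-order MLE."""
    return select_kmax(normalize(series))


def reconstruct_stack(stack, drives: DriveScheme, sigma: float):
    """Apply the voxelwise MLE to a full multi-channel, multi-drive image stack.

    Parameters
    ----------
    stack : complex array, shape (n_channels, n_drives, *spatial)
        Raw complex images, one per channel and drive level.
    drives : DriveScheme
    sigma : float
        Global noise standard deviation per real/imaginary component.

    Returns
    -------
    gamma : complex array, shape (n_channels, *spatial)
        Per-channel reconstructed signal, proportional to the transmit field.
    k_max : int array, shape (n_channels, *spatial)
        Number of drive levels used at each voxel (1..N).
    """
    stack = np.asarray(stack, dtype=complex)
    N = len(drives)
    if stack.ndim < 2 or stack.shape[1] != N:
        raise ValueError(
            f"stack must have shape (channels, {N}, ...), got {stack.shape}"
        )
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    d = drives.as_array()
    # move the drive axis last and normalize
    sprime = np.moveaxis(stack, 1, -1) / d
    gamma, k_max, _ = _mle_core(sprime, d, sigma)
    return gamma, k_max.astype(np.int32)


def estimate_sigma(background) -> float:
    """Noise level from a signal-free background region.

    Pools the real and imaginary parts of the background samples and returns
    their standard deviation about the respective means (each complex sample
    contributes two real observations).
    """
    b = np.asarray(background, dtype=complex).ravel()
    if b.size < 20:
        raise ValueError(f"need at least 20 background samples, got {b.size}")
    parts = np.concatenate([b.real - b.real.mean(), b.imag - b.imag.mean()])
    sigma = float(np.sqrt(np.mean(parts**2)))
    if sigma == 0.0:
        warnings.warn(
            "background region has zero variance; sigma must be positive "
            "for reconstruction",
            stacklevel=2,
        )
    return sigma
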