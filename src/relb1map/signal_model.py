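"""Spoiled gradient-echo (SPGR) steady-state signal model and RF drive design.

The steady-state SPGR signal in a voxel is

    S = M0 * R * (1 - E1) * exp(-TE/T2*) * exp(i*phi) * sin(theta) / (1 - E1*cos(theta))

with ``E1 = exp(-TR/T1)`` and flip angle ``theta = f * d * theta_ref``, where
``f`` is the (unitless) transmit sensitivity of a channel, ``d`` in (0, 1] is
the RF drive scale, and ``theta_ref`` is the flip angle reached at f = d = 1.
At low flip angle the signal is linear in ``theta``; the relative shortfall of
the true signal below that tangent line ("saturation") grows with flip angle
and with T1 weighting, and is what the multi-drive acquisition scheme is
designed around: the lowest drive is picked so the brightest voxel still sits
within a prescribed linearity tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SPGRParams",
    "DriveScheme",
    "spgr_signal",
    "linear_signal",
    "saturation_error",
    "min_drive",
    "make_drive_scheme",
]


@dataclass(frozen=True)
class SPGRParams:
    """Tissue and sequence constants of the SPGR signal equation.

    Times are in milliseconds, angles in radians. ``M0`` is the equilibrium
    magnetization (arbitrary units), ``R`` the net complex receive weight
    after channel combination, ``phi`` the transmit phase, and ``theta_ref``
    the reference flip angle corresponding to transmit sensitivity f = 1 at
    full drive d = 1.
    """

    TR: float
    T1: float
    theta_ref: float
    TE: float = 0.0
    T2star: float = np.inf
    M0: float = 1.0
    R: complex = 1.0 + 0.0j
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (self.TR > 0):
            raise ValueError(f"TR must be positive, got {self.TR}")
        if not (self.T1 > 0):
            raise ValueError(f"T1 must be positive, got {self.T1}")
        if self.TE < 0:
            raise ValueError(f"TE must be non-negative, got {self.TE}")
        if not (self.T2star > 0):
            raise ValueError(f"T2star must be positive, got {self.T2star}")
        if self.TE >= 50 * self.T2star:
            raise ValueError("TE implausibly long relative to T2star")
        if not (self.theta_ref > 0):
            raise ValueError(f"theta_ref must be positive, got {self.theta_ref}")
        if not (self.M0 > 0):
            raise ValueError(f"M0 must be positive, got {self.M0}")

    @property
    def E1(self) -> float:
        return float(np.exp(-self.TR / self.T1))

    @property
    def rho(self) -> complex:
        """Linear-regime coefficient: ``linear_signal = rho * f * d``.

        The tangent of the signal equation at theta = 0 has slope
        M0*R*exp(-TE/T2*)*exp(i*phi) per radian, hence rho carries one factor
        of theta_ref.
        """
        return (
            self.M0
            * self.R
            * np.exp(-self.TE / self.T2star)
            * np.exp(1j * self.phi)
            * self.theta_ref
        )


@dataclass(frozen=True)
class DriveScheme:
    """Ordered RF drive scales d_1 < ... < d_N, each in (0, 1]."""

    drives: tuple
    scheme_kind: str = "explicit"

    def __post_init__(self) -> None:
        d = np.asarray(self.drives, dtype=float)
        if d.size < 1:
            raise ValueError("at least one drive is required")
        if not np.all(d > 0) or not np.all(d <= 1):
            raise ValueError(f"drives must lie in (0, 1], got {self.drives}")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError(f"drives must be strictly ascending, got {self.drives}")
        if self.scheme_kind not in ("linear", "logarithmic", "explicit"):
            raise ValueError(f"unknown scheme_kind {self.scheme_kind!r}")
        object.__setattr__(self, "drives", tuple(float(x) for x in d))

    def __len__(self) -> int:
        return len(self.drives)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.drives, dtype=float)


def spgr_signal(params: SPGRParams, f, d):
    """Noise-free steady-state SPGR signal at transmit sensitivity ``f`` and drive ``d``.

    ``f`` and ``d`` may be scalars or broadcastable arrays; the result is complex.
    """
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(f < 0):
        raise ValueError("transmit sensitivity f must be non-negative")
    if np.any(d <= 0) or np.any(d > 1):
        raise ValueError("drive d must lie in (0, 1]")
    E1 = params.E1
    theta = f * d * params.theta_ref
    amp = params.M0 * params.R * np.exp(-params.TE / params.T2star) * np.exp(1j * params.phi)
    out = amp * (1 - E1) * np.sin(theta) / (1 - E1 * np.cos(theta))
    return out if out.ndim else complex(out)


def linear_signal(params: SPGRParams, f, d):
    """Low-flip-angle (tangent at theta = 0) approximation ``rho * f * d``."""
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(f < 0):
        raise ValueError("transmit sensitivity f must be non-negative")
    if np.any(d <= 0) or np.any(d > 1):
        raise ValueError("drive d must lie in (0, 1]")
    out = params.rho * f * d
    return out if out.ndim else complex(out)


def saturation_error(params: SPGRParams, theta) -> float | np.ndarray:
    """Relative shortfall of the SPGR signal below its linear approximation.

    Returns ``1 - |S(theta)| / |S_linear(theta)|``; 0 at theta = 0 and
    monotone increasing up to 90 degrees for relevant TR/T1. Independent of
    M0, R, TE, T2* and phi, which cancel in the ratio.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta >= np.pi):
        raise ValueError("theta must lie in [0, pi)")
    E1 = params.E1
    with np.errstate(invalid="ignore"):
        ratio = (1 - E1) * np.sin(theta) / (theta * (1 - E1 * np.cos(theta)))
    ratio = np.where(theta == 0, 1.0, ratio)
    out = 1.0 - ratio
    return out if out.ndim else float(out)


def min_drive(params: SPGRParams, f_max: float, tol: float) -> float:
    """Largest drive at which the brightest voxel is still linear to ``tol``.

    Finds the drive ``d`` such that ``saturation_error(f_max * d * theta_ref)``
    equals ``tol`` by bracketed root-finding on d in [1e-6, 1]. If even full
    drive satisfies the tolerance the result is capped at 1.
    """
    if not (f_max > 0):
        raise ValueError("f_max must be positive")
    if not (0 < tol < 0.5):
        raise ValueError("tol must lie in (0, 0.5)")

    def err_at(d: float) -> float:
        theta = f_max * d * params.theta_ref
        if theta >= np.pi:
            # beyond the model's intent; saturation only worsens
            return 1.0 - tol + (theta - np.pi)
        return saturation_error(params, theta) - tol

    lo, hi = 1e-6, 1.0
    if err_at(hi) <= 0:
        return 1.0
    if err_at(lo) > 0:
        raise ValueError(
            "linearity tolerance unattainable even at drive 1e-6; "
            "reduce f_max or theta_ref"
        )
    d = brentq(err_at, lo, hi, xtol=1e-10)
    return float(d)


def make_drive_scheme(d_min: float, N: int, kind: str) -> DriveScheme:
    """Build a drive scheme of ``N`` levels from ``d_min`` up to full drive 1.

    ``linear`` spaces the drives equally; ``logarithmic`` spaces them
    geometrically, ``d_j = d_min**((N-j)/(N-1))``, putting more levels at the
    low end of the range.
    """
    if not (0 < d_min < 1):
        raise ValueError(f"d_min must lie in (0, 1), got {d_min}")
    if N < 2:
        raise ValueError(f"need at least 2 drive levels, got {N}")
    if kind == "linear":
        drives = np.linspace(d_min, 1.0, N)
    elif kind == "logarithmic":
        j = np.arange(1, N + 1)
        drives = d_min ** ((N - j) / (N - 1))
    else:
        raise ValueError(f"unknown sampling kind {kind!r}")
    drives[-1] = 1.0
    return DriveScheme(drives=tuple(drives), scheme_kind=kind)
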