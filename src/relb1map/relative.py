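"""Relative transmit-field maps from per-channel reconstructed images.

Dividing each channel image by the sum of all channel magnitudes cancels the
receive field, proton density and relaxation weighting common to every
channel, leaving a quantity proportional to each channel's share of the
transmit field (with phase preserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RelativeMaps", "relative_map", "relative_phase"]


@dataclass(frozen=True)
class RelativeMaps:
    """Per-channel complex relative sensitivity maps.

    At every voxel where ``valid`` is True the channel magnitudes sum to 1.
    Voxels where all channels are zero are flagged invalid and set to 0.
    """

    rT: np.ndarray  # complex, shape (n_channels, *spatial)
    valid: np.ndarray  # bool, shape (*spatial)
    channel_ids: tuple


def relative_map(images, channel_ids=None) -> RelativeMaps:
    """Form relative maps rT_j = I_j / sum_c |I_c| voxelwise.

    ``images`` is a complex array of shape (n_channels, *spatial). Voxels with
    zero denominator are set to 0 and flagged in the ``valid`` mask.
    """
    I = np.asarray(images, dtype=complex)
    if I.ndim < 2:
        raise ValueError("images must have shape (n_channels, *spatial)")
    denom = np.sum(np.abs(I), axis=0)
    valid = denom > 0
    rT = np.zeros_like(I)
    np.divide(I, denom, out=rT, where=valid)
    if channel_ids is None:
        channel_ids = tuple(range(I.shape[0]))
    elif len(channel_ids) != I.shape[0]:
        raise ValueError("channel_ids length must match number of channels")
    return RelativeMaps(rT=rT, valid=valid, channel_ids=tuple(channel_ids))


def relative_phase(images, reference=None) -> np.ndarray:
    """Per-channel phase maps, optionally relative to a reference channel.

    With ``reference`` set to a channel index, returns
    ``arg(I_j) - arg(I_ref)`` wrapped to (-pi, pi]; with ``reference=None``
    returns the raw ``arg(I_j)``.
    """
    I = np.asarray(images, dtype=complex)
    if I.ndim < 2:
        raise ValueError("images must have shape (n_channels, *spatial)")
    phase = np.angle(I)
    if reference is None:
        return phase
    n_ch = I.shape[0]
    if not (isinstance(reference, (int, np.integer)) and 0 <= reference < n_ch):
        raise ValueError(f"reference must be a channel index in [0, {n_ch}), got {reference!r}")
    rel = phase - phase[reference]
    return wrap_phase(rel)


def wrap_phase(phase) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    phase = np.asarray(phase, dtype=float)
    wrapped = np.mod(-phase + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)
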