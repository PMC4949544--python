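"""NIfTI and sidecar I/O for complex multi-channel, multi-drive image stacks.

Complex images are stored as paired real/imaginary NIfTI volumes (suffixes
``_real`` / ``_imag``) for maximal viewer compatibility. A JSON sidecar
carries the acquisition metadata: the RF drive scales, the noise level, the
channel labels and provenance. The method is purely voxelwise, so NIfTI
affines are passed through untouched and no resampling ever happens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .signal_model import DriveScheme

__all__ = ["Sidecar", "read_sidecar", "write_stack", "read_stack", "write_outputs"]


@dataclass(frozen=True)
class Sidecar:
    """Acquisition metadata stored alongside the image stack."""

    drives: tuple
    channel_ids: tuple
    sigma: float | None = None
    params: dict | None = None
    provenance: dict | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.drives, dtype=float)
        if d.size == 0 or (d.size > 1 and not np.all(np.diff(d) > 0)):
            raise ValueError("sidecar drives must be non-empty and ascending")
        if len(self.channel_ids) == 0:
            raise ValueError("sidecar must list at least one channel")

    def drive_scheme(self) -> DriveScheme:
        return DriveScheme(drives=tuple(self.drives))


def read_sidecar(path) -> Sidecar:
    data = json.loads(Path(path).read_text())
    return Sidecar(
        drives=tuple(data["drives"]),
        channel_ids=tuple(data["channel_ids"]),
        sigma=data.get("sigma"),
        params=data.get("params"),
        provenance=data.get("provenance"),
    )


def _pair_paths(directory: Path, channel, j: int):
    stem = f"ch{channel}_d{j:02d}"
    return directory / f"{stem}_real.nii.gz", directory / f"{stem}_imag.nii.gz"


def _save_nifti(data: np.ndarray, path: Path, affine=None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    if not path.exists():
        raise IOError(f"missing image file: {path}")
    return np.asarray(nib.load(str(path)).dataobj)


def write_stack(stack, sidecar: Sidecar, out_dir, affine=None) -> Path:
    """Write a complex stack (n_channels, n_drives, *spatial) as real/imag
    NIfTI pairs plus the JSON sidecar. Returns the sidecar path."""
    stack = np.asarray(stack, dtype=complex)
    n_ch, n_dr = stack.shape[:2]
    if n_ch != len(sidecar.channel_ids) or n_dr != len(sidecar.drives):
        raise ValueError(
            f"stack shape {stack.shape} inconsistent with sidecar "
            f"({len(sidecar.channel_ids)} channels, {len(sidecar.drives)} drives)"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c, ch in enumerate(sidecar.channel_ids):
        for j in range(n_dr):
            p_re, p_im = _pair_paths(out_dir, ch, j)
            _save_nifti(stack[c, j].real, p_re, affine)
            _save_nifti(stack[c, j].imag, p_im, affine)
    sc_path = out_dir / "sidecar.json"
    sc_path.write_text(json.dumps(asdict(sidecar), indent=2))
    return sc_path


def read_stack(directory, sidecar: Sidecar | None = None):
    """Read a complex stack written by :func:`write_stack`.

    Returns (stack, sidecar). Validates that every real/imaginary pair is
    present and that image dimensions agree across channels and drives.
    """
    directory = Path(directory)
    if sidecar is None:
        sidecar = read_sidecar(directory / "sidecar.json")
    n_dr = len(sidecar.drives)
    images = []
    shape = None
    for ch in sidecar.channel_ids:
        per_drive = []
        for j in range(n_dr):
            p_re, p_im = _pair_paths(directory, ch, j)
            re, im = _load_nifti(p_re), _load_nifti(p_im)
            if re.shape != im.shape:
                raise ValueError(f"real/imag shape mismatch for {p_re.name}")
            if shape is None:
                shape = re.shape
            elif re.shape != shape:
                raise ValueError(
                    f"inconsistent image dimensions: {re.shape} vs {shape}"
                )
            per_drive.append(re + 1j * im)
        images.append(per_drive)
    return np.asarray(images), sidecar


def write_outputs(
    out_dir,
    gamma=None,
    k_max=None,
    maps=None,
    channel_ids=None,
    settings=None,
    affine=None,
) -> dict:
    """Write reconstruction products: per-channel signal estimates
    (real/imag pairs), the integer k_max map, relative-map magnitude/phase
    volumes with the valid-voxel mask, and a JSON run log.

    Returns a dict mapping product names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    if gamma is not None:
        gamma = np.asarray(gamma, dtype=complex)
        ids = channel_ids if channel_ids is not None else range(gamma.shape[0])
        for c, ch in enumerate(ids):
            p_re = out_dir / f"gamma_ch{ch}_real.nii.gz"
            p_im = out_dir / f"gamma_ch{ch}_imag.nii.gz"
            _save_nifti(gamma[c].real, p_re, affine)
            _save_nifti(gamma[c].imag, p_im, affine)
            written[f"gamma_ch{ch}"] = (p_re, p_im)
    if k_max is not None:
        p = out_dir / "kmax.nii.gz"
        _save_nifti(np.asarray(k_max, dtype=np.int16), p, affine)
        written["kmax"] = p
    if maps is not None:
        ids = maps.channel_ids
        for c, ch in enumerate(ids):
            p_mag = out_dir / f"rT_ch{ch}_mag.nii.gz"
            p_ph = out_dir / f"rT_ch{ch}_phase.nii.gz"
            _save_nifti(np.abs(maps.rT[c]), p_mag, affine)
            _save_nifti(np.angle(maps.rT[c]), p_ph, affine)
            written[f"rT_ch{ch}"] = (p_mag, p_ph)
        p_valid = out_dir / "rT_valid_mask.nii.gz"
        _save_nifti(maps.valid.astype(np.uint8), p_valid, affine)
        written["valid_mask"] = p_valid
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(settings or {}, indent=2, default=str))
    written["run_log"] = log_path
    return written
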