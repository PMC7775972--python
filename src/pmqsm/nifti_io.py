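"""NIfTI reading/writing helpers.

Simulated acquisitions are stored as one 4-D magnitude and one 4-D phase
file per coil per repeat (echo as the 4th dimension); maps are 3-D volumes.
The affine encodes the voxel size on the diagonal (the synthetic frames
have no rotation component).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .params import AcquisitionParams
from .phantom import MultiCoilEchoData


def _affine(voxel_size_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(volume: np.ndarray, path, voxel_size_mm=(1, 1, 1),
                description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_size_mm))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_acquisition(data: MultiCoilEchoData, out_dir) -> None:
    """Write magnitude/phase 4-D NIfTI pairs, one per coil per repeat."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = data.params.voxel_size_mm
    for r in range(data.n_repeats):
        for c in range(data.n_coils):
            vols = np.moveaxis(data.data[r, c], 0, -1)  # echo last
            save_volume(np.abs(vols), out / f"rep{r + 1}_coil{c + 1}_mag.nii.gz",
                        vox)
            save_volume(np.angle(vols), out / f"rep{r + 1}_coil{c + 1}_phase.nii.gz",
                        vox)


def load_acquisition(in_dir, params: AcquisitionParams) -> MultiCoilEchoData:
    """Read the magnitude/phase pairs written by :func:`save_acquisition`."""
    in_dir = Path(in_dir)
    mags = sorted(in_dir.glob("rep*_coil*_mag.nii.gz"))
    if not mags:
        raise FileNotFoundError(f"no rep*_coil*_mag.nii.gz files in {in_dir}")
    reps = sorted({int(p.name.split("_")[0][3:]) for p in mags})
    coils = sorted({int(p.name.split("_")[1][4:]) for p in mags})
    first = load_volume(mags[0])
    shape = first.shape[:3]
    n_echo = first.shape[3]
    data = np.empty((len(reps), len(coils), n_echo) + shape, dtype=complex)
    for ri, r in enumerate(reps):
        for ci, c in enumerate(coils):
            mag = load_volume(in_dir / f"rep{r}_coil{c}_mag.nii.gz")
            ph = load_volume(in_dir / f"rep{r}_coil{c}_phase.nii.gz")
            data[ri, ci] = np.moveaxis(mag * np.exp(1j * ph), -1, 0)
    return MultiCoilEchoData(data=data, params=params)
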