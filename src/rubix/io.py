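"""NIfTI dataset bundles, grid-alignment checks and output writers.

Conventions: voxel indices are 0-based; world coordinates go through the
NIfTI affine; bvecs are stored in the image frame (FSL dialect).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import GradientScheme

__all__ = [
    "DatasetBundle",
    "load_bundle",
    "check_alignment",
    "save_nifti",
    "save_parameter_maps",
    "voxel_volume_reduction_percent",
]


def voxel_volume_reduction_percent(fine_voxel_mm, coarse_voxel_mm) -> float:
    """Percent decrease in voxel volume of the finer grid vs the coarser.

    E.g. 1.05 mm vs 1.25 mm isotropic: 100 * (1 - 1.05^3/1.25^3) ~ 40.7%.
    """
    fine = np.prod(np.asarray(fine_voxel_mm, dtype=float))
    coarse = np.prod(np.asarray(coarse_voxel_mm, dtype=float))
    if fine <= 0 or coarse <= 0:
        raise ValueError("voxel sizes must be positive")
    return float(100.0 * (1.0 - fine / coarse))


@dataclass
class DatasetBundle:
    """One diffusion dataset: 4-D data, gradient table, mask and geometry."""

    data: np.ndarray  # (X, Y, Z, K)
    scheme: GradientScheme
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # 4x4
    voxel_sizes: tuple  # mm

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]


def load_bundle(data_path, bvals_path, bvecs_path, mask_path=None) -> DatasetBundle:
    """Load and validate a dataset bundle (.nii or .nii.gz accepted).

    Raises with an informative message when the number of volumes does not
    match the gradient table or the mask grid differs from the data grid.
    """
    img = nib.load(str(data_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{data_path}: expected a 4-D volume, got shape {data.shape}")
    scheme = GradientScheme.from_files(bvals_path, bvecs_path)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"{data_path}: {data.shape[3]} volumes but gradient table has "
            f"{len(scheme)} entries"
        )
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask grid {mask.shape} does not match data grid {data.shape[:3]}"
            )
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    voxel_sizes = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DatasetBundle(
        data=data, scheme=scheme, mask=mask, affine=np.asarray(img.affine),
        voxel_sizes=voxel_sizes,
    )


def check_alignment(hr: DatasetBundle, lr: DatasetBundle, rel_tol: float = 1e-3):
    """Per-axis integer LR/HR voxel-size ratio, or an error with guidance.

    The fusion model requires LR voxel sizes to be integer multiples of the
    HR ones (within ``rel_tol`` relative tolerance) and coinciding grid
    origins.
    """
    ratio = []
    for ax, (h, l) in enumerate(zip(hr.voxel_sizes, lr.voxel_sizes)):
        r = l / h
        r_int = int(round(r))
        if r_int < 1 or abs(r - r_int) > rel_tol * r_int:
            raise ValueError(
                f"axis {ax}: LR voxel size {l} mm is not an integer multiple of "
                f"HR voxel size {h} mm (ratio {r:.4f}); resample the LR data "
                "first (e.g. downsample_volume to twice the HR voxel size)"
            )
        ratio.append(r_int)
    origin_hr = hr.affine[:3, 3]
    origin_lr = lr.affine[:3, 3]
    tol = max(hr.voxel_sizes) * 0.5
    if np.any(np.abs(origin_hr - origin_lr) > tol):
        raise ValueError(
            f"grid origins differ beyond tolerance ({origin_hr} vs {origin_lr}); "
            "align the datasets before fusion"
        )
    return tuple(ratio)


def save_nifti(volume, affine, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), np.asarray(affine))
    nib.save(img, str(path))


def save_parameter_maps(samples, affine, out_dir) -> list:
    """Write the sampler's summary maps as NIfTI files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, vol in samples.parameter_maps().items():
        p = out_dir / f"{name}.nii.gz"
        save_nifti(np.nan_to_num(vol), affine, p)
        paths.append(p)
    return paths
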