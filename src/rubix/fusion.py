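"""Spatial partial-volume model linking low- and high-resolution grids.

A low-resolution (LR) voxel intersects P high-resolution (HR) voxels with
fractions a_p (sum 1).  Under the integer-ratio constraint used throughout
(P HR voxels fit exactly inside one LR voxel) a_p = 1/P and the HR grid is
partitioned into disjoint neighborhoods — the unit of joint inference.

The LR signal prediction is a signal-weighted ratio::

    S_l^LR / S0^LR = (sum_p a_p S_{l,p}^HR) / (sum_p a_p S0_p^HR)

rather than a sum of attenuations; the ratio form is less sensitive to
averaging signal across tissue types, which matters at tissue boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localmodel import VoxelParams, predict_voxel_signal
from .schemes import GradientScheme

__all__ = [
    "NeighborhoodMap",
    "NeighborhoodModel",
    "predict_lr_signal",
    "build_neighborhoods",
    "downsample_volume",
]


@dataclass(frozen=True)
class NeighborhoodMap:
    """One LR voxel and the P HR voxels it intersects."""

    lr_index: tuple
    hr_indices: tuple  # P tuples of HR voxel coordinates
    weights: np.ndarray  # a_p, sum to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.hr_indices) != w.size:
            raise ValueError("weights and hr_indices lengths differ")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights a_p must be positive and sum to 1")
        object.__setattr__(self, "hr_indices", tuple(map(tuple, self.hr_indices)))
        object.__setattr__(self, "weights", w)

    @property
    def P(self) -> int:
        return len(self.hr_indices)


@dataclass
class NeighborhoodModel:
    """Joint parameters of one neighborhood: P HR voxels + LR baseline/noise."""

    map: NeighborhoodMap
    hr_params: list  # P VoxelParams
    S0_LR: float
    tau_LR: float = 1.0
    tau_HR: np.ndarray | None = None  # per-HR-voxel precisions

    def __post_init__(self) -> None:
        if len(self.hr_params) != self.map.P:
            raise ValueError("hr_params length must equal P")
        if not self.S0_LR > 0:
            raise ValueError("S0_LR must be positive")
        if not self.tau_LR > 0:
            raise ValueError("tau_LR must be positive")
        if self.tau_HR is None:
            self.tau_HR = np.array([vp.tau for vp in self.hr_params])
        self.tau_HR = np.asarray(self.tau_HR, dtype=float)
        if np.any(self.tau_HR <= 0):
            raise ValueError("every tau_HR must be positive")


def predict_lr_signal(model: NeighborhoodModel, lr_scheme: GradientScheme | None) -> np.ndarray:
    """LR signal prediction of length L from the neighborhood's HR parameters.

    The LR scheme may differ from the HR scheme in both b-values and
    directions: each HR voxel's local model is simply evaluated at the LR
    measurement points.
    """
    if lr_scheme is None or len(lr_scheme) == 0:
        return np.empty(0)
    a = model.map.weights
    denom = float(np.sum(a * np.array([vp.S0 for vp in model.hr_params])))
    if denom == 0.0:
        raise ZeroDivisionError("degenerate neighborhood: sum_p a_p S0_p == 0")
    num = np.zeros(len(lr_scheme))
    for w, vp in zip(a, model.hr_params):
        num += w * predict_voxel_signal(vp, lr_scheme)
    return model.S0_LR * num / denom


def build_neighborhoods(hr_grid_shape, per_axis_ratio) -> list[NeighborhoodMap]:
    """Partition an HR grid into LR neighborhoods under an integer ratio.

    Every HR voxel belongs to exactly one neighborhood; P = prod(ratio) and
    all weights are 1/P.
    """
    hr_shape = tuple(int(s) for s in hr_grid_shape)
    ratio = tuple(int(r) for r in per_axis_ratio)
    if len(hr_shape) != 3 or len(ratio) != 3:
        raise ValueError("expected 3-D grid shape and per-axis ratio")
    if any(r < 1 for r in ratio):
        raise ValueError("per-axis ratio entries must be >= 1")
    if any(s % r != 0 for s, r in zip(hr_shape, ratio)):
        raise ValueError(
            f"per-axis ratio {ratio} does not divide HR grid shape {hr_shape}; "
            "the spatial model requires an integer LR/HR voxel ratio"
        )
    lr_shape = tuple(s // r for s, r in zip(hr_shape, ratio))
    P = ratio[0] * ratio[1] * ratio[2]
    weights = np.full(P, 1.0 / P)
    maps = []
    for i in range(lr_shape[0]):
        for j in range(lr_shape[1]):
            for k in range(lr_shape[2]):
                hr_idx = [
                    (i * ratio[0] + di, j * ratio[1] + dj, k * ratio[2] + dk)
                    for di in range(ratio[0])
                    for dj in range(ratio[1])
                    for dk in range(ratio[2])
                ]
                maps.append(
                    NeighborhoodMap(lr_index=(i, j, k), hr_indices=tuple(hr_idx),
                                    weights=weights.copy())
                )
    return maps


def downsample_volume(data, per_axis_factor) -> np.ndarray:
    """Block-mean downsampling of a 3-D or 4-D volume.

    Magnitude signals are averaged (not log-signals), matching the physical
    forward model of an LR acquisition over the same tissue.  The 4th
    (diffusion) axis, if present, is untouched.
    """
    data = np.asarray(data, dtype=float)
    factor = tuple(int(f) for f in per_axis_factor)
    if len(factor) != 3:
        raise ValueError("per_axis_factor must have 3 entries")
    spatial = data.shape[:3]
    if any(s % f != 0 for s, f in zip(spatial, factor)):
        raise ValueError(
            f"factor {factor} does not divide spatial shape {spatial}"
        )
    nx, ny, nz = (s // f for s, f in zip(spatial, factor))
    fx, fy, fz = factor
    rest = data.shape[3:]
    reshaped = data.reshape(nx, fx, ny, fy, nz, fz, *rest)
    return reshaped.mean(axis=(1, 3, 5))
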