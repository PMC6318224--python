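"""Synthetic paired HR/LR multi-shell phantoms with known ground truth.

The generator emulates the two acquisition families the fusion model is
designed for: a low-resolution, angularly rich 3-shell protocol
(b = 1000/2000/3000 s/mm^2, ~90 directions/shell) and a high-resolution
2-shell protocol (b = 1000/2000, ~65 directions/shell), on aligned grids
with an integer per-axis voxel-size ratio.  Noise is Rician at a
controllable SNR (S0/sigma at b = 0), matching the magnitude
reconstruction the likelihood assumes.  An optional sub-voxel misalignment
of the HR field before LR synthesis provides a registration-error stress
case.

What it deliberately does not emulate: EPI distortion, eddy currents, PSF
blurring along the phase-encode direction, or field-strength-dependent
relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fusion import build_neighborhoods
from .localmodel import (
    BallParams,
    FibreCompartment,
    KernelParams,
    VoxelParams,
    predict_voxel_signal,
)
from .schemes import GradientScheme

__all__ = [
    "PhantomSpec",
    "make_scheme",
    "make_fibre_field",
    "simulate_pair",
    "add_rician_noise",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

FIELD_KINDS = ("single", "crossing90", "crossing60", "three_way", "boundary_csf", "fanning")


def make_scheme(
    shells,
    n_dirs_per_shell: int,
    n_b0: int = 5,
    seed: int = 0,
    n_iter: int = 200,
) -> GradientScheme:
    """Multi-shell gradient table with near-uniform directions.

    Directions are spread by electrostatic repulsion of antipodal point
    pairs on the sphere (the same direction set is reused on every shell,
    as in typical multi-shell protocols).  Deterministic given ``seed``.
    """
    if n_dirs_per_shell < 6:
        raise ValueError("need at least 6 directions per shell")
    dirs = _repulsion_directions(n_dirs_per_shell, seed=seed, n_iter=n_iter)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for b in shells:
        bvals.append(np.full(n_dirs_per_shell, float(b)))
        bvecs.append(dirs)
    return GradientScheme(bvals=np.concatenate(bvals), bvecs=np.vstack(bvecs))


def _repulsion_directions(n: int, seed: int = 0, n_iter: int = 200, step: float = 0.05):
    """Approximately uniform antipodally symmetric unit vectors."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                dist2[dist2 < 1e-12] = np.inf  # a point vs its own antipode
            force += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        # project force onto the tangent plane and take a small step
        force -= v * np.sum(force * v, axis=1, keepdims=True)
        v += step * force / n
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def min_nearest_neighbour_angle(bvecs) -> float:
    """Smallest pairwise angular separation (degrees, antipodally folded)."""
    v = np.asarray(bvecs, dtype=float)
    dots = np.abs(v @ v.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(axis=1), 0, 1)).min()))


@dataclass
class PhantomSpec:
    """Study conditions for one paired phantom."""

    hr_grid_shape: tuple = (6, 6, 6)
    per_axis_ratio: tuple = (2, 2, 2)
    hr_shells: tuple = (1000.0, 2000.0)
    hr_dirs_per_shell: int = 65
    hr_n_b0: int = 6
    lr_shells: tuple = (1000.0, 2000.0, 3000.0)
    lr_dirs_per_shell: int = 90
    lr_n_b0: int = 5
    field_kind: str = "crossing90"
    snr_hr: float = 20.0
    snr_lr: float = 40.0
    S0: float = 1000.0
    misalignment_shift: tuple | None = None  # sub-voxel HR shift, in HR voxels
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_hr <= 0 or self.snr_lr <= 0:
            raise ValueError("SNR values must be positive")

    def hr_scheme(self) -> GradientScheme:
        return make_scheme(self.hr_shells, self.hr_dirs_per_shell, self.hr_n_b0,
                           seed=self.rng_seed)

    def lr_scheme(self) -> GradientScheme:
        return make_scheme(self.lr_shells, self.lr_dirs_per_shell, self.lr_n_b0,
                           seed=self.rng_seed + 1)


def _wm_ball() -> BallParams:
    return BallParams(d_m=1.0e-3, d_std=1.0e-4)


def _csf_ball() -> BallParams:
    # fast, broadly distributed isotropic diffusion
    return BallParams(d_m=3.0e-3, d_std=1.0e-3)


def _kernel() -> KernelParams:
    return KernelParams(lambda_m=1.0e-3, lambda_R=0.13)


def _vox(S0, ball, fibres) -> VoxelParams:
    return VoxelParams(S0=S0, ball=ball, kernel=_kernel(), fibres=tuple(fibres))


def make_fibre_field(kind: str, grid_shape, S0: float = 1000.0) -> np.ndarray:
    """Ground-truth VoxelParams per HR voxel for a named configuration.

    Kinds: ``single`` (f1 = 0.7 along +x), ``crossing90`` / ``crossing60``
    (two populations, f = 0.35 each), ``three_way`` (three populations,
    f = 0.25 each), ``boundary_csf`` (WM slab against a pure-CSF slab) and
    ``fanning`` (orientation rotating smoothly across the grid).
    """
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3:
        raise ValueError("grid_shape must be 3-D")
    out = np.empty(shape, dtype=object)
    v60 = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0.0])

    if kind == "single":
        vp = _vox(S0, _wm_ball(), [FibreCompartment(0.7, _X)])
        out[...] = vp
    elif kind == "crossing90":
        vp = _vox(S0, _wm_ball(),
                  [FibreCompartment(0.35, _X), FibreCompartment(0.35, _Y)])
        out[...] = vp
    elif kind == "crossing60":
        vp = _vox(S0, _wm_ball(),
                  [FibreCompartment(0.35, _X), FibreCompartment(0.35, v60)])
        out[...] = vp
    elif kind == "three_way":
        vp = _vox(S0, _wm_ball(),
                  [FibreCompartment(0.25, _X), FibreCompartment(0.25, _Y),
                   FibreCompartment(0.25, _Z)])
        out[...] = vp
    elif kind == "boundary_csf":
        wm = _vox(S0, _wm_ball(), [FibreCompartment(0.7, _X)])
        csf = _vox(S0, _csf_ball(), [])  # f_AN = 0 on the CSF side
        half = shape[2] // 2
        out[..., :half] = wm
        out[..., half:] = csf
    elif kind == "fanning":
        for i in range(shape[0]):
            ang = np.pi / 3 * (i / max(shape[0] - 1, 1) - 0.5)
            v = np.array([np.cos(ang), np.sin(ang), 0.0])
            out[i, ...] = _vox(S0, _wm_ball(), [FibreCompartment(0.6, v)])
    else:
        raise ValueError(f"unknown fibre-field kind {kind!r}; choose from {FIELD_KINDS}")
    return out


def add_rician_noise(signal, sigma: float, rng) -> np.ndarray:
    """Magnitude of (S + e1, e2) with e ~ N(0, sigma^2): Rician noise."""
    signal = np.asarray(signal, dtype=float)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def simulate_pair(spec: PhantomSpec):
    """Simulate one paired phantom.

    Returns ``(hr_data, lr_data, truth)``.  ``truth`` carries the parameter
    field, both schemes, the noise-free signal cubes and noise sigmas.  The
    LR data are generated through the same signal-ratio spatial model used
    in inference; with ``misalignment_shift`` set, the noise-free HR signal
    field is first shifted trilinearly (registration-error stress case).
    """
    hr_scheme = spec.hr_scheme()
    lr_scheme = spec.lr_scheme()
    field = make_fibre_field(spec.field_kind, spec.hr_grid_shape, S0=spec.S0)
    shape = field.shape
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.rng_seed), 2)))

    hr_clean = np.empty(shape + (len(hr_scheme),))
    hr_at_lr = np.empty(shape + (len(lr_scheme),))  # HR-voxel signals at LR points
    S0_field = np.empty(shape)
    cache: dict[int, tuple] = {}
    for idx in np.ndindex(shape):
        vp = field[idx]
        key = id(vp)
        if key not in cache:
            cache[key] = (
                predict_voxel_signal(vp, hr_scheme),
                predict_voxel_signal(vp, lr_scheme),
            )
        hr_clean[idx], hr_at_lr[idx] = cache[key]
        S0_field[idx] = vp.S0

    if spec.misalignment_shift is not None:
        shift = tuple(spec.misalignment_shift) + (0.0,)
        hr_at_lr = ndimage.shift(hr_at_lr, shift, order=1, mode="nearest")
        S0_field = ndimage.shift(S0_field, spec.misalignment_shift, order=1,
                                 mode="nearest")

    # LR synthesis through the spatial model: signal-weighted neighborhood ratio
    maps = build_neighborhoods(shape, spec.per_axis_ratio)
    lr_shape = tuple(s // r for s, r in zip(shape, spec.per_axis_ratio))
    lr_clean = np.empty(lr_shape + (len(lr_scheme),))
    for nb in maps:
        a = nb.weights
        sig = np.array([hr_at_lr[idx] for idx in nb.hr_indices])
        s0 = np.array([S0_field[idx] for idx in nb.hr_indices])
        S0_LR = float(np.sum(a * s0))  # LR baseline: volume-weighted HR baseline
        lr_clean[nb.lr_index] = S0_LR * (a @ sig) / np.sum(a * s0)

    sigma_hr = spec.S0 / spec.snr_hr
    sigma_lr = spec.S0 / spec.snr_lr
    hr_data = add_rician_noise(hr_clean, sigma_hr, rng)
    lr_data = add_rician_noise(lr_clean, sigma_lr, rng)

    truth = {
        "field": field,
        "hr_scheme": hr_scheme,
        "lr_scheme": lr_scheme,
        "hr_clean": hr_clean,
        "lr_clean": lr_clean,
        "sigma_hr": sigma_hr,
        "sigma_lr": sigma_lr,
        "spec": spec,
    }
    return hr_data, lr_data, truth


def true_orientations(field) -> np.ndarray:
    """(X, Y, Z, N_max, 3) array of ground-truth orientations (NaN-padded)."""
    shape = field.shape
    n_max = max(len(field[idx].fibres) for idx in np.ndindex(shape))
    n_max = max(n_max, 1)
    out = np.full(shape + (n_max, 3), np.nan)
    for idx in np.ndindex(shape):
        for n, fc in enumerate(field[idx].fibres):
            out[idx + (n,)] = fc.v
    return out
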