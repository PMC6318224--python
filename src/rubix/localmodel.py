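"""Voxel-wise forward model for parametric spherical deconvolution.

The diffusion-attenuated signal in a voxel is a partial-volume mixture of an
isotropic "ball" compartment and up to N anisotropic fibre compartments::

    S_k = S0 [ (1 - sum_n f_n) E_ball(b_k) + sum_n f_n E_fibre(b_k, g_k; v_n) ]

The ball carries a Gamma distribution of diffusivities (mean ``d_m``,
standard deviation ``d_std``), whose Laplace transform gives the attenuation
``(beta / (beta + b))**alpha`` with ``beta = d_m/d_std^2``,
``alpha = d_m*beta``.  Each fibre is the impulse response of an axially
symmetric tensor with mean eigenvalue ``lambda_m`` and radial/axial ratio
``lambda_R = lambda_2/lambda_1``; the fODF is a sum of spherical delta
functions so the convolution collapses onto the kernel evaluated at the
fibre orientations.  The model constrains ``lambda_m = d_m`` so that both
compartments share a mean diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schemes import GradientScheme

__all__ = [
    "BallParams",
    "KernelParams",
    "FibreCompartment",
    "VoxelParams",
    "ball_attenuation",
    "kernel_attenuation",
    "predict_voxel_signal",
]

#: below this d_std (mm^2/s) the Gamma ball is numerically mono-exponential
DSTD_MONOEXP_THRESHOLD = 1e-7

_UNIT_TOL = 1e-6


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError(f"{name} must be a 3-vector")
    if np.any(np.abs(np.linalg.norm(v, axis=-1) - 1.0) > _UNIT_TOL):
        raise ValueError(f"{name} must have unit norm")
    return v


@dataclass(frozen=True)
class BallParams:
    """Isotropic compartment: Gamma-distributed diffusivities."""

    d_m: float  # mean diffusivity, mm^2/s
    d_std: float = 0.0  # std of the diffusivity distribution, mm^2/s

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_m) and self.d_m > 0):
            raise ValueError(f"d_m must be positive and finite, got {self.d_m}")
        if not (np.isfinite(self.d_std) and self.d_std >= 0):
            raise ValueError(f"d_std must be non-negative, got {self.d_std}")

    @property
    def beta(self) -> float:
        return self.d_m / self.d_std**2

    @property
    def alpha(self) -> float:
        return self.d_m * self.beta


@dataclass(frozen=True)
class KernelParams:
    """Axially symmetric single-fibre response tensor.

    ``lambda_m`` is the mean eigenvalue (mm^2/s) and ``lambda_R`` the
    radial-to-axial eigenvalue ratio lambda_2/lambda_1, in (0, 1).
    """

    lambda_m: float
    lambda_R: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda_m) and self.lambda_m > 0):
            raise ValueError(f"lambda_m must be positive, got {self.lambda_m}")
        if not (0.0 < self.lambda_R < 1.0):
            raise ValueError(f"lambda_R must lie in (0, 1), got {self.lambda_R}")


@dataclass(frozen=True)
class FibreCompartment:
    """One fODF delta: volume fraction f and unit orientation v (v == -v)."""

    f: float
    v: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"fibre fraction must be in [0, 1], got {self.f}")
        object.__setattr__(self, "v", _check_unit(self.v, "fibre orientation"))


@dataclass(frozen=True)
class VoxelParams:
    """All per-voxel unknowns of the local model."""

    S0: float
    ball: BallParams
    kernel: KernelParams
    fibres: tuple = field(default_factory=tuple)
    tau: float = 1.0  # noise precision 1/sigma^2

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S0) and self.S0 > 0):
            raise ValueError(f"S0 must be positive, got {self.S0}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        fibres = tuple(self.fibres)
        total = sum(fc.f for fc in fibres)
        if total > 1.0 + 1e-12:
            raise ValueError(f"fibre fractions sum to {total} > 1")
        object.__setattr__(self, "fibres", fibres)

    @property
    def f_total(self) -> float:
        """Total anisotropic volume fraction f_AN."""
        return sum(fc.f for fc in self.fibres)


def ball_attenuation(b, ball: BallParams) -> np.ndarray:
    """Attenuation of the Gamma-ball compartment at weighting(s) ``b``.

    Returns ``(beta/(beta + b))**alpha``; for ``d_std`` below
    :data:`DSTD_MONOEXP_THRESHOLD` the analytic mono-exponential limit
    ``exp(-b d_m)`` is used to avoid alpha/beta overflow.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or not np.all(np.isfinite(b)):
        raise ValueError("b-values must be finite and non-negative")
    if ball.d_std < DSTD_MONOEXP_THRESHOLD:
        return np.exp(-b * ball.d_m)
    beta = ball.beta
    return (beta / (beta + b)) ** ball.alpha


def kernel_attenuation(b, g, kernel: KernelParams, v) -> np.ndarray:
    """Single-fibre attenuation exp(-b 3*lam_m/(2*lam_R+1) [(1-lam_R)(g.v)^2 + lam_R]).

    ``g`` may be (3,) or (K, 3); broadcasting against ``b`` follows numpy
    rules.  Invariant under v -> -v.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0) or not np.all(np.isfinite(b)):
        raise ValueError("b-values must be finite and non-negative")
    g = np.asarray(g, dtype=float)
    v = _check_unit(v, "v")
    dot = g @ v
    lam_R = kernel.lambda_R
    scale = 3.0 * kernel.lambda_m / (2.0 * lam_R + 1.0)
    return np.exp(-b * scale * ((1.0 - lam_R) * dot**2 + lam_R))


def predict_voxel_signal(params: VoxelParams, scheme: GradientScheme) -> np.ndarray:
    """Predicted signal vector (length K) for one voxel under ``scheme``."""
    f_total = params.f_total  # validated <= 1 on construction
    iso = ball_attenuation(scheme.bvals, params.ball)
    signal = (1.0 - f_total) * iso
    for fc in params.fibres:
        if fc.f == 0.0:
            continue
        signal = signal + fc.f * kernel_attenuation(
            scheme.bvals, scheme.bvecs, params.kernel, fc.v
        )
    return params.S0 * signal
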