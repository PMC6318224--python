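"""Prior densities for the deconvolution model.

All densities are returned as (possibly unnormalised) log densities and are
-inf outside their support.  The priors are:

* ``S0``, ``tau`` — flat on (0, inf) (improper; handled by support checks).
* ``f_1`` — uniform on [0, 1]; ``f_n, n >= 2`` — automatic relevance
  determination (ARD) shrinkage ``p(f) ∝ 1/f^w``, which switches off fibre
  compartments the data do not support.  ``w < 1`` relaxes the penalty.
* ``d_m`` — Gamma(shape 3, scale 0.25e-3 mm^2/s), peaking near diffusivities
  seen in brain parenchyma.
* ``d_std`` — ARD ``p ∝ 1/d_std``, encouraging a single diffusion
  coefficient per voxel.
* ``lambda_R`` — Gaussian N(mu, sigma^2) truncated to (0, 1); the
  hyper-parameters are learned from coherent white matter (corpus callosum)
  via :func:`learn_response_prior`.
* orientations — uniform on the sphere in the voxel-wise model; in the
  fusion model a mixture of Watson distributions whose modes/concentrations
  are neighborhood-level hyper-parameters estimated from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, special, stats

from .tensor import fractional_anisotropy

__all__ = [
    "PriorConfig",
    "OrientationPriorState",
    "log_prior_fractions",
    "log_prior_dm",
    "log_prior_dstd",
    "log_prior_lambdaR",
    "watson_log_kappa_normaliser",
    "watson_log_prior",
    "learn_response_prior",
]

#: floor applied inside improper 1/x densities so proposals stay finite
ARD_FLOOR = 1e-8


@dataclass
class PriorConfig:
    """Hyper-parameters of all priors.

    ``ard_weight_w`` is the ARD severity on the volume fractions (1.0
    standard, 0.8 relaxed); ``lambdaR_mu``/``lambdaR_sigma`` default to the
    corpus-callosum group values (0.13, 0.03) and can be re-learned per
    dataset with :func:`learn_response_prior`.
    """

    ard_weight_w: float = 1.0
    dm_gamma_shape: float = 3.0
    dm_gamma_scale: float = 0.25e-3  # mm^2/s
    lambdaR_mu: float = 0.13
    lambdaR_sigma: float = 0.03
    fraction_floor: float = ARD_FLOOR
    n_watson_modes: int = 3
    watson_kappa_min: float = 0.01
    watson_kappa_max: float = 5000.0

    def __post_init__(self) -> None:
        if self.ard_weight_w <= 0:
            raise ValueError("ARD weight w must be positive")
        if self.dm_gamma_shape <= 0 or self.dm_gamma_scale <= 0:
            raise ValueError("Gamma hyper-parameters must be positive")
        if not (0 < self.lambdaR_mu < 1) or self.lambdaR_sigma <= 0:
            raise ValueError("lambda_R prior needs 0 < mu < 1 and sigma > 0")

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        import yaml

        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OrientationPriorState:
    """M Watson modes/concentrations shared across one neighborhood."""

    modes: np.ndarray  # (M, 3) unit vectors
    concentrations: np.ndarray  # (M,) kappa >= 0

    def __post_init__(self) -> None:
        modes = np.asarray(self.modes, dtype=float).reshape(-1, 3)
        kappa = np.atleast_1d(np.asarray(self.concentrations, dtype=float))
        if modes.shape[0] != kappa.size:
            raise ValueError("modes and concentrations lengths differ")
        if np.any(np.abs(np.linalg.norm(modes, axis=1) - 1.0) > 1e-6):
            raise ValueError("Watson modes must be unit vectors")
        if np.any(kappa < 0):
            raise ValueError("Watson concentrations must be >= 0")
        self.modes = modes
        self.concentrations = kappa

    @property
    def M(self) -> int:
        return self.modes.shape[0]


def log_prior_fractions(f, w: float, floor: float = ARD_FLOOR) -> float:
    """ARD log-prior on volume fractions: flat on f_1, -w*log f_n for n >= 2.

    Returns -inf when any fraction leaves [0, 1] or the sum exceeds 1.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f < 0) or np.any(f > 1) or f.sum() > 1.0 + 1e-12:
        return -np.inf
    if f.size <= 1:
        return 0.0
    return float(-w * np.sum(np.log(np.maximum(f[1:], floor))))


def log_prior_dm(d_m: float, shape: float = 3.0, scale: float = 0.25e-3) -> float:
    """Gamma log-prior on the mean diffusivity (mm^2/s)."""
    if not d_m > 0:
        return -np.inf
    return float(stats.gamma.logpdf(d_m, a=shape, scale=scale))


def log_prior_dstd(d_std: float, floor: float = ARD_FLOOR) -> float:
    """ARD log-prior p(d_std) ∝ 1/d_std (unnormalised)."""
    if not d_std > 0:
        return -np.inf
    return float(-np.log(max(d_std, floor)))


def log_prior_lambdaR(lam_R: float, mu: float = 0.13, sigma: float = 0.03) -> float:
    """Gaussian log-prior on the kernel eigenvalue ratio, truncated to (0, 1)."""
    if not (0.0 < lam_R < 1.0):
        return -np.inf
    return float(-0.5 * ((lam_R - mu) / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi)))


def watson_log_kappa_normaliser(kappa) -> np.ndarray:
    """log of the Watson normalising constant c(kappa) = 1/(4 pi M(1/2,3/2,kappa)).

    Uses the Kummer function directly for moderate kappa and its asymptotic
    expansion M(1/2,3/2,k) ~ e^k/(2k) (1 + 1/(2k)) for large kappa, where the
    direct evaluation overflows.
    """
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa, dtype=float)
    small = kappa < 600
    if np.any(small):
        out[small] = -np.log(4 * np.pi * special.hyp1f1(0.5, 1.5, kappa[small]))
    if np.any(~small):
        k = kappa[~small]
        log_m = k - np.log(2 * k) + np.log1p(0.5 / k)
        out[~small] = -np.log(4 * np.pi) - log_m
    return out


def watson_log_prior(v, state: OrientationPriorState) -> float:
    """Log-density of an equal-weight mixture of Watson distributions at v.

    Antipodally symmetric: density(v) == density(-v).
    """
    v = np.asarray(v, dtype=float)
    dots = state.modes @ v
    logc = watson_log_kappa_normaliser(state.concentrations)
    comps = logc + state.concentrations * dots**2
    return float(special.logsumexp(comps) - np.log(state.M))


def learn_response_prior(
    dti_eigenvalues: np.ndarray,
    cc_mask: np.ndarray,
    fa_top_fraction: float = 0.5,
    erode: bool = True,
):
    """Learn (mu, sigma) of the lambda_R prior from a coherent-WM mask.

    The mask (typically the corpus-callosum midbody) is eroded once with a
    6-connected structuring element, the voxels with the top
    ``fa_top_fraction`` FA values inside it are retained, and the mean and
    standard deviation of lambda_R = (l2 + l3) / (2 l1) across those voxels
    are returned.
    """
    evals = np.asarray(dti_eigenvalues, dtype=float)
    if evals.shape[-1] != 3:
        raise ValueError("eigenvalue array must end with axis of length 3")
    mask = np.asarray(cc_mask, dtype=bool)
    if mask.shape != evals.shape[:-1]:
        raise ValueError("mask shape does not match eigenvalue field")
    if not mask.any():
        raise ValueError("empty mask")
    if erode and mask.ndim == 3:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        eroded = ndimage.binary_erosion(mask, structure=structure)
        if eroded.any():
            mask = eroded
    sel = evals[mask]
    if np.any(sel[:, 0] <= 0):
        raise ValueError("principal eigenvalue must be positive inside the mask")
    fa = fractional_anisotropy(sel)
    n_keep = max(1, int(np.ceil(fa_top_fraction * fa.size)))
    keep = np.argsort(fa)[::-1][:n_keep]
    lam_R = (sel[keep, 1] + sel[keep, 2]) / (2.0 * sel[keep, 0])
    return float(lam_R.mean()), float(lam_R.std())
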