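"""Ordinary log-linear diffusion tensor fit.

Used for learning the response-anisotropy prior from coherent white matter,
for initialising MCMC chains, and for display conventions.  This is the
standard least-squares fit of log(S/S0) against the b-matrix; it makes no
attempt at robust/weighted variants.
"""

from __future__ import annotations

import numpy as np

from .schemes import GradientScheme

__all__ = ["dti_fit", "fractional_anisotropy"]


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    # columns: [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0]
    X = np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones(len(b)),
        ]
    )
    return X


def fractional_anisotropy(evals: np.ndarray) -> np.ndarray:
    """FA from eigenvalues; last axis holds (l1, l2, l3)."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def dti_fit(signals: np.ndarray, scheme: GradientScheme):
    """Log-linear least-squares tensor fit.

    Parameters
    ----------
    signals : (..., K) array
        Measured signals; any leading shape (single voxel, list, or volume).
    scheme : GradientScheme
        Needs at least 6 diffusion-weighted points and one b = 0.

    Returns
    -------
    dict with keys ``evals`` (..., 3) descending and clamped to >= 0,
    ``evecs`` (..., 3, 3) with ``evecs[..., :, i]`` the i-th eigenvector,
    ``fa`` (...,), ``md`` (...,), ``s0`` (...,), ``pdd`` (..., 3) the
    principal diffusion direction.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(scheme):
        raise ValueError("signal length does not match scheme")
    if np.count_nonzero(scheme.bvals > 0) < 6 or not np.any(scheme.b0_mask):
        raise ValueError("tensor fit needs >= 6 weighted points and >= 1 b=0")

    X = _design_matrix(scheme)
    lead = signals.shape[:-1]
    flat = signals.reshape(-1, signals.shape[-1])
    logS = np.log(np.clip(flat, 1e-12, None))
    coef, *_ = np.linalg.lstsq(X, logS.T, rcond=None)
    coef = coef.T  # (V, 7)

    V = coef.shape[0]
    D = np.empty((V, 3, 3))
    D[:, 0, 0] = coef[:, 0]
    D[:, 1, 1] = coef[:, 1]
    D[:, 2, 2] = coef[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 5]

    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = np.clip(evals[:, ::-1], 0.0, None)  # descending, non-negative
    evecs = evecs[:, :, ::-1]

    out = {
        "evals": evals.reshape(*lead, 3),
        "evecs": evecs.reshape(*lead, 3, 3),
        "fa": fractional_anisotropy(evals).reshape(lead),
        "md": evals.mean(axis=-1).reshape(lead),
        "s0": np.exp(coef[:, 6]).reshape(lead),
        "pdd": evecs[:, :, 0].reshape(*lead, 3),
    }
    return out
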