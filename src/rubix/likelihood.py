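"""Rician measurement likelihoods.

Magnitude MRI data with SENSE1-style reconstruction carry Rician noise: a
measurement Y given a noise-free prediction S and precision tau = 1/sigma^2
has density  tau * Y * exp(-tau (Y^2 + S^2)/2) * I0(tau * Y * S).  The
Bessel factor is evaluated through the exponentially scaled ``i0e`` so the
log-likelihood stays finite at high SNR where I0 itself overflows.
"""

from __future__ import annotations

import numpy as np
from scipy import special

from .fusion import NeighborhoodModel, predict_lr_signal
from .localmodel import predict_voxel_signal

__all__ = ["rician_log_likelihood", "joint_log_likelihood"]


def rician_log_likelihood(Y, S, tau: float) -> float:
    """Sum over measurements of the Rician log-density.

    ``log tau + log Y - tau (Y^2 + S^2)/2 + log I0(tau Y S)`` per point.
    Y_k = 0 contributes -inf (log 0), consistent with the density being a
    proper pdf on Y > 0.
    """
    Y = np.asarray(Y, dtype=float)
    S = np.asarray(S, dtype=float)
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs S {S.shape}")
    if not tau > 0:
        raise ValueError("tau must be positive")
    if np.any(Y < 0) or np.any(S < 0):
        raise ValueError("Rician likelihood requires Y >= 0 and S >= 0")
    x = tau * Y * S
    # log I0(x) = log(i0e(x)) + x, stable for arbitrarily large x
    log_bessel = np.log(special.i0e(x)) + x
    with np.errstate(divide="ignore"):
        logY = np.log(Y)
    terms = np.log(tau) + logY - tau * (Y**2 + S**2) / 2.0 + log_bessel
    return float(np.sum(terms))


def joint_log_likelihood(
    model: NeighborhoodModel,
    Y_LR,
    Y_HR_per_voxel,
    lr_scheme,
    hr_scheme,
) -> float:
    """Joint log-likelihood of one neighborhood's LR and HR data.

    The two datasets (and the P HR voxels) are conditionally independent
    given the parameters, so the joint is the LR term plus the sum of the
    per-voxel HR terms.  ``Y_LR`` may be None/empty when no LR data exist.
    """
    total = 0.0
    if Y_LR is not None and np.size(Y_LR) > 0:
        S_LR = predict_lr_signal(model, lr_scheme)
        total += rician_log_likelihood(Y_LR, S_LR, model.tau_LR)
    if len(Y_HR_per_voxel) != model.map.P:
        raise ValueError("need one HR measurement vector per HR voxel")
    for Y, vp, tau in zip(Y_HR_per_voxel, model.hr_params, model.tau_HR):
        S = predict_voxel_signal(vp, hr_scheme)
        total += rician_log_likelihood(Y, S, float(tau))
    return total
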