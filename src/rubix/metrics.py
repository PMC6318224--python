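"""Posterior summaries: crossing-fibre counts and cones of uncertainty.

Orientations are axial quantities (v and -v are the same fibre), so all
averaging goes through the dyadic tensor v v^T.  The 95% cone of
uncertainty of a set of orientation draws is the 95th percentile of the
angles each draw subtends with the mean dyad.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mean_dyad",
    "cone_of_uncertainty_95",
    "count_fibres",
    "fibre_summary",
]


def mean_dyad(orientation_draws) -> np.ndarray:
    """Principal eigenvector of the mean dyadic tensor (1/T) sum v v^T.

    Sign-invariant: flipping any draw leaves the result unchanged (up to an
    overall sign, which is meaningless for an axial quantity).
    """
    V = np.asarray(orientation_draws, dtype=float).reshape(-1, 3)
    if V.shape[0] < 1:
        raise ValueError("need at least one draw")
    D = (V.T @ V) / V.shape[0]
    w, vec = np.linalg.eigh(D)
    return vec[:, -1]


def cone_of_uncertainty_95(orientation_draws, min_draws: int = 20) -> float:
    """95% cone of uncertainty in degrees around the mean dyad.

    The angle of each draw is taken modulo the antipodal symmetry
    (|cos| of the angle to the mean dyad); the 95th percentile uses linear
    interpolation.
    """
    V = np.asarray(orientation_draws, dtype=float).reshape(-1, 3)
    if V.shape[0] < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {V.shape[0]}")
    mu = mean_dyad(V)
    cosang = np.clip(np.abs(V @ mu) / np.linalg.norm(V, axis=1), 0.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    return float(np.percentile(angles, 95, method="linear"))


def count_fibres(posterior_mean_fractions, threshold: float = 0.05):
    """Supported-fibre count per voxel and ROI crossing fractions.

    Parameters
    ----------
    posterior_mean_fractions : (V, N) array
        Posterior-mean volume fractions per voxel and compartment.
    threshold : float
        A compartment counts when its mean fraction exceeds this (default
        5%).

    Returns
    -------
    counts : (V,) int array
    roi : dict with ``frac_ge2`` and ``frac_ge3`` — fractions of voxels
        supporting at least 2 / at least 3 fibres.
    """
    f = np.atleast_2d(np.asarray(posterior_mean_fractions, dtype=float))
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fractions must lie in [0, 1]")
    counts = (f > threshold).sum(axis=1)
    V = counts.size
    roi = {
        "frac_ge2": float(np.mean(counts >= 2)) if V else 0.0,
        "frac_ge3": float(np.mean(counts >= 3)) if V else 0.0,
    }
    return counts, roi


def fibre_summary(samples, threshold: float = 0.05, pooled: bool = True) -> pd.DataFrame:
    """Tidy per-voxel summary of a :class:`~rubix.mcmc.PosteriorSamples`.

    One row per voxel: index, mean fractions, supported-fibre count and
    cone(s) of uncertainty.  With ``pooled=True`` the cone column averages
    over the supported compartments, otherwise only the first compartment
    is reported.
    """
    mf = samples.mean_fractions
    counts, _ = count_fibres(mf, threshold)
    cones = samples.cones_95()
    rows = []
    for i, idx in enumerate(samples.voxel_indices):
        supported = mf[i] > threshold
        if pooled and supported.any():
            cone = float(cones[i, supported].mean())
        else:
            cone = float(cones[i, 0])
        row = {
            "x": idx[0], "y": idx[1], "z": idx[2],
            "n_fibres": int(counts[i]),
            "cone95_deg": cone,
            "in_mask": bool(samples.in_mask[i]),
        }
        for n in range(mf.shape[1]):
            row[f"mean_f{n + 1}"] = mf[i, n]
            row[f"cone95_f{n + 1}_deg"] = cones[i, n]
        rows.append(row)
    return pd.DataFrame(rows)
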