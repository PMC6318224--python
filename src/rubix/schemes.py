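"""Gradient tables (b-values and diffusion-sensitising directions).

A diffusion acquisition is described by K measurement points, each a pair
(b_k, g_k) of a diffusion weighting b (s/mm^2) and a unit gradient direction
g.  Measurements sharing a b-value form a "shell".  The FSL text dialect is
used on disk: ``bvals`` is one whitespace-separated row of K numbers,
``bvecs`` is three rows (x, y, z) of K numbers each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GradientScheme", "read_bvals_bvecs", "write_bvals_bvecs"]

_UNIT_TOL = 1e-6
#: b-values closer than this (s/mm^2) are grouped into one shell.
SHELL_TOL = 100.0


@dataclass(frozen=True)
class GradientScheme:
    """The (b_k, g_k) table for one dataset.

    Parameters
    ----------
    bvals : (K,) array
        Diffusion weightings in s/mm^2, all >= 0.
    bvecs : (K, 3) array
        Unit gradient directions.  b = 0 entries may carry the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.ndim != 1 or bvals.size < 1:
            raise ValueError("bvals must be a non-empty 1-D array")
        if bvecs.shape[0] != bvals.size:
            raise ValueError(
                f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) lengths differ"
            )
        if np.any(bvals < 0) or not np.all(np.isfinite(bvals)):
            raise ValueError("bvals must be finite and non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > _UNIT_TOL):
            raise ValueError("every bvec with b > 0 must have unit norm")
        labels = self.shell_labels
        if labels is None:
            labels = _label_shells(bvals)
        labels = np.asarray(labels, dtype=int)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "shell_labels", labels)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_measurements(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_labels == 0

    @property
    def shells(self) -> np.ndarray:
        """Representative b-value of each shell, ascending (shell 0 first)."""
        out = []
        for lab in np.unique(self.shell_labels):
            out.append(self.bvals[self.shell_labels == lab].mean())
        return np.asarray(out)

    @classmethod
    def from_files(cls, bvals_path, bvecs_path) -> "GradientScheme":
        bvals, bvecs = read_bvals_bvecs(bvals_path, bvecs_path)
        return cls(bvals=bvals, bvecs=bvecs)

    def to_files(self, bvals_path, bvecs_path) -> None:
        write_bvals_bvecs(self.bvals, self.bvecs, bvals_path, bvecs_path)


def _label_shells(bvals: np.ndarray, tol: float = SHELL_TOL) -> np.ndarray:
    """Group b-values into shells; label 0 is reserved for b ~ 0."""
    labels = np.zeros(bvals.size, dtype=int)
    nonzero = np.flatnonzero(bvals > tol)
    if nonzero.size == 0:
        return labels
    order = np.argsort(bvals[nonzero])
    current = 0
    last_b = None
    for idx in nonzero[order]:
        b = bvals[idx]
        if last_b is None or b - last_b > tol:
            current += 1
        labels[idx] = current
        last_b = b
    return labels


def read_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an FSL-style gradient table.

    ``bvals``: one row of K values.  ``bvecs``: three rows (x, y, z) with K
    columns.  A transposed K x 3 bvecs file is accepted and fixed up.
    """
    bvals = np.loadtxt(Path(bvals_path), ndmin=1).ravel()
    bvecs = np.loadtxt(Path(bvecs_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous; FSL convention is rows = components
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvecs shape {bvecs.shape} inconsistent with {bvals.size} bvals"
        )
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bvals_path, bvecs_path) -> None:
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float).reshape(-1, 3)
    np.savetxt(Path(bvals_path), bvals[None, :], fmt="%.6g")
    np.savetxt(Path(bvecs_path), bvecs.T, fmt="%.8f")
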