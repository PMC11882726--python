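"""Nearest-positive-semidefinite smoothing and the per-SNP Z-difference filter.

Genetic covariance matrices assembled from pairwise regressions over
cohorts with very different sample sizes need not be positive
semidefinite.  ``nearest_psd`` projects by eigenvalue clipping: the
symmetric eigendecomposition is taken, eigenvalues below a floor are
replaced by the floor, and the matrix is reconstructed.  This is the
Frobenius-nearest matrix with all eigenvalues >= floor, done in a single
deterministic pass (no alternating projections); diagonal entries are
not preserved, which is intentional at these dimensions.

Because smoothing perturbs the moments every SNP model is fitted to,
SNPs whose association statistics react strongly to it are unreliable:
``zdiff_filter`` removes any SNP whose effect Z under the pre- vs
post-smoothed matrices differs by strictly more than a threshold
(default 1) on any factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SmoothingReport", "nearest_psd", "zdiff_filter"]

_SYM_TOL = 1e-8


@dataclass
class SmoothingReport:
    min_eigenvalue_pre: float
    min_eigenvalue_post: float
    max_abs_change: float

    @property
    def changed(self) -> bool:
        return self.max_abs_change > 0.0


def nearest_psd(a: np.ndarray, floor: float = 1e-10) -> tuple[np.ndarray, SmoothingReport]:
    """Clip eigenvalues of a symmetric matrix to ``floor`` and reconstruct.

    Inputs already satisfying the floor are returned unchanged
    (elementwise identical).  Asymmetry beyond tolerance is an input
    error; tiny asymmetry is symmetrized away first.
    """
    a = np.asarray(a, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("nearest_psd expects a square matrix")
    asym = np.max(np.abs(a - a.T)) if a.size else 0.0
    scale = max(np.max(np.abs(a)), 1.0)
    if asym > _SYM_TOL * scale:
        raise ValueError(f"matrix asymmetric beyond tolerance (max |a-a'|={asym:.3g})")
    sym = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= floor:
        return a.copy(), SmoothingReport(float(vals[0]), float(vals[0]), 0.0)
    clipped = np.maximum(vals, floor)
    out = (vecs * clipped) @ vecs.T
    out = (out + out.T) / 2.0
    post = float(np.linalg.eigvalsh(out)[0])
    return out, SmoothingReport(float(vals[0]), post, float(np.max(np.abs(out - sym))))


def zdiff_filter(pre_z: pd.DataFrame, post_z: pd.DataFrame,
                 threshold: float = 1.0) -> tuple[pd.Index, pd.DataFrame]:
    """Drop SNPs whose effect Z moved by strictly more than ``threshold``.

    ``pre_z`` and ``post_z`` are SNP-indexed frames with one column per
    factor.  A SNP is removed iff |pre - post| > threshold on *any*
    factor (a |dZ| of exactly ``threshold`` survives).  Returns the
    retained index and a removal log with the offending |dZ| values.
    """
    if not pre_z.index.equals(post_z.index) or list(pre_z.columns) != list(post_z.columns):
        raise ValueError("pre/post Z frames must share index and columns")
    dz = (pre_z - post_z).abs()
    removed_mask = (dz > threshold).any(axis=1)
    log = dz.loc[removed_mask].copy()
    log["max_abs_dz"] = dz.loc[removed_mask].max(axis=1)
    return pre_z.index[~removed_mask], log
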