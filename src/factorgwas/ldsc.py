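"""LD-score regression: SNP heritability, genetic covariance, block jackknife.

Univariate model: E[z_j^2] = intercept + (N_j h^2 / M) * l_j.
Bivariate model: E[z_aj z_bj] = intercept + (sqrt(N_aj N_bj) sigma_g / M) * l_j,
with the free intercept absorbing confounding and sample overlap.

Estimation is weighted least squares in two passes.  The first pass
weights by 1/l_j only (LD oversampling); the second adds the standard
heteroskedasticity weight, the reciprocal of the approximate variance of
the regressand under the first-pass fit:

    univariate:  var(z^2)    ~ 2 (a + b x)^2
    bivariate:   var(z_a z_b) ~ (a_ab + b_ab x)^2 + (a_a + b_a x_a)(a_b + b_b x_b)

Standard errors come from a delete-a-block jackknife over ``n_blocks``
SNP blocks contiguous in the table's sort order; the multi-trait
sampling covariance matrix V is the joint jackknife covariance of all
half-vectorized elements of S.

vech convention (asserted by all V consumers): column-major lower
triangle including the diagonal, i.e. (0,0),(1,0),..,(t-1,0),(1,1),..
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import AlignedPanel, SumStatsTable, merge_cohorts

__all__ = [
    "H2Estimate", "GencovEstimate", "CovarianceStack", "ScreenReport",
    "estimate_h2", "estimate_gencov", "build_covariance_stack",
    "standardize", "screen_indicators", "screen",
    "vech", "unvech", "vech_indices",
]


class LdscInputError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


# --- vech helpers -------------------------------------------------------

def vech_indices(t: int) -> list[tuple[int, int]]:
    """Column-major lower-triangle index order, diagonal included."""
    return [(i, j) for j in range(t) for i in range(j, t)]


def vech(m: np.ndarray) -> np.ndarray:
    t = m.shape[0]
    return np.array([m[i, j] for i, j in vech_indices(t)])


def unvech(v: np.ndarray, t: int) -> np.ndarray:
    m = np.zeros((t, t))
    for val, (i, j) in zip(v, vech_indices(t)):
        m[i, j] = m[j, i] = val
    return m


# --- results ------------------------------------------------------------

@dataclass(frozen=True)
class H2Estimate:
    h2: float
    se: float
    intercept: float

    @property
    def z(self) -> float:
        return self.h2 / self.se


@dataclass(frozen=True)
class GencovEstimate:
    cov: float
    se: float
    intercept: float


@dataclass
class CovarianceStack:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    V covers vech(S) in the column-major lower-triangle order of
    :func:`vech_indices`; diag(V) holds the squared jackknife SEs of the
    corresponding S elements.
    """

    labels: list[str]
    S: np.ndarray
    V: np.ndarray
    n_blocks: int
    intercepts: np.ndarray | None = None

    @property
    def n_traits(self) -> int:
        return len(self.labels)

    def se_matrix(self) -> np.ndarray:
        return unvech(np.sqrt(np.diag(self.V)), self.n_traits)

    def to_json(self, path) -> None:
        obj = {
            "labels": list(self.labels),
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "n_blocks": int(self.n_blocks),
            "vech_order": "column-major lower triangle incl. diagonal",
        }
        if self.intercepts is not None:
            obj["intercepts"] = self.intercepts.tolist()
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CovarianceStack":
        with open(path) as fh:
            obj = json.load(fh)
        icpt = np.asarray(obj["intercepts"]) if "intercepts" in obj else None
        return cls(list(obj["labels"]), np.asarray(obj["S"]), np.asarray(obj["V"]),
                   int(obj["n_blocks"]), icpt)


# --- weighted block regression -----------------------------------------

def _block_edges(m: int, n_blocks: int) -> np.ndarray:
    return (np.arange(n_blocks) * m) // n_blocks


def _wls_sums(x: np.ndarray, y: np.ndarray, w: np.ndarray, edges: np.ndarray):
    """Per-block and total normal-equation sums for y ~ 1 + x with weights w."""
    parts = np.stack([w, w * x, w * x * x, w * y, w * x * y], axis=0)
    blocks = np.add.reduceat(parts, edges, axis=1)  # (5, B)
    total = blocks.sum(axis=1)
    return total, blocks


def _solve_ab(sums: np.ndarray) -> np.ndarray:
    """Solve the 2x2 normal equations; sums rows = (w, wx, wxx, wy, wxy)."""
    s = np.atleast_2d(sums.T).T  # (5, B) or (5, 1)
    det = s[0] * s[2] - s[1] ** 2
    a = (s[2] * s[3] - s[1] * s[4]) / det  # intercept
    b = (s[0] * s[4] - s[1] * s[3]) / det  # slope
    return np.stack([a, b], axis=0)


class _PairRegression:
    """One LDSC regression with per-block sums for delete-a-block jackknife."""

    def __init__(self, x, y, w, edges):
        self.total, self.blocks = _wls_sums(x, y, w, edges)
        ab = _solve_ab(self.total)
        self.intercept, self.slope = float(ab[0, 0]), float(ab[1, 0])
        loo = self.total[:, None] - self.blocks
        ab_loo = _solve_ab(loo)
        self.loo_intercepts = ab_loo[0]
        self.loo_slopes = ab_loo[1]  # (B,)

    @property
    def jackknife_se(self) -> float:
        b = len(self.loo_slopes)
        dev = self.loo_slopes - self.loo_slopes.mean()
        return float(np.sqrt((b - 1) / b * np.sum(dev**2)))


_HET_FLOOR = 0.05


def _first_pass(x, y, l2):
    w0 = 1.0 / np.maximum(l2, 1.0)
    ab = _solve_ab(_wls_sums(x, y, w0, np.array([0]))[0])
    return float(ab[0, 0]), float(ab[1, 0])


def _univariate(z, x, l2, edges):
    # raw first-pass coefficients go into the weights (floored below):
    # clipping would break both the self-covariance identity (a trait
    # paired with its own copy must reproduce the h^2 regression
    # weight-for-weight) and sign equivariance under trait negation
    a0, b0 = _first_pass(x, z * z, l2)
    het = 2.0 * (a0 + b0 * x) ** 2
    w = 1.0 / (np.maximum(l2, 1.0) * np.maximum(het, _HET_FLOOR))
    return _PairRegression(x, z * z, w, edges), (a0, b0)


def _bivariate(za, zb, xa, xb, xab, l2, edges, uni_a, uni_b):
    y = za * zb
    a0, b0 = _first_pass(xab, y, l2)
    aa, ba = uni_a
    ab_, bb = uni_b
    het = (a0 + b0 * xab) ** 2 + (aa + ba * xa) * (ab_ + bb * xb)
    w = 1.0 / (np.maximum(l2, 1.0) * np.maximum(het, _HET_FLOOR))
    return _PairRegression(xab, y, w, edges)


def _prepare(panel: AlignedPanel, ldscores: pd.DataFrame, m: int, n_blocks: int):
    merged = panel.snps.merge(ldscores, on="SNP", how="inner")
    if len(merged) < 2 * n_blocks:
        raise LdscInputError(
            f"{len(merged)} SNPs after LD-score intersection; need >= {2 * n_blocks}"
        )
    idx = panel.snps.reset_index().merge(merged[["SNP"]], on="SNP")["index"].to_numpy()
    l2 = merged["L2"].to_numpy(float)
    Z = panel.Z[idx]
    N = panel.N[idx]
    edges = _block_edges(len(l2), n_blocks)
    return Z, N, l2, edges, m


def estimate_h2(table: SumStatsTable, ldscores: pd.DataFrame, m: int,
                n_blocks: int = 200) -> H2Estimate:
    """SNP heritability of one trait with delete-a-block jackknife SE."""
    df = table.data.merge(ldscores, on="SNP", how="inner")
    if len(df) < 2 * n_blocks:
        raise LdscInputError(
            f"{len(df)} SNPs after LD-score intersection; need >= {2 * n_blocks}"
        )
    z = df["Z"].to_numpy(float)
    x = df["N"].to_numpy(float) * df["L2"].to_numpy(float) / m
    edges = _block_edges(len(df), n_blocks)
    reg, _ = _univariate(z, x, df["L2"].to_numpy(float), edges)
    return H2Estimate(reg.slope, reg.jackknife_se, reg.intercept)


def estimate_gencov(a: SumStatsTable, b: SumStatsTable, ldscores: pd.DataFrame,
                    m: int, n_blocks: int = 200) -> GencovEstimate:
    """Bivariate LDSC genetic covariance between two traits."""
    panel = merge_cohorts([a, b])
    Z, N, l2, edges, m = _prepare(panel, ldscores, m, n_blocks)
    xa = N[:, 0] * l2 / m
    xb = N[:, 1] * l2 / m
    _, u_a = _univariate(Z[:, 0], xa, l2, edges)
    _, u_b = _univariate(Z[:, 1], xb, l2, edges)
    xab = np.sqrt(N[:, 0] * N[:, 1]) * l2 / m
    reg = _bivariate(Z[:, 0], Z[:, 1], xa, xb, xab, l2, edges, u_a, u_b)
    return GencovEstimate(reg.slope, reg.jackknife_se, reg.intercept)


def build_covariance_stack(panel: AlignedPanel, ldscores: pd.DataFrame, m: int,
                           n_blocks: int = 200) -> CovarianceStack:
    """Assemble S from all pairwise regressions and V from the joint jackknife.

    The diagonal entries of S are the univariate h^2 regressions; V is the
    jackknife covariance of the delete-a-block slope estimates across all
    vech(S) elements, so diag(V) equals the squared SEs of the pairwise
    calls by construction.
    """
    if panel.n_traits < 2:
        raise LdscInputError("need a panel with at least two traits")
    Z, N, l2, edges, m = _prepare(panel, ldscores, m, n_blocks)
    t = panel.n_traits
    x_uni = [N[:, i] * l2 / m for i in range(t)]
    uni = [_univariate(Z[:, i], x_uni[i], l2, edges) for i in range(t)]
    order = vech_indices(t)
    loo = np.empty((len(order), len(edges)))
    S = np.zeros((t, t))
    icpt = np.zeros((t, t))
    for p, (i, k) in enumerate(order):
        if i == k:
            reg = uni[i][0]
        else:
            xab = np.sqrt(N[:, i] * N[:, k]) * l2 / m
            reg = _bivariate(Z[:, i], Z[:, k], x_uni[i], x_uni[k], xab, l2,
                             edges, uni[i][1], uni[k][1])
        S[i, k] = S[k, i] = reg.slope
        icpt[i, k] = icpt[k, i] = reg.intercept
        loo[p] = reg.loo_slopes
    b = len(edges)
    dev = loo - loo.mean(axis=1, keepdims=True)
    V = (b - 1) / b * dev @ dev.T
    return CovarianceStack(list(panel.traits), S, V, n_blocks, icpt)


def standardize(stack: CovarianceStack) -> CovarianceStack:
    """Rescale a stack to the genetic correlation scale.

    S becomes the correlation matrix (unit diagonal); V is transformed by
    the delta-method Jacobian of r_ik = S_ik / sqrt(S_ii S_kk), so the
    rows/columns for diagonal elements become exactly zero.  Idempotent.
    """
    t = stack.n_traits
    d = np.diag(stack.S)
    for lbl, v in zip(stack.labels, d):
        if v <= 0:
            raise NumericalError(f"non-positive genetic variance for '{lbl}'")
    order = vech_indices(t)
    pos = {ik: p for p, ik in enumerate(order)}
    J = np.zeros((len(order), len(order)))
    R = stack.S / np.sqrt(np.outer(d, d))
    for p, (i, k) in enumerate(order):
        if i == k:
            continue
        r = R[i, k]
        J[p, pos[(i, k)]] = 1.0 / np.sqrt(d[i] * d[k])
        J[p, pos[(i, i)]] = -r / (2.0 * d[i])
        J[p, pos[(k, k)]] = -r / (2.0 * d[k])
    np.fill_diagonal(R, 1.0)
    V = J @ stack.V @ J.T
    return CovarianceStack(list(stack.labels), R, V, stack.n_blocks, stack.intercepts)


# --- indicator screening ------------------------------------------------

@dataclass
class ScreenReport:
    retained: list[str]
    excluded: list[tuple[str, str]]  # (label, reason)


def screen(h2: np.ndarray, h2_se: np.ndarray, r_g: np.ndarray, labels,
           h2_z_threshold: float = 1.645, collinearity_r: float = 0.9) -> ScreenReport:
    """Apply the two inclusion rules to trait-level estimates.

    First traits whose h^2 z-score falls below ``h2_z_threshold``
    (one-sided significance of SNP heritability) are excluded; then, in a
    single simultaneous pass over the survivors, any trait whose |r_g|
    exceeds ``collinearity_r`` with two or more other survivors is
    excluded as multicollinear.
    """
    labels = list(labels)
    excluded: list[tuple[str, str]] = []
    zscores = np.asarray(h2, float) / np.asarray(h2_se, float)
    alive = []
    for i, lbl in enumerate(labels):
        if zscores[i] < h2_z_threshold:
            excluded.append((lbl, f"non-significant SNP heritability (z={zscores[i]:.2f})"))
        else:
            alive.append(i)
    counts = {
        i: sum(1 for k in alive if k != i and abs(r_g[i, k]) > collinearity_r)
        for i in alive
    }
    retained = []
    for i in alive:
        if counts[i] >= 2:
            partners = [labels[k] for k in alive
                        if k != i and abs(r_g[i, k]) > collinearity_r]
            excluded.append((labels[i], "multicollinear with " + ", ".join(partners)))
        else:
            retained.append(labels[i])
    return ScreenReport(retained, excluded)


def screen_indicators(stack: CovarianceStack, h2_z_threshold: float = 1.645,
                      collinearity_r: float = 0.9) -> ScreenReport:
    """Screen a raw (covariance-scale) stack per the inclusion rules."""
    sd = stack.se_matrix()
    r = standardize(stack).S
    return screen(np.diag(stack.S), np.diag(sd), r, stack.labels,
                  h2_z_threshold, collinearity_r)
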