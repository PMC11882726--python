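"""Diagonally weighted least squares estimation of genomic factor models.

Estimation follows the convention of structural equation modelling on
LDSC output: parameters minimize

    F(theta) = (s - sigma(theta))' D^-1 (s - sigma(theta)),   D = diag(V)

where ``s`` is the half-vectorized genetic covariance matrix and ``V``
its jackknife sampling covariance.  Standard errors use the full-V
sandwich formula  (Delta' W Delta)^-1 Delta' W V W Delta (Delta' W Delta)^-1
with W = D^-1 and Delta the analytic Jacobian of sigma.

Model chi-square convention (used everywhere, including nested
differences): the residual-based quadratic form

    T = res' [V^-1 - V^-1 Delta (Delta' V^-1 Delta)^-1 Delta' V^-1] res

evaluated at the DWLS estimates.  T is asymptotically chi-square with
df = moments - free parameters for a correctly specified model, for any
consistent estimator of theta, so its expectation is df and differences
between nested models are asymptotically chi-square on the df
difference.  Printed chi-square values from other software are not
comparable convention-for-convention; the statistic is exercised only
through its distributional properties and the identities AIC = chi2 + 2k
and df + k = moments.

Fit indices: AIC = chi2 + 2k; CFI relative to the independence model
(all covariances fixed to zero, variances free); SRMR is the root mean
square of the standardized residual moments over the lower triangle
including the diagonal, standardized by the observed variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ldsc import CovarianceStack, vech_indices
from .models import FREE, ModelSpec

__all__ = [
    "FitResult", "ModelError", "fit", "fit_many", "independence_model",
    "classify_fit", "compare_models", "genetic_multiple_regression",
    "subset_stack", "CompiledModel",
]


class ModelError(RuntimeError):
    """Non-identified or numerically singular model."""


# --- compiled model -----------------------------------------------------

class CompiledModel:
    """A spec compiled to fast sigma(theta) / Jacobian evaluation.

    ``snp_mode`` augments the model with one exogenous standardized
    genotype (variance fixed to 1): ``"factors"`` adds free SNP->factor
    paths (common-pathway model), ``"indicators"`` adds free
    SNP->indicator paths (independent-pathways model).  The moment
    vector is then [vech(S_yy), cov(y, SNP)]; the fixed SNP variance is
    not a fitted moment.
    """

    def __init__(self, spec: ModelSpec, snp_mode: str | None = None):
        self.spec = spec
        self.snp_mode = snp_mode
        self.inds = list(spec.indicators)
        self.facs = list(spec.factors)
        t, f = len(self.inds), len(self.facs)
        self.t, self.f = t, f
        self.i_of = {x: i for i, x in enumerate(self.inds)}
        self.f_of = {x: i for i, x in enumerate(self.facs)}

        self.lam0 = np.zeros((t, f))
        self.psi0 = np.eye(f)
        self.theta0_mat = np.zeros((t, t))
        for (ind, fac), val in spec.loadings.items():
            if val is not FREE:
                self.lam0[self.i_of[ind], self.f_of[fac]] = val
        for fac, val in spec.factor_vars.items():
            if val is not FREE:
                self.psi0[self.f_of[fac], self.f_of[fac]] = val
        for (fa, fb), val in spec.factor_covs.items():
            if val is not FREE:
                a, b = self.f_of[fa], self.f_of[fb]
                self.psi0[a, b] = self.psi0[b, a] = val
        for ind, val in spec.residuals.items():
            if val is not FREE:
                self.theta0_mat[self.i_of[ind], self.i_of[ind]] = val
        for (ia, ib), val in spec.residual_covs.items():
            if val is not FREE:
                a, b = self.i_of[ia], self.i_of[ib]
                self.theta0_mat[a, b] = self.theta0_mat[b, a] = val

        self.params: list[tuple[str, object]] = list(spec.free_parameters())
        if snp_mode == "factors":
            self.params += [("snp_path", fac) for fac in self.facs]
        elif snp_mode == "indicators":
            self.params += [("snp_path", ind) for ind in self.inds]
        elif snp_mode is not None:
            raise ValueError(f"unknown snp_mode {snp_mode!r}")
        self.k = len(self.params)

        pairs = vech_indices(t)
        self.vI = np.array([i for i, _ in pairs])
        self.vJ = np.array([j for _, j in pairs])
        self.p_yy = len(pairs)
        self.p = self.p_yy + (t if snp_mode else 0)
        if self.k > self.p:
            raise ModelError(
                f"{spec.name}: {self.k} free parameters exceed {self.p} moments"
            )

    # parameter vector -> model matrices
    def build(self, theta: np.ndarray):
        lam = self.lam0.copy()
        psi = self.psi0.copy()
        th = self.theta0_mat.copy()
        b = np.zeros(self.f)
        d = np.zeros(self.t)
        for val, (kind, key) in zip(theta, self.params):
            if kind == "loading":
                ind, fac = key
                lam[self.i_of[ind], self.f_of[fac]] = val
            elif kind == "factor_cov":
                a, c = self.f_of[key[0]], self.f_of[key[1]]
                psi[a, c] = psi[c, a] = val
            elif kind == "factor_var":
                a = self.f_of[key]
                psi[a, a] = val
            elif kind == "residual":
                a = self.i_of[key]
                th[a, a] = val
            elif kind == "residual_cov":
                a, c = self.i_of[key[0]], self.i_of[key[1]]
                th[a, c] = th[c, a] = val
            elif kind == "snp_path":
                if self.snp_mode == "factors":
                    b[self.f_of[key]] = val
                else:
                    d[self.i_of[key]] = val
        return lam, psi, th, b, d

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, th, b, d = self.build(theta)
        M = psi + np.outer(b, b) if self.snp_mode == "factors" else psi
        syy = lam @ M @ lam.T + th
        if self.snp_mode == "indicators":
            syy = syy + np.outer(d, d)
        out = syy[self.vI, self.vJ]
        if self.snp_mode:
            syg = lam @ b + d
            out = np.concatenate([out, syg])
        return out

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, th, b, d = self.build(theta)
        t, I, J = self.t, self.vI, self.vJ
        M = psi + np.outer(b, b) if self.snp_mode == "factors" else psi
        G = lam @ M  # (t, f)
        Lb = lam @ b
        Delta = np.zeros((self.p, self.k))
        for q, (kind, key) in enumerate(self.params):
            row = np.zeros(self.p)
            if kind == "loading":
                i, fi = self.i_of[key[0]], self.f_of[key[1]]
                m = G[:, fi]
                row[: self.p_yy] = (I == i) * m[J] + (J == i) * m[I]
                if self.snp_mode == "factors":
                    row[self.p_yy + i] = b[fi]
            elif kind == "factor_cov":
                u = lam[:, self.f_of[key[0]]]
                v = lam[:, self.f_of[key[1]]]
                row[: self.p_yy] = u[I] * v[J] + v[I] * u[J]
            elif kind == "factor_var":
                u = lam[:, self.f_of[key]]
                row[: self.p_yy] = u[I] * u[J]
            elif kind == "residual":
                i = self.i_of[key]
                row[: self.p_yy] = (I == i) & (J == i)
            elif kind == "residual_cov":
                a, c = self.i_of[key[0]], self.i_of[key[1]]
                row[: self.p_yy] = ((I == a) & (J == c)) | ((I == c) & (J == a))
            elif kind == "snp_path" and self.snp_mode == "factors":
                fi = self.f_of[key]
                u = lam[:, fi]
                row[: self.p_yy] = u[I] * Lb[J] + Lb[I] * u[J]
                row[self.p_yy:] = u
            elif kind == "snp_path":
                i = self.i_of[key]
                row[: self.p_yy] = (I == i) * d[J] + (J == i) * d[I]
                row[self.p_yy + i] = 1.0
            Delta[:, q] = row
        return Delta

    def default_start(self, S: np.ndarray, s_yg: np.ndarray | None = None) -> np.ndarray:
        """Heuristic starting values from the observed moments."""
        diag = np.clip(np.diag(S), 1e-4, None)
        theta = np.empty(self.k)
        for q, (kind, key) in enumerate(self.params):
            if kind == "loading":
                theta[q] = 0.5 * np.sqrt(diag[self.i_of[key[0]]])
            elif kind == "factor_cov":
                theta[q] = 0.2
            elif kind == "factor_var":
                theta[q] = float(np.mean(diag))
            elif kind == "residual":
                theta[q] = 0.5 * diag[self.i_of[key]]
            elif kind == "residual_cov":
                theta[q] = 0.0
            elif kind == "snp_path":
                theta[q] = 0.0 if s_yg is None else float(np.mean(s_yg))
        return theta


# --- fit results --------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, sandwich SEs and fit statistics for one fitted model."""

    name: str
    estimates: dict[tuple[str, object], float]
    se: dict[tuple[str, object], float]
    chi2: float
    df: int
    p_value: float
    k: int
    converged: bool
    heywood: list[str]
    aic: float = np.nan
    cfi: float = np.nan
    srmr: float = np.nan
    theta: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    sigma_yy: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    S_obs: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def loading(self, indicator: str, factor: str) -> tuple[float, float]:
        key = ("loading", (indicator, factor))
        return self.estimates[key], self.se[key]


def _safe_inverse(V: np.ndarray) -> np.ndarray:
    """Inverse of a jackknife covariance, ridged if numerically singular."""
    scale = float(np.mean(np.diag(V)))
    for eps in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            return np.linalg.inv(V + eps * scale * np.eye(len(V)))
        except np.linalg.LinAlgError:
            continue
    raise ModelError("sampling covariance matrix not invertible")


def _browne_chi2(res: np.ndarray, Delta: np.ndarray, Vi: np.ndarray, df: int) -> float:
    if df <= 0:
        return 0.0
    vr = Vi @ res
    dv = Delta.T @ vr
    A = Delta.T @ Vi @ Delta
    try:
        sol = np.linalg.solve(A, dv)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(A, dv, rcond=None)[0]
    return float(max(res @ vr - dv @ sol, 0.0))


def _param_bounds(model: CompiledModel, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generous box bounds preventing runaway along Heywood ridges."""
    scale = float(np.sqrt(np.clip(np.diag(S), 1e-8, None).max()))
    lo = np.empty(model.k)
    hi = np.empty(model.k)
    for q, (kind, _key) in enumerate(model.params):
        if kind == "loading":
            lo[q], hi[q] = -4 * scale, 4 * scale
        elif kind == "factor_cov":
            lo[q], hi[q] = -2.0, 2.0
        elif kind == "factor_var":
            lo[q], hi[q] = -1.0, 16 * scale**2 + 1.0
        elif kind == "snp_path":
            lo[q], hi[q] = -2.0, 2.0
        else:  # residual variances / covariances (Heywood range allowed)
            lo[q], hi[q] = -4 * scale**2, 4 * scale**2
    return lo, hi


def _gauss_newton(model: CompiledModel, s: np.ndarray, w: np.ndarray,
                  theta0: np.ndarray, bounds: tuple[np.ndarray, np.ndarray],
                  max_iter: int = 300) -> tuple[np.ndarray, bool]:
    """Projected Levenberg-Marquardt on the weighted least-squares objective.

    Convergence is declared either on the (ridged) Newton decrement,
    which estimates twice the remaining objective decrease, or when
    accepted steps stop improving the objective beyond numerical noise
    (stalling at a box bound); both remain robust when the Gauss-Newton
    Hessian is nearly singular along weakly identified directions.
    """
    lo, hi = bounds
    theta = np.clip(theta0, lo, hi)
    res = s - model.sigma(theta)
    f = float(res @ (w * res))
    lam = 1e-3
    eye = np.eye(model.k)
    stall = 0
    for _ in range(max_iter):
        Delta = model.jacobian(theta)
        A = (Delta * w[:, None]).T @ Delta
        g = Delta.T @ (w * res)
        scale = max(float(np.trace(A)) / max(model.k, 1), 1e-300)
        try:
            nd = float(g @ np.linalg.solve(A + 1e-8 * scale * eye, g))
        except np.linalg.LinAlgError:
            return theta, False
        if nd < 1e-15 * (1.0 + f):
            return theta, True
        improved = False
        for _trial in range(40):
            try:
                step = np.linalg.solve(A + lam * scale * eye, g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = np.clip(theta + step, lo, hi)
            res_c = s - model.sigma(cand)
            f_c = float(res_c @ (w * res_c))
            if np.isfinite(f_c) and f_c < f:
                gain = f - f_c
                theta, res, f = cand, res_c, f_c
                lam = max(lam / 3.0, 1e-12)
                improved = True
                stall = stall + 1 if gain < 1e-13 * (1.0 + f) else 0
                break
            lam *= 10.0
            if lam > 1e10:
                break
        if not improved or stall >= 3:
            return theta, True  # no meaningful descent left: (local) optimum
    return theta, False


def _minimize(model: CompiledModel, s: np.ndarray, w: np.ndarray,
              theta0: np.ndarray, bounds: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, bool]:
    """Quasi-Newton with analytic gradient, Gauss-Newton polish, multi-start."""
    wn = w / w.mean()  # scale-free objective; same minimizer

    def fun(theta):
        res = s - model.sigma(theta)
        return float(res @ (wn * res))

    def grad(theta):
        res = s - model.sigma(theta)
        return -2.0 * model.jacobian(theta).T @ (wn * res)

    theta, ok = _gauss_newton(model, s, wn, theta0, bounds)
    if ok:
        return theta, True
    best_x, best_f = theta, fun(theta)
    rng = np.random.default_rng(20240117)
    box = list(zip(bounds[0], bounds[1]))
    for trial in range(5):
        start = theta0 if trial == 0 else theta0 + 0.1 * rng.standard_normal(model.k)
        start = np.clip(start, bounds[0], bounds[1])
        r = optimize.minimize(fun, start, jac=grad, method="L-BFGS-B",
                              bounds=box, options={"maxiter": 800, "ftol": 1e-14})
        x, ok = _gauss_newton(model, s, wn, r.x, bounds, max_iter=100)
        f = fun(x)
        if f < best_f:
            best_x, best_f = x, f
        if ok:
            return x, True
    return best_x, False


def subset_stack(stack: CovarianceStack, labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (S, V) sub-blocks for ``labels`` in the given order."""
    sel = [stack.labels.index(l) for l in labels]
    S = stack.S[np.ix_(sel, sel)]
    t_full = stack.n_traits
    full_pos = {}
    for p, (i, j) in enumerate(vech_indices(t_full)):
        full_pos[(i, j)] = p
        full_pos[(j, i)] = p
    rows = [full_pos[(sel[i], sel[j])] for i, j in vech_indices(len(sel))]
    V = stack.V[np.ix_(rows, rows)]
    return S, V


def independence_model(indicators: list[str]) -> ModelSpec:
    """Baseline: all covariances fixed to zero, variances free."""
    return ModelSpec("independence", list(indicators), [], {})


def fit(stack: CovarianceStack, spec: ModelSpec, *, baseline: FitResult | None = None,
        compute_indices: bool = True, theta0: np.ndarray | None = None,
        Vi: np.ndarray | None = None) -> FitResult:
    """Fit one model to a covariance stack by DWLS.

    Computes sandwich standard errors, the residual-based model
    chi-square, and (unless ``compute_indices=False``) AIC/CFI/SRMR with
    the independence model fitted on the same stack as baseline.
    Nonconvergence is reported via ``converged``; Heywood cases (negative
    free residual variances) are flagged, not constrained.
    """
    S, V = subset_stack(stack, spec.indicators)
    result = _fit_moments(spec, S, V, theta0=theta0, Vi=Vi)
    if compute_indices:
        if baseline is None:
            baseline = fit(stack, independence_model(spec.indicators),
                           compute_indices=False)
        _attach_indices(result, baseline)
    return result


def _fit_moments(spec: ModelSpec, S: np.ndarray, V: np.ndarray, *,
                 snp_mode: str | None = None, s_yg: np.ndarray | None = None,
                 v_snp: np.ndarray | None = None, theta0: np.ndarray | None = None,
                 Vi: np.ndarray | None = None) -> FitResult:
    model = CompiledModel(spec, snp_mode)
    s = vech_from(S, model.vI, model.vJ)
    V_aug = V
    if snp_mode:
        s = np.concatenate([s, s_yg])
        V_aug = np.zeros((model.p, model.p))
        V_aug[: model.p_yy, : model.p_yy] = V
        V_aug[model.p_yy:, model.p_yy:] = np.diag(v_snp)
    dV = np.diag(V_aug).copy()
    if np.any(dV <= 0):
        raise ModelError("sampling covariance has non-positive diagonal")
    w = 1.0 / dV
    if theta0 is None:
        theta0 = model.default_start(S, s_yg)
    theta, converged = _minimize(model, s, w, theta0, _param_bounds(model, S))
    sig = model.sigma(theta)
    res = s - sig
    Delta = model.jacobian(theta)
    A = (Delta * w[:, None]).T @ Delta
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ModelError(f"{spec.name}: singular information matrix (cond={cond:.2g})")
    Ainv = np.linalg.inv(A)
    WD = Delta * w[:, None]
    B = WD.T @ V_aug @ WD
    cov = Ainv @ B @ Ainv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if Vi is None:
        Vi = _safe_inverse(V_aug)
    df = model.p - model.k
    chi2 = _browne_chi2(res, Delta, Vi, df)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    heywood = [key for (kind, key), est in zip(model.params, theta)
               if kind == "residual" and est < 0]
    estimates = dict(zip(model.params, map(float, theta)))
    ses = dict(zip(model.params, map(float, se)))
    t = model.t
    lam, psi, th, b, d = model.build(theta)
    sigma_yy = lam @ (psi + np.outer(b, b) if snp_mode == "factors" else psi) @ lam.T + th
    if snp_mode == "indicators":
        sigma_yy += np.outer(d, d)
    return FitResult(spec.name, estimates, ses, chi2, df, p_value, model.k,
                     converged, heywood, aic=chi2 + 2 * model.k,
                     theta=theta, sigma_yy=sigma_yy, S_obs=S)


def vech_from(S: np.ndarray, I: np.ndarray, J: np.ndarray) -> np.ndarray:
    return S[I, J]


def _attach_indices(result: FitResult, baseline: FitResult) -> None:
    num = max(result.chi2 - result.df, 0.0)
    den = max(baseline.chi2 - baseline.df, num, 0.0)
    result.cfi = 1.0 if den == 0.0 else float(np.clip(1.0 - num / den, 0.0, 1.0))
    sd = np.sqrt(np.clip(np.diag(result.S_obs), 1e-12, None))
    resid = (result.S_obs - result.sigma_yy) / np.outer(sd, sd)
    tril = np.tril_indices_from(resid)
    result.srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))


def classify_fit(cfi: float, srmr: float) -> str:
    """Joint absolute-fit label: the weaker of the CFI and SRMR labels.

    CFI >= 0.95 good, >= 0.90 acceptable; SRMR < 0.05 good, < 0.10
    acceptable; anything else poor.
    """
    order = {"good": 0, "acceptable": 1, "poor": 2}
    c = "good" if cfi >= 0.95 else "acceptable" if cfi >= 0.90 else "poor"
    s = "good" if srmr < 0.05 else "acceptable" if srmr < 0.10 else "poor"
    return c if order[c] >= order[s] else s


def fit_many(stack: CovarianceStack, specs: dict[str, ModelSpec]) -> dict[str, FitResult]:
    """Fit several models on one stack, sharing the baseline per indicator set."""
    baselines: dict[tuple, FitResult] = {}
    out: dict[str, FitResult] = {}
    for name, spec in specs.items():
        key = tuple(spec.indicators)
        if key not in baselines:
            baselines[key] = fit(stack, independence_model(list(key)),
                                 compute_indices=False)
        out[name] = fit(stack, spec, baseline=baselines[key])
    return out


def compare_models(fits: dict[str, FitResult]):
    """Comparison table: chi2, df, p, AIC, CFI, SRMR, dAIC, best-by-AIC."""
    import pandas as pd

    rows = []
    best = min(fits, key=lambda n: fits[n].aic)
    best_aic = fits[best].aic
    for name, f in fits.items():
        rows.append({
            "model": name, "chi2": f.chi2, "df": f.df, "p": f.p_value,
            "AIC": f.aic, "CFI": f.cfi, "SRMR": f.srmr,
            "fit": classify_fit(f.cfi, f.srmr),
            "dAIC": f.aic - best_aic, "best": name == best,
        })
    return pd.DataFrame(rows)


def delta_chi2(nested: FitResult, reference: FitResult) -> tuple[float, int, float]:
    """Nested-model chi-square difference test (nested has more df)."""
    d_chi = nested.chi2 - reference.chi2
    d_df = nested.df - reference.df
    p = float(stats.chi2.sf(max(d_chi, 0.0), d_df)) if d_df > 0 else np.nan
    return d_chi, d_df, p


def genetic_multiple_regression(stack: CovarianceStack, outcome: str,
                                predictors: list[str]) -> dict[str, tuple[float, float]]:
    """Partial genetic regression coefficients of ``outcome`` on ``predictors``.

    Solves the genetic normal equations beta = S_pp^-1 S_po on the
    stack's scale; standard errors propagate V through the numerical
    Jacobian of beta with respect to the involved vech(S) elements
    (delta method).
    """
    labels = predictors + [outcome]
    for l in labels:
        if l not in stack.labels:
            raise ModelError(f"trait '{l}' not in stack")
    t = stack.n_traits
    order = vech_indices(t)
    idx = {l: i for i, l in enumerate(stack.labels)}

    def beta_of(S: np.ndarray) -> np.ndarray:
        P = np.array([[S[idx[a], idx[b]] for b in predictors] for a in predictors])
        o = np.array([S[idx[a], idx[outcome]] for a in predictors])
        try:
            return np.linalg.solve(P, o)
        except np.linalg.LinAlgError as e:
            raise ModelError("singular predictor submatrix") from e

    beta = beta_of(stack.S)
    h = 1e-6
    Jac = np.zeros((len(predictors), len(order)))
    for q, (i, j) in enumerate(order):
        Sp = stack.S.copy()
        Sm = stack.S.copy()
        Sp[i, j] = Sp[j, i] = Sp[i, j] + h
        Sm[i, j] = Sm[j, i] = Sm[i, j] - h
        Jac[:, q] = (beta_of(Sp) - beta_of(Sm)) / (2 * h)
    cov = Jac @ stack.V @ Jac.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return {p: (float(b), float(s)) for p, b, s in zip(predictors, beta, se)}
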