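"""Per-SNP GWAS on latent genetic factors, with heterogeneity and QC filters.

For each SNP the genetic covariance matrix is augmented with the SNP as
an extra standardized variable: cov(SNP, trait_i) = z_i / sqrt(N_i) on
the standardized-genotype scale (SNP variance fixed to 1), with
sampling variances 1/N_i and zero assumed cross-terms appended to V.
The accepted factor model plus free SNP -> factor regressions is then
refitted per SNP (measurement parameters are re-estimated, warm-started
from the SNP-free solution), giving each factor's effect, sandwich SE,
Z and two-sided p.

Q-SNP heterogeneity compares this common-pathway model against an
independent-pathways model in which the SNP hits every indicator
directly: Q is the model chi-square difference, with
df = n_indicators - n_factor_paths, large values meaning the SNP's
indicator effects are not proportional to the loadings.

``run_latent_gwas`` chains the full QC sequence: PSD-smooth S and V,
drop SNPs whose factor Z moves by more than the threshold between the
pre- and post-smoothed runs (on any factor), drop SNPs with Q-SNP p
below the genome-wide threshold, and write one summary-statistics table
per factor.  The per-factor effective sample size reported in the
output is the chi-square-implied 1/SE^2 (median over SNPs), a
convention of this implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ldsc import CovarianceStack
from .models import ModelSpec
from .sem import CompiledModel, ModelError, _fit_moments, _safe_inverse, subset_stack
from .smoothing import nearest_psd, zdiff_filter
from .sumstats import AlignedPanel, SumStatsTable, p_from_z

logger = logging.getLogger(__name__)

__all__ = ["GwasFilters", "LatentGwasEngine", "GwasRunResult",
           "snp_to_covariances", "run_latent_gwas"]


@dataclass(frozen=True)
class GwasFilters:
    zdiff_threshold: float = 1.0
    qsnp_alpha: float = 5e-8
    apply_zdiff: bool = True
    apply_qsnp: bool = True


def snp_to_covariances(z_row: np.ndarray, n_row: np.ndarray,
                       stack: CovarianceStack) -> tuple[np.ndarray, np.ndarray]:
    """Augment (S, V) with one SNP as an extra variable (placed last).

    Returns ``S_plus`` of shape (t+1, t+1) with cov(SNP, trait_i) =
    z_i/sqrt(N_i) and var(SNP) = 1, and ``V_plus`` over the moment order
    [vech(S), cov(y, SNP)]: block-diagonal with the per-trait sampling
    variances 1/N_i and zero cross-terms (the fixed SNP variance is not
    a sampled moment).
    """
    t = stack.n_traits
    s_yg = np.asarray(z_row, float) / np.sqrt(np.asarray(n_row, float))
    S_plus = np.zeros((t + 1, t + 1))
    S_plus[:t, :t] = stack.S
    S_plus[t, :t] = S_plus[:t, t] = s_yg
    S_plus[t, t] = 1.0
    p_yy = t * (t + 1) // 2
    V_plus = np.zeros((p_yy + t, p_yy + t))
    V_plus[:p_yy, :p_yy] = stack.V
    V_plus[p_yy:, p_yy:] = np.diag(1.0 / np.asarray(n_row, float))
    return S_plus, V_plus


@dataclass
class GwasRunResult:
    factor_tables: dict[str, SumStatsTable]
    per_snp: pd.DataFrame
    report: dict


class LatentGwasEngine:
    """Reusable per-SNP fitter for one (stack, spec) pair."""

    def __init__(self, stack: CovarianceStack, spec: ModelSpec):
        self.spec = spec
        self.labels = list(spec.indicators)
        self.S, self.V = subset_stack(stack, self.labels)
        sub = CovarianceStack(self.labels, self.S, self.V, stack.n_blocks)
        self.stack = sub
        self.base = _fit_moments(spec, self.S, self.V)
        if not self.base.converged:
            raise ModelError(f"{spec.name}: SNP-free measurement model did not converge")
        self.Vi_yy = _safe_inverse(self.V)
        model = CompiledModel(spec)
        lam, _, _, _, _ = model.build(self.base.theta)
        self.lam_hat = lam
        self.t = model.t
        self.factors = list(spec.factors)

    def _vi_aug(self, n_row: np.ndarray) -> np.ndarray:
        p_yy = self.Vi_yy.shape[0]
        t = self.t
        Vi = np.zeros((p_yy + t, p_yy + t))
        Vi[:p_yy, :p_yy] = self.Vi_yy
        Vi[p_yy:, p_yy:] = np.diag(np.asarray(n_row, float))
        return Vi

    def fit_snp(self, z_row: np.ndarray, n_row: np.ndarray,
                with_qsnp: bool = True) -> dict:
        """Fit the SNP-augmented model(s) at one SNP.

        Returns per-factor (beta, se, z, p) from the common-pathway
        model plus, when requested, the Q-SNP statistic from the
        independent-pathways comparison.  Nonconvergence is flagged in
        the returned record, never raised.
        """
        s_yg = np.asarray(z_row, float) / np.sqrt(np.asarray(n_row, float))
        v_snp = 1.0 / np.asarray(n_row, float)
        Vi = self._vi_aug(n_row)
        b0 = np.linalg.lstsq(self.lam_hat, s_yg, rcond=None)[0]
        theta0 = np.concatenate([self.base.theta, b0])
        common = _fit_moments(self.spec, self.S, self.V, snp_mode="factors",
                              s_yg=s_yg, v_snp=v_snp, theta0=theta0, Vi=Vi)
        k_base = len(self.base.theta)
        rec: dict = {
            "converged": common.converged,
            # drift of the re-estimated measurement parameters from the
            # SNP-free solution (should be tiny for null SNPs)
            "max_measurement_shift": float(
                np.max(np.abs(common.theta[:k_base] - self.base.theta))),
        }
        for fac in self.factors:
            beta, se = common.estimates[("snp_path", fac)], common.se[("snp_path", fac)]
            z = beta / se if se > 0 else np.nan
            rec[fac] = {"beta": beta, "se": se, "z": z,
                        "p": float(p_from_z(np.array([z]))[0])}
        if with_qsnp:
            theta0d = np.concatenate([self.base.theta, s_yg])
            indep = _fit_moments(self.spec, self.S, self.V, snp_mode="indicators",
                                 s_yg=s_yg, v_snp=v_snp, theta0=theta0d, Vi=Vi)
            q = max(common.chi2 - indep.chi2, 0.0)
            q_df = self.t - len(self.factors)
            from scipy.stats import chi2 as chi2_dist
            rec["qsnp"] = {"chi2": q, "df": q_df,
                           "p": float(chi2_dist.sf(q, q_df))}
            rec["converged"] = rec["converged"] and indep.converged
        return rec

    def scan(self, panel: AlignedPanel, with_qsnp: bool = True) -> pd.DataFrame:
        """Fit every SNP in the panel; one row per SNP, columns per factor."""
        cols = {c: [] for fac in self.factors
                for c in (f"{fac}_beta", f"{fac}_se", f"{fac}_z", f"{fac}_p")}
        cols.update({"qsnp_chi2": [], "qsnp_df": [], "qsnp_p": [], "converged": []})
        tr_idx = [panel.traits.index(l) for l in self.labels]
        for r in range(panel.n_snps):
            rec = self.fit_snp(panel.Z[r, tr_idx], panel.N[r, tr_idx], with_qsnp)
            for fac in self.factors:
                for stat in ("beta", "se", "z", "p"):
                    cols[f"{fac}_{stat}"].append(rec[fac][stat])
            if with_qsnp:
                cols["qsnp_chi2"].append(rec["qsnp"]["chi2"])
                cols["qsnp_df"].append(rec["qsnp"]["df"])
                cols["qsnp_p"].append(rec["qsnp"]["p"])
            else:
                cols["qsnp_chi2"].append(np.nan)
                cols["qsnp_df"].append(0)
                cols["qsnp_p"].append(np.nan)
            cols["converged"].append(rec["converged"])
        df = pd.DataFrame(cols)
        df.insert(0, "SNP", panel.snps["SNP"].to_numpy())
        return df.set_index("SNP")


def _smooth_stack(stack: CovarianceStack):
    S_post, rep_s = nearest_psd(stack.S)
    V_post, rep_v = nearest_psd(stack.V)
    smoothed = CovarianceStack(list(stack.labels), S_post, V_post,
                               stack.n_blocks, stack.intercepts)
    return smoothed, rep_s, rep_v


def run_latent_gwas(panel: AlignedPanel, stack: CovarianceStack, spec: ModelSpec,
                    filters: GwasFilters = GwasFilters()) -> GwasRunResult:
    """Full factor GWAS with the smoothing, Z-difference and Q-SNP filters."""
    smoothed, rep_s, rep_v = _smooth_stack(stack)
    engine = LatentGwasEngine(smoothed, spec)
    post = engine.scan(panel, with_qsnp=filters.apply_qsnp)
    factors = list(spec.factors)
    zcols = [f"{f}_z" for f in factors]

    removed_zdiff: set[str] = set()
    if filters.apply_zdiff and (rep_s.changed or rep_v.changed):
        pre_engine = LatentGwasEngine(stack, spec)
        pre = pre_engine.scan(panel, with_qsnp=False)
        retained, log = zdiff_filter(pre[zcols], post[zcols], filters.zdiff_threshold)
        removed_zdiff = set(post.index) - set(retained)
        logger.info("z-difference filter removed %d SNPs", len(removed_zdiff))
    removed_qsnp: set[str] = set()
    if filters.apply_qsnp:
        mask = post["qsnp_p"] < filters.qsnp_alpha
        removed_qsnp = set(post.index[mask]) - removed_zdiff

    per_snp = post.copy()
    per_snp["zdiff_removed"] = per_snp.index.isin(removed_zdiff)
    per_snp["qsnp_removed"] = per_snp.index.isin(removed_qsnp)
    keep = ~(per_snp["zdiff_removed"] | per_snp["qsnp_removed"])

    meta = panel.snps.set_index("SNP")
    tables: dict[str, SumStatsTable] = {}
    for fac in factors:
        se = per_snp[f"{fac}_se"].to_numpy(float)
        with np.errstate(divide="ignore"):
            n_eff = np.where(se > 0, 1.0 / se**2, np.nan)
        n_report = float(np.nanmedian(n_eff[keep.to_numpy()]))
        df = pd.DataFrame({
            "SNP": per_snp.index,
            "CHR": meta.loc[per_snp.index, "CHR"].to_numpy(),
            "BP": meta.loc[per_snp.index, "BP"].to_numpy(),
            "A1": meta.loc[per_snp.index, "A1"].to_numpy(),
            "A2": meta.loc[per_snp.index, "A2"].to_numpy(),
            "Z": per_snp[f"{fac}_z"].to_numpy(float),
            "N": n_report,
            "P": per_snp[f"{fac}_p"].to_numpy(float),
            "BETA": per_snp[f"{fac}_beta"].to_numpy(float),
            "SE": se,
            "FACTOR": fac,
            "QSNP_P": per_snp["qsnp_p"].to_numpy(float),
        })
        tables[fac] = SumStatsTable(f"{fac}", df.loc[keep.to_numpy()].reset_index(drop=True))

    report = {
        "n_input": int(panel.n_snps),
        "n_zdiff_removed": len(removed_zdiff),
        "n_qsnp_removed": len(removed_qsnp),
        "n_output": int(keep.sum()),
        "zdiff_threshold": filters.zdiff_threshold,
        "qsnp_alpha": filters.qsnp_alpha,
        "smoothing_S": vars(rep_s),
        "smoothing_V": vars(rep_v),
        "n_nonconverged": int((~per_snp["converged"]).sum()),
    }
    assert report["n_input"] - report["n_output"] == (
        report["n_zdiff_removed"] + report["n_qsnp_removed"])
    return GwasRunResult(tables, per_snp, report)
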