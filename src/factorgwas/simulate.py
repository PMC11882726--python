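"""Simulation of multi-cohort GWAS summary statistics from a latent factor model.

Summary statistics are drawn directly at the Z-score level from the
moment structure assumed by LD-score regression: for SNP j with LD score
l_j out of M SNPs,

    E[z_ij^2]      = 1 + N_i * h_i^2 * l_j / M
    E[z_ij z_kj]   = sqrt(N_i N_k) * sigma_g,ik * l_j / M + c_ik

where ``sigma_g`` is the genetic covariance implied by the generating
factor model (S = Lambda diag(factor_h2) Lambda' + diag(specific_h2),
phenotypes standardized to unit variance) and ``c_ik`` is the cross-trait
intercept induced by sample overlap (overlap fraction x phenotypic
correlation of the overlapping samples).  Z vectors are independent
across SNPs, multivariate normal within a SNP.  No individual-level
genotypes and no LD block structure are simulated: the generator matches
exactly the assumptions the downstream estimators use, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import AlignedPanel, SumStatsTable, p_from_z

__all__ = [
    "TraitSpec",
    "GeneratorConfig",
    "simulate_ld_scores",
    "simulate_sumstats",
    "simulate_panel",
    "simulate_snp_block",
    "default_demo_config",
    "write_ld_scores",
    "read_ld_scores",
]


class GeneratorError(ValueError):
    """Raised for inconsistent generator configurations."""


@dataclass(frozen=True)
class TraitSpec:
    label: str
    n: int
    reverse_coded: bool = False


@dataclass
class GeneratorConfig:
    """Generating model for a multi-cohort panel of GWAS summary statistics.

    ``loadings`` is the (traits x factors) matrix of standardized genetic
    loadings; with ``factor_h2`` the per-factor variance shares and
    ``specific_h2`` the per-trait residual genetic variances, the
    generating genetic covariance matrix (phenotype-standardized, so its
    diagonal is SNP heritability) is

        S = loadings @ diag(factor_h2) @ loadings.T + diag(specific_h2).

    ``overlap`` holds the pairwise shared-sample fraction (of the
    geometric-mean N) and ``overlap_rho`` the phenotypic correlation in
    the overlapping samples; their product is the cross-trait LDSC
    intercept of the pair.
    """

    m_snps: int
    traits: list[TraitSpec]
    loadings: np.ndarray
    factor_h2: np.ndarray
    specific_h2: np.ndarray
    overlap: np.ndarray | None = None
    overlap_rho: float = 0.0
    ldscore_law: tuple = ("gamma", {"mean": 10.0, "shape": 2.0})
    seed: int = 0
    factor_labels: list[str] = field(default_factory=list)

    def genetic_covariance(self) -> np.ndarray:
        lam = np.asarray(self.loadings, float)
        S = lam @ np.diag(np.asarray(self.factor_h2, float)) @ lam.T
        S[np.diag_indices_from(S)] += np.asarray(self.specific_h2, float)
        return S

    def intercept_matrix(self) -> np.ndarray:
        t = len(self.traits)
        C = np.eye(t)
        if self.overlap is not None:
            ov = np.asarray(self.overlap, float)
            if ov.shape != (t, t) or not np.allclose(ov, ov.T) or not np.allclose(np.diag(ov), 1.0):
                raise GeneratorError("overlap must be symmetric with unit diagonal")
            off = ov * self.overlap_rho
            C = off - np.diag(np.diag(off)) + np.eye(t)
        return C

    def validate(self) -> None:
        t = len(self.traits)
        lam = np.asarray(self.loadings, float)
        if lam.shape[0] != t:
            raise GeneratorError("loadings rows must match number of traits")
        if np.any(np.asarray(self.specific_h2, float) < 0):
            raise GeneratorError("specific_h2 must be non-negative")
        h2 = np.diag(self.genetic_covariance())
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise GeneratorError(
                f"per-trait SNP heritability out of [0,1]: {np.round(h2, 4)}"
            )
        self.intercept_matrix()


def simulate_ld_scores(m_snps: int, ldscore_law=("gamma", {"mean": 10.0, "shape": 2.0}),
                       seed: int = 0) -> pd.DataFrame:
    """Draw per-SNP LD scores l_j >= 1 from a named law.

    Laws: ``("constant", {"value": v})``; ``("uniform", {"low": a, "high": b})``;
    ``("gamma", {"mean": mu, "shape": k})`` giving 1 + Gamma(k, (mu-1)/k).
    Returns a DataFrame with columns ``SNP`` and ``L2``.
    """
    if m_snps < 1:
        raise GeneratorError("m_snps must be >= 1")
    name, params = ldscore_law
    rng = np.random.default_rng(seed)
    if name == "constant":
        l2 = np.full(m_snps, float(params.get("value", 1.0)))
    elif name == "uniform":
        l2 = rng.uniform(params["low"], params["high"], size=m_snps)
    elif name == "gamma":
        shape = float(params.get("shape", 2.0))
        mean = float(params.get("mean", 10.0))
        if mean < 1:
            raise GeneratorError("gamma law mean must be >= 1")
        l2 = 1.0 + rng.gamma(shape, (mean - 1.0) / shape, size=m_snps)
    else:
        raise GeneratorError(f"unknown ldscore law '{name}'")
    l2 = np.maximum(l2, 1.0)
    snps = [f"rs{j + 1}" for j in range(m_snps)]
    return pd.DataFrame({"SNP": snps, "L2": l2})


def _snp_frame(m: int) -> pd.DataFrame:
    """Deterministic SNP identities: 22 contiguous chromosome blocks, 10 kb spacing."""
    chrom = 1 + (np.arange(m) * 22) // max(m, 1)
    per_chr = np.zeros(m, dtype=np.int64)
    counts: dict[int, int] = {}
    for j, c in enumerate(chrom):
        counts[c] = counts.get(c, 0) + 1
        per_chr[j] = counts[c]
    return pd.DataFrame({
        "SNP": [f"rs{j + 1}" for j in range(m)],
        "CHR": chrom.astype(str),
        "BP": per_chr * 10_000,
        "A1": "A",
        "A2": "G",
    })


def simulate_sumstats(config: GeneratorConfig,
                      ldscores: pd.DataFrame | None = None) -> tuple[list[SumStatsTable], pd.DataFrame]:
    """Simulate one summary-statistics table per trait plus the LD-score table.

    Z vectors are drawn per SNP from N(0, l_j * A + C) with
    A = diag(sqrt(N)) S diag(sqrt(N)) / M and C the intercept matrix;
    reverse-coded traits have their Z negated afterwards.  Deterministic
    for a fixed ``config.seed``.
    """
    config.validate()
    m, t = config.m_snps, len(config.traits)
    rng = np.random.default_rng(config.seed)
    if ldscores is None:
        ldscores = simulate_ld_scores(m, config.ldscore_law, seed=config.seed + 1)
    l2 = ldscores["L2"].to_numpy(float)
    if len(l2) != m:
        raise GeneratorError("ldscores length must equal m_snps")
    N = np.array([tr.n for tr in config.traits], float)
    S = config.genetic_covariance()
    C = config.intercept_matrix()
    A = np.sqrt(np.outer(N, N)) * S / m
    # batched Cholesky over SNPs (chunked to bound memory)
    Z = np.empty((m, t))
    chunk = 20_000
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        cov = l2[lo:hi, None, None] * A[None, :, :] + C[None, :, :]
        for jitter in (0.0, 1e-10, 1e-8, 1e-6):
            try:
                L = np.linalg.cholesky(cov + jitter * np.eye(t)[None, :, :])
                break
            except np.linalg.LinAlgError:  # exactly singular (e.g. trait copies)
                continue
        else:
            raise GeneratorError("per-SNP covariance not positive semidefinite")
        eps = rng.standard_normal((hi - lo, t, 1))
        Z[lo:hi] = (L @ eps)[:, :, 0]
    base = _snp_frame(m)
    tables = []
    for i, tr in enumerate(config.traits):
        zi = -Z[:, i] if tr.reverse_coded else Z[:, i]
        df = base.copy()
        df["Z"] = zi
        df["N"] = float(tr.n)
        df["P"] = p_from_z(zi)
        tables.append(SumStatsTable(tr.label, df))
    return tables, ldscores


def simulate_panel(config: GeneratorConfig,
                   ldscores: pd.DataFrame | None = None) -> tuple[AlignedPanel, pd.DataFrame]:
    """Simulate directly into an :class:`AlignedPanel` (single orientation)."""
    tables, ld = simulate_sumstats(config, ldscores)
    Z = np.column_stack([t.data["Z"].to_numpy() for t in tables])
    N = np.column_stack([t.data["N"].to_numpy() for t in tables])
    snps = tables[0].data[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    return AlignedPanel(snps, [t.trait for t in tables], Z, N), ld


def simulate_snp_block(n_snps: int, sample_sizes: np.ndarray,
                       trait_beta: np.ndarray | None = None,
                       intercepts: np.ndarray | None = None,
                       seed: int = 0,
                       label_offset: int = 0) -> AlignedPanel:
    """Simulate a block of individual test SNPs with known per-trait effects.

    ``trait_beta`` holds the true per-trait SNP effects on the
    standardized-genotype, standardized-phenotype scale (one row per SNP,
    or one row broadcast to all SNPs; ``None`` means null everywhere):
    Z_i = sqrt(N_i) * beta_i + noise with noise ~ N(0, intercepts).
    Used for factor-GWAS calibration and power checks.
    """
    N = np.asarray(sample_sizes, float)
    t = len(N)
    rng = np.random.default_rng(seed)
    C = np.eye(t) if intercepts is None else np.asarray(intercepts, float)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n_snps, t)) @ L.T
    if trait_beta is not None:
        beta = np.atleast_2d(np.asarray(trait_beta, float))
        Z = Z + np.sqrt(N)[None, :] * beta
    snps = _snp_frame(n_snps).copy()
    snps["SNP"] = [f"qs{label_offset + j + 1}" for j in range(n_snps)]
    traits = [f"trait{i + 1}" for i in range(t)]
    return AlignedPanel(snps, traits, Z, np.tile(N, (n_snps, 1)))


# --- demo configuration mirroring the study design ----------------------

#: retained indicators with study sample sizes
DEMO_TRAITS = [
    TraitSpec("UKB_Trails", 93_024),
    TraitSpec("UKB_Pairs", 81_701),
    TraitSpec("UKB_SDST", 84_125, reverse_coded=True),
    TraitSpec("UKB_Digit", 81_701),
    TraitSpec("UKB_PMemory", 162_335),
    TraitSpec("CHARGE_DSST", 32_070),
    TraitSpec("CHARGE_Stroop", 12_866, reverse_coded=True),
    TraitSpec("ALSPAC_WM", 4_611),
    TraitSpec("NIH_G4", 9_879, reverse_coded=True),
]

DEMO_FACTORS = ["EF", "WM", "SUB"]

#: which traits load on the working-memory and substitution specific factors
_WM_TRAITS = {"UKB_Digit", "UKB_Pairs", "ALSPAC_WM", "NIH_G4"}
_SUB_TRAITS = {"UKB_SDST", "CHARGE_DSST"}

#: generating SNP heritabilities, shaped like the study's estimates
DEMO_H2 = {
    "UKB_Trails": 0.1141, "UKB_Pairs": 0.3765, "UKB_SDST": 0.1564,
    "UKB_Digit": 0.1433, "UKB_PMemory": 0.0368, "CHARGE_DSST": 0.156,
    "CHARGE_Stroop": 0.1035, "ALSPAC_WM": 0.279, "NIH_G4": 0.3436,
}


def default_demo_config(m_snps: int = 50_000, seed: int = 0,
                        overlap_rho: float = 0.25) -> GeneratorConfig:
    """Nine-trait generating model patterned on the accepted bifactor structure.

    A general factor loads every indicator with ~55% of each trait's
    genetic variance; orthogonal working-memory and substitution factors
    carry a further ~25% for their indicators; the remainder is
    trait-specific.  The five biobank traits share 80% of their samples
    (phenotypic correlation ``overlap_rho`` in the overlap), emulating
    cohort-level sample overlap; other pairs are disjoint.
    """
    t = len(DEMO_TRAITS)
    lam = np.zeros((t, 3))
    spec = np.zeros(t)
    for i, tr in enumerate(DEMO_TRAITS):
        h2 = DEMO_H2[tr.label]
        shares = {"EF": 0.55}
        if tr.label in _WM_TRAITS:
            shares["WM"] = 0.25
        if tr.label in _SUB_TRAITS:
            # DSST carries no specific variance beyond the substitution
            # factor, matching the accepted model's fixed-zero residual
            shares["SUB"] = 0.45 if tr.label == "CHARGE_DSST" else 0.25
        for f, share in shares.items():
            lam[i, DEMO_FACTORS.index(f)] = np.sqrt(share * h2)
        spec[i] = h2 * (1.0 - sum(shares.values()))
    overlap = np.eye(t)
    ukb = [i for i, tr in enumerate(DEMO_TRAITS) if tr.label.startswith("UKB_")]
    for i in ukb:
        for k in ukb:
            if i != k:
                overlap[i, k] = 0.8
    return GeneratorConfig(
        m_snps=m_snps,
        traits=list(DEMO_TRAITS),
        loadings=lam,
        factor_h2=np.ones(3),
        specific_h2=spec,
        overlap=overlap,
        overlap_rho=overlap_rho,
        seed=seed,
        factor_labels=list(DEMO_FACTORS),
    )


def write_ld_scores(ldscores: pd.DataFrame, path, m_path=None) -> None:
    """Write the two-column (SNP, L2) LD-score file and optional M count file."""
    ldscores.to_csv(path, sep="\t", index=False, columns=["SNP", "L2"])
    if m_path is not None:
        with open(m_path, "w") as fh:
            fh.write(f"{len(ldscores)}\n")


def read_ld_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    if not {"SNP", "L2"}.issubset(df.columns):
        raise GeneratorError(f"{path}: LD-score file needs SNP and L2 columns")
    return df[["SNP", "L2"]]
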