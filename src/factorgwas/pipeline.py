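"""End-to-end orchestration: simulate/read -> LDSC -> screen -> smooth -> CFA zoo -> factor GWAS -> post-GWAS.

One declarative YAML config drives every stage; the resolved config is
written verbatim into the run directory before any computation so a run
is fully auditable.  A single top-level seed governs all stochastic
stages through a documented derivation (child seed = (seed + crc32 of
the stage name) mod 2^31), giving reproducibility with stage-level
independence.  Stage artifacts are written as each stage completes,
even when a later stage fails; configuration errors fail fast, per-SNP
numerical problems fail late (the offending SNP is flagged).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import gwas as gwas_mod
from . import ldsc as ldsc_mod
from . import postgwas as post_mod
from . import sem as sem_mod
from . import simulate as sim_mod
from . import sumstats as ss_mod
from .models import model_zoo, parse_model_dsl

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fit_report", "parse_fit_report"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Schema-validated configuration for one pipeline run."""

    outdir: str
    seed: int
    mode: str = "synthetic"                  # synthetic | files
    # synthetic mode
    m_snps: int = 20_000
    overlap_rho: float = 0.25
    # files mode
    sumstats_files: list[str] = field(default_factory=list)
    trait_labels: list[str] = field(default_factory=list)
    reverse_coded: list[str] = field(default_factory=list)
    ldscore_file: str | None = None
    m_total: int | None = None
    # LDSC options
    n_blocks: int = 100
    h2_z_threshold: float = 1.645
    collinearity_r: float = 0.9
    # models
    models: list[str] = field(default_factory=lambda: ["zoo"])
    gwas_model: str = "bifactor_wm_substitution"
    custom_model_dsl: str | None = None
    # GWAS filters
    zdiff_threshold: float = 1.0
    qsnp_alpha: float = 5e-8
    gwas_max_snps: int | None = 200
    # post-GWAS
    p_sig: float = 5e-8
    r2_indep: float = 0.6
    r2_lead: float = 0.1
    merge_window: int = 250_000
    r2_novel: float = 0.6
    ld_file: str | None = None
    prior_snps_file: str | None = None
    prior_loci_file: str | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as e:
            raise ConfigError(str(e)) from e
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be synthetic|files, got {self.mode!r}")
        if self.mode == "files" and not self.sumstats_files:
            raise ConfigError("files mode needs sumstats_files")
        if self.mode == "files" and (self.ldscore_file is None or self.m_total is None):
            raise ConfigError("files mode needs ldscore_file and m_total")
        for name, val in (("qsnp_alpha", self.qsnp_alpha), ("p_sig", self.p_sig),
                          ("r2_indep", self.r2_indep), ("r2_lead", self.r2_lead),
                          ("r2_novel", self.r2_novel)):
            if not 0.0 < val < 1.0:
                raise ConfigError(f"{name} must lie in (0,1)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + zlib.crc32(stage.encode())) % (2**31)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _model_set(config: PipelineConfig) -> dict:
    zoo = model_zoo()
    out = {}
    for name in config.models:
        if name == "zoo":
            out.update(zoo)
        elif name == "custom":
            if not config.custom_model_dsl:
                raise ConfigError("models includes 'custom' but custom_model_dsl empty")
            spec = parse_model_dsl(config.custom_model_dsl, name="custom")
            out["custom"] = spec
        elif name in zoo:
            out[name] = zoo[name]
        else:
            raise ConfigError(f"unknown model '{name}'")
    return out


# --- stages -------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path):
    gen = sim_mod.default_demo_config(m_snps=config.m_snps,
                                      seed=config.stage_seed("simulate"),
                                      overlap_rho=config.overlap_rho)
    tables, ldscores = sim_mod.simulate_sumstats(gen)
    ssdir = outdir / "sumstats"
    ssdir.mkdir(exist_ok=True)
    for t in tables:
        ss_mod.write_sumstats(t, ssdir / f"{t.trait}.sumstats")
    sim_mod.write_ld_scores(ldscores, outdir / "ldscores.l2.ldscore",
                            outdir / "ldscores.l2.M")
    # flip the traits distributed on a higher-is-worse scale, as the
    # analysis does before modelling
    tables = [ss_mod.reverse_code(t) if tr.reverse_coded else t
              for t, tr in zip(tables, gen.traits)]
    return tables, ldscores, gen


def stage_read(config: PipelineConfig):
    dialect = ss_mod.CANONICAL_DIALECT
    tables = []
    labels = config.trait_labels or [None] * len(config.sumstats_files)
    for path, label in zip(config.sumstats_files, labels):
        t = ss_mod.read_sumstats(path, dialect, trait=label)
        if t.trait in config.reverse_coded:
            t = ss_mod.reverse_code(t)
        tables.append(t)
    ldscores = sim_mod.read_ld_scores(config.ldscore_file)
    return tables, ldscores, None


def stage_ldsc(config: PipelineConfig, tables, ldscores, m, outdir: Path):
    panel = ss_mod.merge_cohorts(tables)
    stack = ldsc_mod.build_covariance_stack(panel, ldscores, m, config.n_blocks)
    stack.to_json(outdir / "covariance_stack.json")
    screen = ldsc_mod.screen_indicators(stack, config.h2_z_threshold,
                                        config.collinearity_r)
    with open(outdir / "screen_report.json", "w") as fh:
        json.dump({"retained": screen.retained, "excluded": screen.excluded,
                   "h2_z_threshold": config.h2_z_threshold,
                   "collinearity_r": config.collinearity_r}, fh, indent=1)
    return panel, stack, screen


def stage_fit(config: PipelineConfig, stack, outdir: Path):
    specs = _model_set(config)
    usable = {n: s for n, s in specs.items()
              if set(s.indicators) <= set(stack.labels)}
    fits = sem_mod.fit_many(stack, usable)
    report = make_fit_report(fits)
    (outdir / "fit_report.txt").write_text(report)
    return fits


def stage_gwas(config: PipelineConfig, panel, stack, outdir: Path):
    specs = _model_set(config)
    zoo = model_zoo()
    spec = specs.get(config.gwas_model) or zoo.get(config.gwas_model)
    if spec is None:
        raise ConfigError(f"gwas_model '{config.gwas_model}' not defined")
    if config.gwas_max_snps is not None and panel.n_snps > config.gwas_max_snps:
        panel = ss_mod.AlignedPanel(panel.snps.iloc[: config.gwas_max_snps].copy(),
                                    list(panel.traits),
                                    panel.Z[: config.gwas_max_snps],
                                    panel.N[: config.gwas_max_snps])
    filters = gwas_mod.GwasFilters(config.zdiff_threshold, config.qsnp_alpha)
    run = gwas_mod.run_latent_gwas(panel, stack, spec, filters)
    for fac, table in run.factor_tables.items():
        ss_mod.write_sumstats(table, outdir / f"factor_{fac}.sumstats",
                              extra_columns=("BETA", "SE", "FACTOR", "QSNP_P"))
    with open(outdir / "gwas_report.json", "w") as fh:
        json.dump(run.report, fh, indent=1, default=float)
    return run


def stage_postgwas(config: PipelineConfig, run, outdir: Path):
    ld = post_mod.LDTable.from_file(config.ld_file) if config.ld_file else post_mod.LDTable()
    prior_snps = (post_mod.read_prior_snps(config.prior_snps_file)
                  if config.prior_snps_file else [])
    prior_loci = (post_mod.read_prior_loci(config.prior_loci_file)
                  if config.prior_loci_file else [])
    results = {}
    for fac, table in run.factor_tables.items():
        clumps = post_mod.clump(table, ld, config.p_sig, config.r2_indep,
                                config.r2_lead)
        loci = post_mod.define_loci(table, clumps, config.merge_window)
        novelty = post_mod.novelty_filter(clumps.independent, loci, prior_snps,
                                          prior_loci, ld, config.r2_novel)
        results[fac] = (clumps, loci, novelty)
        (outdir / f"{fac}_independent_snps.txt").write_text(
            "\n".join(clumps.independent) + ("\n" if clumps.independent else ""))
        (outdir / f"{fac}_lead_snps.txt").write_text(
            "\n".join(clumps.leads) + ("\n" if clumps.leads else ""))
        with open(outdir / f"{fac}_loci.txt", "w") as fh:
            for loc in loci:
                fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.lead}\n")
        with open(outdir / f"{fac}_novelty.json", "w") as fh:
            json.dump({"novel_snps": novelty.novel_snps,
                       "novel_loci": [[l.chrom, l.start, l.end] for l in novelty.novel_loci],
                       "audit": novelty.audit}, fh, indent=1)
    return results


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.dump(outdir / "resolved_config.yaml")
    pkg_logger = logging.getLogger("factorgwas")
    pkg_logger.setLevel(logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    pkg_logger.addHandler(fh)
    try:
        logger.info("thresholds: h2_z=%s collinearity_r=%s zdiff=%s qsnp_alpha=%s "
                    "p_sig=%s r2_indep=%s r2_lead=%s r2_novel=%s",
                    config.h2_z_threshold, config.collinearity_r,
                    config.zdiff_threshold, config.qsnp_alpha, config.p_sig,
                    config.r2_indep, config.r2_lead, config.r2_novel)
        if config.mode == "synthetic":
            tables, ldscores, gen = stage_simulate(config, outdir)
            m = config.m_snps
        else:
            tables, ldscores, gen = stage_read(config)
            m = config.m_total
        panel, stack, screen = stage_ldsc(config, tables, ldscores, m, outdir)
        if screen.retained != list(stack.labels):
            retained_tables = [t for t in tables if t.trait in screen.retained]
            if len(retained_tables) < 2:
                raise ldsc_mod.LdscInputError("fewer than two indicators retained")
            panel = ss_mod.merge_cohorts(retained_tables)
            stack = ldsc_mod.build_covariance_stack(panel, ldscores, m,
                                                    config.n_blocks)
        stage_fit(config, stack, outdir)
        run = stage_gwas(config, panel, stack, outdir)
        stage_postgwas(config, run, outdir)
    finally:
        pkg_logger.removeHandler(fh)
        fh.close()
    return outdir


# --- fit report ---------------------------------------------------------

_REPORT_COLS = ["model", "chi2", "df", "p", "AIC", "CFI", "SRMR", "fit", "best"]


def make_fit_report(fits: dict) -> str:
    """Render fits as a text table (columns: model, chi2, df, p, AIC, CFI, SRMR)."""
    if not fits:
        raise ValueError("make_fit_report needs at least one fit")
    df = sem_mod.compare_models(fits)
    df = df[_REPORT_COLS]
    return df.to_csv(sep="\t", index=False, float_format="%.10g")


def parse_fit_report(text: str):
    """Parse :func:`make_fit_report` output back into a DataFrame (lossless)."""
    import io

    import pandas as pd

    return pd.read_csv(io.StringIO(text), sep="\t")
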