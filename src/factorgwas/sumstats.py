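"""Reading, harmonizing and merging GWAS summary statistics.

The canonical dialect is the munged-sumstats layout used by LD-score
regression tooling: whitespace/tab-delimited text with a header row and
columns ``SNP A1 A2 Z N P`` (plus optional ``CHR BP MAF``).  ``A1`` is
always the effect allele and ``Z`` is signed on the A1 count scale.
Files carrying ``BETA``/``SE`` instead of ``Z`` are converted on read.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column names, in output order
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P", "MAF")

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that cannot be oriented without strand information
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumstatsError(ValueError):
    """Raised for malformed or empty summary-statistics input."""


class DialectError(ValueError):
    """Raised when a column map cannot satisfy the mandatory columns."""


@dataclass(frozen=True)
class Dialect:
    """Column-name map from canonical names to file headers, plus defaults.

    ``columns`` maps canonical names (``SNP``, ``A1``, ...) to the header
    used in the file; canonical names absent from the map are looked up
    under their own name (case-insensitive).  ``defaults`` supplies
    per-trait constants for columns missing entirely, e.g. a study-level
    sample size when no per-SNP ``N`` column exists.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    defaults: Mapping[str, float] = field(default_factory=dict)

    def resolve(self, header: Sequence[str]) -> dict[str, str]:
        lower = {h.lower(): h for h in header}
        out: dict[str, str] = {}
        for canon in ("SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P", "MAF", "BETA", "SE"):
            name = self.columns.get(canon, canon)
            if name.lower() in lower:
                out[canon] = lower[name.lower()]
        return out


CANONICAL_DIALECT = Dialect()


@dataclass
class SumStatsTable:
    """Per-SNP association records for a single trait.

    Invariants: rsIDs unique, Z finite, N >= 1, P in (0, 1], A1 != A2.
    Enforced by :meth:`validate`, which drops offending rows and logs
    the count rather than failing.
    """

    trait: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SumStatsTable":
        return SumStatsTable(self.trait, self.data.copy())

    def validate(self) -> "SumStatsTable":
        """Drop rows violating the table invariants; log the removal count."""
        df = self.data
        n0 = len(df)
        keep = (
            np.isfinite(df["Z"].to_numpy(float))
            & (df["N"].to_numpy(float) >= 1)
            & (df["P"].to_numpy(float) > 0)
            & (df["P"].to_numpy(float) <= 1)
            & (df["A1"] != df["A2"])
            & df["A1"].isin(_VALID_ALLELES)
            & df["A2"].isin(_VALID_ALLELES)
        )
        df = df.loc[keep]
        df = df.drop_duplicates(subset="SNP", keep="first")
        dropped = n0 - len(df)
        if dropped:
            logger.info("%s: dropped %d invalid/duplicate rows", self.trait, dropped)
        if len(df) == 0:
            raise SumstatsError(f"{self.trait}: no valid rows after filtering")
        return SumStatsTable(self.trait, df.reset_index(drop=True))


def read_sumstats(path, dialect: Dialect = CANONICAL_DIALECT, trait: str | None = None) -> SumStatsTable:
    """Read one trait's summary statistics from whitespace-delimited text.

    ``BETA``/``SE`` are converted to ``Z = BETA/SE`` when no ``Z`` column is
    mapped; ``P`` is recomputed from ``Z`` (two-sided normal) when absent;
    a missing ``N`` column falls back to ``dialect.defaults['N']``.
    """
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        raw = pd.read_csv(fh, sep=r"\s+")
    if raw.empty:
        raise SumstatsError(f"{path}: empty file")
    cols = dialect.resolve(raw.columns)
    for mandatory in ("SNP", "A1", "A2"):
        if mandatory not in cols:
            raise DialectError(f"{path}: cannot map mandatory column {mandatory}")
    if "Z" not in cols and not ("BETA" in cols and "SE" in cols):
        raise DialectError(f"{path}: need Z or BETA+SE")

    df = pd.DataFrame({"SNP": raw[cols["SNP"]].astype(str)})
    df["CHR"] = raw[cols["CHR"]].astype(str) if "CHR" in cols else "0"
    df["BP"] = raw[cols["BP"]].astype(np.int64) if "BP" in cols else 0
    df["A1"] = raw[cols["A1"]].astype(str).str.upper()
    df["A2"] = raw[cols["A2"]].astype(str).str.upper()
    if "Z" in cols:
        df["Z"] = raw[cols["Z"]].astype(float)
    else:
        se = raw[cols["SE"]].astype(float)
        df["Z"] = raw[cols["BETA"]].astype(float) / se.where(se != 0, np.nan)
    if "N" in cols:
        df["N"] = raw[cols["N"]].astype(float)
    elif "N" in dialect.defaults:
        df["N"] = float(dialect.defaults["N"])
    else:
        raise DialectError(f"{path}: no N column and no default N")
    if "P" in cols:
        df["P"] = raw[cols["P"]].astype(float)
    else:
        df["P"] = p_from_z(df["Z"].to_numpy())
    if "MAF" in cols:
        df["MAF"] = raw[cols["MAF"]].astype(float)
    label = trait if trait is not None else path.rsplit("/", 1)[-1].split(".")[0]
    return SumStatsTable(label, df).validate()


def write_sumstats(table: SumStatsTable, path, extra_columns: Iterable[str] = ()) -> None:
    """Write a table in the canonical dialect (tab-separated, header row)."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.data.columns]
    cols += [c for c in extra_columns if c in table.data.columns and c not in cols]
    table.data.to_csv(path, sep="\t", index=False, columns=cols)


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided normal p-value, clipped into (0, 1]."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def reverse_code(table: SumStatsTable) -> SumStatsTable:
    """Flip a trait's direction of effect by negating every Z score.

    Used so positive loadings correspond to better task performance for
    traits scored with higher = worse (error counts, reaction times).
    P, N and alleles are untouched; applying twice is the identity.
    """
    out = table.copy()
    out.data["Z"] = -out.data["Z"].to_numpy()
    return out


def harmonize_alleles(table: SumStatsTable, reference: Mapping[str, tuple[str, str]]) -> SumStatsTable:
    """Orient a table's alleles to a reference rsid -> (A1, A2) map.

    Rows whose alleles are swapped relative to the reference (directly or on
    the opposite strand) have Z negated and alleles replaced by the
    reference pair.  Strand-ambiguous rows (A/T, C/G) and rows whose alleles
    are incompatible with the reference are dropped (logged, not fatal).
    Rows absent from the reference pass through unchanged.
    """
    df = table.data
    a1 = df["A1"].to_numpy(object)
    a2 = df["A2"].to_numpy(object)
    z = df["Z"].to_numpy(float).copy()
    maf = df["MAF"].to_numpy(float).copy() if "MAF" in df.columns else None
    keep = np.ones(len(df), bool)
    n_ambig = n_incompat = 0
    for i, rsid in enumerate(df["SNP"]):
        if (a1[i], a2[i]) in AMBIGUOUS_PAIRS:
            keep[i] = False
            n_ambig += 1
            continue
        ref = reference.get(rsid)
        if ref is None:
            continue
        r1, r2 = ref
        f1, f2 = _COMPLEMENT[a1[i]], _COMPLEMENT[a2[i]]
        if (a1[i], a2[i]) == (r1, r2) or (f1, f2) == (r1, r2):
            pass  # already oriented (possibly via strand flip)
        elif (a2[i], a1[i]) == (r1, r2) or (f2, f1) == (r1, r2):
            z[i] = -z[i]
            if maf is not None:
                maf[i] = 1.0 - maf[i]
        else:
            keep[i] = False
            n_incompat += 1
            continue
        a1[i], a2[i] = r1, r2
    if n_ambig or n_incompat:
        logger.info(
            "%s: dropped %d strand-ambiguous and %d allele-incompatible rows",
            table.trait, n_ambig, n_incompat,
        )
    out = df.copy()
    out["A1"] = a1
    out["A2"] = a2
    out["Z"] = z
    if maf is not None:
        out["MAF"] = maf
    return SumStatsTable(table.trait, out.loc[keep].reset_index(drop=True))


@dataclass
class AlignedPanel:
    """Multi-trait Z/N matrices on the rsID intersection of several tables.

    All traits share one allele orientation per SNP (the first input
    table's); ``Z`` and ``N`` are (n_snps, n_traits) arrays with columns
    ordered as the input tables.
    """

    snps: pd.DataFrame  # SNP, CHR, BP, A1, A2
    traits: list[str]
    Z: np.ndarray
    N: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def sorted_by_position(self) -> "AlignedPanel":
        order = np.lexsort((self.snps["BP"].to_numpy(), self.snps["CHR"].to_numpy()))
        return AlignedPanel(
            self.snps.iloc[order].reset_index(drop=True),
            list(self.traits), self.Z[order], self.N[order],
        )


def merge_cohorts(tables: Sequence[SumStatsTable]) -> AlignedPanel:
    """Intersect >= 2 cohort tables on rsID and harmonize to the first table.

    Raises :class:`SumstatsError` naming the first non-overlapping pair if
    the intersection is empty.
    """
    if len(tables) < 2:
        raise SumstatsError("merge_cohorts requires at least two tables")
    first = tables[0]
    common = set(first.data["SNP"])
    for t in tables[1:]:
        nxt = common & set(t.data["SNP"])
        if not nxt:
            raise SumstatsError(
                f"no shared SNPs between '{first.trait}' and '{t.trait}'"
            )
        common = nxt
    reference = {
        r.SNP: (r.A1, r.A2)
        for r in first.data.itertuples()
        if r.SNP in common and (r.A1, r.A2) not in AMBIGUOUS_PAIRS
    }
    harmonized = [harmonize_alleles(t, reference) for t in tables]
    # ambiguous/incompatible drops shrink the intersection further
    for t in harmonized:
        common &= set(t.data["SNP"])
    base = harmonized[0].data
    base = base.loc[base["SNP"].isin(common)].sort_values(["CHR", "BP", "SNP"], kind="mergesort")
    snp_order = base["SNP"].to_numpy()
    Z = np.empty((len(snp_order), len(tables)))
    N = np.empty_like(Z)
    for j, t in enumerate(harmonized):
        sub = t.data.set_index("SNP").loc[snp_order]
        Z[:, j] = sub["Z"].to_numpy(float)
        N[:, j] = sub["N"].to_numpy(float)
    snps = base[[c for c in ("SNP", "CHR", "BP", "A1", "A2") if c in base.columns]].reset_index(drop=True)
    return AlignedPanel(snps, [t.trait for t in tables], Z, N)
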