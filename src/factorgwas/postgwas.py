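"""Independent significant SNPs, lead SNPs, genomic risk loci, novelty filter.

Clumping re-implements the standard definitions used by GWAS annotation
platforms: genome-wide significant SNPs are scanned by ascending p-value
(ties broken by position, then rsID); a SNP is *independent significant*
if its LD r^2 with every previously selected one is below ``r2_indep``
(default 0.6), and *lead* SNPs are the subset of independent significant
SNPs mutually below ``r2_lead`` (default 0.1).  Risk loci span each
lead's assigned SNPs and are merged when closer than ``merge_window``
base pairs (default 250 kb) on the same chromosome.

The novelty filter removes, in order: (1) significant SNPs whose rsID
matches a previously reported significant SNP; (2) significant SNPs in
LD (r^2 strictly greater than ``r2_novel``, default 0.6) with any
previously reported significant SNP; (3) risk loci overlapping a
previously reported locus by at least one base pair (closed intervals,
same chromosome).  An audit trail names the removing rule per item.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .sumstats import SumStatsTable

__all__ = ["LDTable", "RiskLocus", "ClumpResult", "clump", "define_loci",
           "novelty_filter", "NoveltyResult"]


class LDTable:
    """Symmetric SNP-pair r^2 lookup; self-pairs are 1, absent pairs 0."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, float(r2))

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
        self._r2[(a, b) if a <= b else (b, a)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get((a, b) if a <= b else (b, a), 0.0)

    def partners(self, a: str, threshold: float) -> set[str]:
        out = set()
        for (x, y), r2 in self._r2.items():
            if r2 >= threshold:
                if x == a:
                    out.add(y)
                elif y == a:
                    out.add(x)
        return out

    @classmethod
    def from_file(cls, path) -> "LDTable":
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.lower(): c for c in df.columns}
        need = [cols.get(k) for k in ("snp_a", "snp_b", "r2")]
        if any(c is None for c in need):
            raise ValueError(f"{path}: LD table needs columns SNP_A SNP_B R2")
        return cls((r[need[0]], r[need[1]], r[need[2]]) for _, r in df.iterrows())

    def to_file(self, path) -> None:
        rows = [(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class RiskLocus:
    chrom: str
    start: int  # 1-based closed interval
    end: int
    lead: str
    members: list[str] = field(default_factory=list)

    def overlaps(self, other: "RiskLocus") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


@dataclass
class ClumpResult:
    independent: list[str]            # independent significant SNPs, by ascending p
    leads: list[str]                  # lead SNPs (subset of independent)
    pruned_by: dict[str, str]         # sig SNP -> independent SNP that absorbed it
    lead_of: dict[str, str]           # independent SNP -> its lead
    significant: list[str]            # all input significant SNPs


def _sig_order(table: SumStatsTable, p_sig: float) -> pd.DataFrame:
    df = table.data
    sig = df.loc[df["P"].to_numpy(float) < p_sig].copy()
    return sig.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort")


def clump(table: SumStatsTable, ld: LDTable, p_sig: float = 5e-8,
          r2_indep: float = 0.6, r2_lead: float = 0.1) -> ClumpResult:
    """Greedy selection of independent significant and lead SNPs.

    Deterministic given the documented tie-break (ascending p, then
    position, then rsID); invariant to input row order.  Every
    significant SNP is either selected or assigned to the
    smallest-p independent SNP it is in LD with (``pruned_by``).
    """
    for thr in (p_sig, r2_indep, r2_lead):
        if not 0.0 < thr < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
    sig = _sig_order(table, p_sig)
    independent: list[str] = []
    pruned_by: dict[str, str] = {}
    for snp in sig["SNP"]:
        blocker = next((s for s in independent if ld.r2(snp, s) >= r2_indep), None)
        if blocker is None:
            independent.append(snp)
        else:
            pruned_by[snp] = blocker
    leads: list[str] = []
    lead_of: dict[str, str] = {}
    for snp in independent:
        blocker = next((s for s in leads if ld.r2(snp, s) >= r2_lead), None)
        if blocker is None:
            leads.append(snp)
            lead_of[snp] = snp
        else:
            lead_of[snp] = blocker
    return ClumpResult(independent, leads, pruned_by, lead_of, list(sig["SNP"]))


def define_loci(table: SumStatsTable, clumps: ClumpResult,
                merge_window: int = 250_000) -> list[RiskLocus]:
    """Merge each lead's assigned SNPs into genomic risk loci.

    A lead's members are itself, its assigned independent SNPs, and
    every significant SNP pruned by those; the candidate interval spans
    the member positions and candidates on the same chromosome closer
    than ``merge_window`` bp are merged.  Locus bounds equal the min and
    max member positions exactly.
    """
    if not clumps.significant:
        return []
    pos = table.data.set_index("SNP")
    members_of: dict[str, list[str]] = {l: [] for l in clumps.leads}
    for snp in clumps.significant:
        indep = clumps.pruned_by.get(snp, snp)
        members_of[clumps.lead_of[indep]].append(snp)
    candidates = []
    for lead, members in members_of.items():
        bps = pos.loc[members, "BP"].astype(int)
        chroms = pos.loc[members, "CHR"].astype(str)
        chrom = str(pos.loc[lead, "CHR"])
        same = [m for m, c in zip(members, chroms) if c == chrom]
        bp_same = pos.loc[same, "BP"].astype(int)
        candidates.append(RiskLocus(chrom, int(bp_same.min()), int(bp_same.max()),
                                    lead, sorted(same, key=lambda s: int(pos.loc[s, "BP"]))))
        del bps
    candidates.sort(key=lambda l: (l.chrom, l.start, l.end))
    merged: list[RiskLocus] = []
    for loc in candidates:
        if merged and merged[-1].chrom == loc.chrom \
                and loc.start - merged[-1].end <= merge_window:
            prev = merged[-1]
            best_lead = min(
                (prev.lead, loc.lead),
                key=lambda s: float(pos.loc[s, "P"]),
            )
            merged[-1] = RiskLocus(prev.chrom, prev.start, max(prev.end, loc.end),
                                   best_lead, sorted(set(prev.members + loc.members),
                                                     key=lambda s: int(pos.loc[s, "BP"])))
        else:
            merged.append(loc)
    return merged


@dataclass
class NoveltyResult:
    novel_snps: list[str]
    novel_loci: list[RiskLocus]
    audit: list[tuple[str, str]]  # (item, removing rule)


def novelty_filter(sig_snps: Iterable[str], loci: Iterable[RiskLocus],
                   prior_snps: Iterable[str], prior_loci: Iterable[RiskLocus],
                   ld: LDTable, r2_novel: float = 0.6) -> NoveltyResult:
    """Remove previously reported associations from current results.

    Stage 1 drops exact rsID matches with ``prior_snps``; stage 2 drops
    SNPs with r^2 strictly greater than ``r2_novel`` to any prior
    significant SNP (boundary r^2 == r2_novel survives); stage 3 drops
    loci with >= 1 bp closed-interval overlap with any prior locus.
    With empty priors the filter is the identity.
    """
    prior_set = set(prior_snps)
    prior_loci = list(prior_loci)
    audit: list[tuple[str, str]] = []
    novel: list[str] = []
    for snp in sig_snps:
        if snp in prior_set:
            audit.append((snp, "rsID match with prior significant SNP"))
            continue
        partner = next((p for p in prior_set if ld.r2(snp, p) > r2_novel), None)
        if partner is not None:
            audit.append((snp, f"LD r2 > {r2_novel} with prior SNP {partner}"))
            continue
        novel.append(snp)
    novel_loci: list[RiskLocus] = []
    for loc in loci:
        hit = next((p for p in prior_loci if loc.overlaps(p)), None)
        if hit is not None:
            audit.append((f"{loc.chrom}:{loc.start}-{loc.end}",
                          f"overlaps prior locus {hit.chrom}:{hit.start}-{hit.end}"))
        else:
            novel_loci.append(loc)
    return NoveltyResult(novel, novel_loci, audit)


def read_prior_snps(path) -> list[str]:
    """Plain rsID list, one per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_prior_loci(path) -> list[RiskLocus]:
    """Three-column text (chrom, start, end), 1-based closed intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split()[:3]
            out.append(RiskLocus(chrom, int(start), int(end), lead=""))
    return out
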