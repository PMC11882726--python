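"""Clumping, locus definition and novelty filtering against toy LD tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from factorgwas.postgwas import (
    LDTable,
    RiskLocus,
    clump,
    define_loci,
    novelty_filter,
    read_prior_loci,
    read_prior_snps,
)
from factorgwas.sumstats import SumStatsTable


def make_table(rows):
    df = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "P"])
    return SumStatsTable("gwas", df)


def brute_force_clump(table, ld, p_sig, r2_indep, r2_lead):
    """Independent oracle: explicit pairwise r2 matrix + sequential scan."""
    df = table.data
    sig = df.loc[df["P"] < p_sig].copy()
    sig = sig.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort")
    snps = list(sig["SNP"])
    r2 = {(a, b): ld.r2(a, b) for a, b in itertools.product(snps, snps)}
    independent = []
    for s in snps:
        if all(r2[(s, t)] < r2_indep for t in independent):
            independent.append(s)
    leads = []
    for s in independent:
        if all(r2[(s, t)] < r2_lead for t in leads):
            leads.append(s)
    return independent, leads


class TestClump:
    def test_correlated_pair_keeps_smaller_p(self):
        table = make_table([
            ["rs1", "1", 100, "A", "G", 6.0, 1e4, 1e-9],
            ["rs2", "1", 200, "A", "G", 5.8, 1e4, 1e-8 * 0.5],
        ])
        ld = LDTable([("rs1", "rs2", 0.7)])
        res = clump(table, ld, r2_indep=0.6)
        assert res.independent == ["rs1"]
        assert res.pruned_by == {"rs2": "rs1"}

    def test_isolated_snp_is_independent_and_lead(self):
        table = make_table([["rs1", "1", 100, "A", "G", 6.0, 1e4, 1e-9]])
        res = clump(table, LDTable())
        assert res.independent == ["rs1"]
        assert res.leads == ["rs1"]

    def test_matches_brute_force_on_seeded_toy(self):
        rng = np.random.default_rng(99)
        n = 20
        rows = []
        for i in range(n):
            p = 10.0 ** rng.uniform(-12, -5)
            rows.append([f"rs{i}", "1", 1000 * (i + 1), "A", "G", 6.0, 1e4, p])
        table = make_table(rows)
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    ld.add(f"rs{i}", f"rs{j}", float(rng.random()))
        res = clump(table, ld)
        ind, leads = brute_force_clump(table, ld, 5e-8, 0.6, 0.1)
        assert res.independent == ind
        assert res.leads == leads

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        rows = [[f"rs{i}", "1", 100 * (i + 1), "A", "G", 6.0, 1e4,
                 10.0 ** rng.uniform(-10, -8)] for i in range(8)]
        ld = LDTable([(f"rs{i}", f"rs{i+1}", 0.8) for i in range(7)])
        a = clump(make_table(rows), ld)
        b = clump(make_table(list(reversed(rows))), ld)
        assert a.independent == b.independent
        assert a.leads == b.leads

    def test_accounting_completeness(self):
        rng = np.random.default_rng(5)
        rows = [[f"rs{i}", "1", 100 * (i + 1), "A", "G", 6.0, 1e4,
                 10.0 ** rng.uniform(-10, -8)] for i in range(12)]
        ld = LDTable()
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.4:
                    ld.add(f"rs{i}", f"rs{j}", float(rng.random()))
        res = clump(make_table(rows), ld)
        assigned = set(res.independent) | set(res.pruned_by)
        assert assigned == set(res.significant)
        assert not (set(res.independent) & set(res.pruned_by))

    def test_bad_threshold_rejected(self):
        table = make_table([["rs1", "1", 100, "A", "G", 6.0, 1e4, 1e-9]])
        with pytest.raises(ValueError):
            clump(table, LDTable(), p_sig=0.0)


class TestDefineLoci:
    def test_nearby_leads_merged(self):
        table = make_table([
            ["rs1", "1", 100_000, "A", "G", 6.0, 1e4, 1e-10],
            ["rs2", "1", 200_000, "A", "G", 5.8, 1e4, 1e-9],
        ])
        res = clump(table, LDTable())  # both independent leads
        loci = define_loci(table, res, merge_window=250_000)
        assert len(loci) == 1
        assert loci[0].start == 100_000 and loci[0].end == 200_000
        assert loci[0].lead == "rs1"

    def test_empty_input(self):
        table = make_table([["rs1", "1", 100, "A", "G", 1.0, 1e4, 0.5]])
        res = clump(table, LDTable())
        assert define_loci(table, res) == []

    def test_bounds_are_member_extremes(self):
        table = make_table([
            ["rs1", "2", 500_000, "A", "G", 7.0, 1e4, 1e-12],
            ["rs2", "2", 400_000, "A", "G", 6.0, 1e4, 1e-9],
            ["rs3", "2", 650_000, "A", "G", 5.7, 1e4, 1e-8 * 0.3],
        ])
        ld = LDTable([("rs1", "rs2", 0.9), ("rs1", "rs3", 0.8)])
        res = clump(table, ld)
        loci = define_loci(table, res)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (400_000, 650_000)
        assert loci[0].members == ["rs2", "rs1", "rs3"]

    def test_distinct_chromosomes_never_merge(self):
        table = make_table([
            ["rs1", "1", 100, "A", "G", 6.0, 1e4, 1e-10],
            ["rs2", "2", 150, "A", "G", 6.0, 1e4, 1e-10],
        ])
        res = clump(table, LDTable())
        assert len(define_loci(table, res)) == 2


class TestNoveltyFilter:
    def test_forced_toy_outcome(self):
        ld = LDTable([("rs1", "rs2", 0.7)])
        out = novelty_filter(["rs1", "rs2", "rs3"], [], ["rs2"], [], ld)
        assert out.novel_snps == ["rs3"]
        rules = dict(out.audit)
        assert "rsID match" in rules["rs2"]
        assert "LD r2" in rules["rs1"]

    def test_boundary_r2_survives(self):
        ld = LDTable([("rs1", "rs2", 0.6)])
        out = novelty_filter(["rs1"], [], ["rs2"], [], ld, r2_novel=0.6)
        assert out.novel_snps == ["rs1"]

    def test_overlapping_locus_removed(self):
        cur = [RiskLocus("1", 100, 200, "rs1")]
        prior = [RiskLocus("1", 150, 250, "x")]
        out = novelty_filter([], cur, [], prior, LDTable())
        assert out.novel_loci == []
        assert "overlaps prior locus" in out.audit[0][1]

    def test_adjacent_but_disjoint_locus_kept(self):
        cur = [RiskLocus("1", 100, 200, "rs1")]
        prior = [RiskLocus("1", 201, 300, "x"), RiskLocus("2", 100, 200, "y")]
        out = novelty_filter([], cur, [], prior, LDTable())
        assert len(out.novel_loci) == 1

    def test_empty_priors_is_identity(self):
        cur_loci = [RiskLocus("1", 1, 2, "rs1")]
        out = novelty_filter(["rs1", "rs2"], cur_loci, [], [], LDTable())
        assert out.novel_snps == ["rs1", "rs2"]
        assert out.novel_loci == cur_loci
        assert out.audit == []

    def test_stagewise_subset_property(self):
        rng = np.random.default_rng(11)
        snps = [f"rs{i}" for i in range(15)]
        ld = LDTable()
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.2:
                    ld.add(snps[i], snps[j], float(rng.random()))
        prior = list(rng.choice(snps, 4, replace=False))
        out = novelty_filter(snps, [], prior, [], ld)
        assert set(out.novel_snps) <= set(snps)
        assert len(out.novel_snps) + len(out.audit) == len(snps)


class TestLDTable:
    def test_symmetry_self_and_missing(self):
        ld = LDTable([("a", "b", 0.5)])
        assert ld.r2("a", "b") == ld.r2("b", "a") == 0.5
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "zz") == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LDTable([("a", "b", 1.5)])

    def test_file_round_trip(self, tmp_path):
        ld = LDTable([("a", "b", 0.5), ("b", "c", 0.25)])
        path = tmp_path / "ld.txt"
        ld.to_file(path)
        back = LDTable.from_file(path)
        assert back.r2("a", "b") == 0.5
        assert back.r2("c", "b") == 0.25


def test_prior_file_readers(tmp_path):
    snp_file = tmp_path / "prior.txt"
    snp_file.write_text("rs1\nrs2\n\n")
    assert read_prior_snps(snp_file) == ["rs1", "rs2"]
    loci_file = tmp_path / "loci.bed"
    loci_file.write_text("# header\n1 100 200\n2 5 6\n")
    loci = read_prior_loci(loci_file)
    assert loci[0].chrom == "1" and loci[0].start == 100 and loci[0].end == 200
    assert len(loci) == 2
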