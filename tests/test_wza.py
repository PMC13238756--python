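"""Gene-level weighted-Z aggregation and consensus machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cudelim.containers import GeneAnnotation, RegionSet, ScanStats
from cudelim.wza_consensus import (assign_snps_to_genes, overlap_consensus,
                                   qtl_proximity, region_enrichment,
                                   term_enrichment, top_candidates, wza)


def _genes(rows):
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom",
                                                      "start", "end"]))


def _meta(positions, chrom="chr1"):
    idx = pd.Index([f"s{i}" for i in range(len(positions))], name="snp_id")
    return pd.DataFrame({"chrom": chrom, "pos": positions}, index=idx)


class TestAssign:
    def test_one_based_boundary_conversion(self):
        genes = _genes([("g1", "chr1", 100, 200)])
        meta = _meta([101, 100, 200, 201])
        mapping, _ = assign_snps_to_genes(meta, genes, min_snps=1)
        got = set(mapping["snp_id"])
        # 1-based 101 -> 0-based 100: inside; 1-based 100 -> 99: outside;
        # 1-based 200 -> 199: inside; 1-based 201 -> 200: outside
        assert got == {"s0", "s2"}

    def test_min_snps_excludes_small_genes(self):
        genes = _genes([("big", "chr1", 0, 100), ("small", "chr1", 200, 300)])
        meta = _meta([1, 2, 3, 4, 5, 201, 202, 203, 204])
        mapping, background = assign_snps_to_genes(meta, genes, min_snps=5)
        assert background == {"big"}
        assert set(mapping["gene_id"]) == {"big"}

    def test_overlapping_genes_share_snps(self):
        genes = _genes([("a", "chr1", 0, 50), ("b", "chr1", 25, 80)])
        meta = _meta([30, 31, 32, 33, 34])
        mapping, background = assign_snps_to_genes(meta, genes, min_snps=5)
        assert background == {"a", "b"}
        assert len(mapping) == 10

    def test_chrom_mismatch_errors(self):
        genes = _genes([("g1", "chrX", 0, 10)])
        with pytest.raises(ValueError, match="chromosome"):
            assign_snps_to_genes(_meta([5]), genes, min_snps=1)


class TestWza:
    def test_five_snp_closed_form(self):
        """Equal weights, empirical p = (0.1..0.5):
        Z = sum(Phi^-1(1-p)) / sqrt(5)."""
        genes = _genes([("g1", "chr1", 0, 100)])
        meta = _meta([1, 2, 3, 4, 5])
        mapping, _ = assign_snps_to_genes(meta, genes, min_snps=5)
        p = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5],
                      index=meta.index, name="p")
        scan = ScanStats("toy", "", p, "is_p_value")
        w = pd.Series(1.0, index=meta.index)
        out = wza(scan, mapping, w)
        expect = sum(stats.norm.ppf(1 - x) for x in [0.1, 0.2, 0.3, 0.4, 0.5]) / np.sqrt(5)
        assert out.loc["g1", "Z"] == pytest.approx(expect, abs=1e-12)
        assert out.loc["g1", "p"] == pytest.approx(stats.norm.sf(expect), abs=1e-12)

    def test_rank_only_monotone_invariance(self):
        """Any strictly monotone transform of a higher_more_extreme statistic
        leaves the WZA table unchanged."""
        rng = np.random.default_rng(0)
        genes = _genes([("g1", "chr1", 0, 500), ("g2", "chr1", 600, 1100)])
        meta = _meta(list(range(1, 11)) + list(range(601, 611)))
        mapping, _ = assign_snps_to_genes(meta, genes, min_snps=5)
        vals = pd.Series(rng.random(20) + 0.1, index=meta.index)
        w = pd.Series(rng.uniform(0.1, 0.25, 20), index=meta.index)
        t1 = wza(ScanStats("m", "", vals, "higher_more_extreme"), mapping, w)
        t2 = wza(ScanStats("m", "", np.exp(3 * vals), "higher_more_extreme"),
                 mapping, w)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_gene_z_standard_normal(self):
        """Independent uniform SNP p-values: gene Z has mean ~0, var ~1."""
        rng = np.random.default_rng(1)
        n_genes, snps_per = 500, 8
        rows = [(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(n_genes)]
        genes = _genes(rows)
        positions = [i * 1000 + 10 * (j + 1) for i in range(n_genes)
                     for j in range(snps_per)]
        meta = _meta(positions)
        mapping, _ = assign_snps_to_genes(meta, genes, min_snps=5)
        stat = pd.Series(rng.random(len(meta)), index=meta.index)
        w = pd.Series(rng.uniform(0.15, 0.25, len(meta)), index=meta.index)
        out = wza(ScanStats("m", "", stat, "higher_more_extreme"), mapping, w)
        assert abs(out["Z"].mean()) < 0.1
        assert abs(out["Z"].var() - 1.0) < 0.2

    def test_tie_saturation_flagged(self):
        genes = _genes([("g1", "chr1", 0, 100), ("g2", "chr1", 100, 200)])
        meta = _meta([1, 2, 3, 4, 5, 101, 102, 103, 104, 105])
        mapping, _ = assign_snps_to_genes(meta, genes, min_snps=5)
        vals = pd.Series(1.0, index=meta.index)
        w = pd.Series(1.0, index=meta.index)
        out = wza(ScanStats("m", "", vals, "higher_more_extreme"), mapping, w)
        assert out["Z"].nunique() == 1


class TestTopCandidatesAndOverlap:
    def test_strict_threshold(self):
        t = pd.DataFrame({"p": [0.001, 0.0009999, 0.5]},
                         index=["a", "b", "c"])
        t.index.name = "gene_id"
        out = top_candidates({"m": t}, p_max=0.001)
        assert out["m"] == {"b"}

    def test_overlap_set_arithmetic(self):
        """Sets of sizes 151 and 188 sharing 81: union 258, 31.4%."""
        a = {f"g{i}" for i in range(151)}
        b = {f"g{i}" for i in range(70, 258)}
        assert len(a & b) == 81 and len(b) == 188
        pairwise, consensus, union = overlap_consensus({"A": a, "B": b})
        row = pairwise.iloc[0]
        assert row["union"] == 258
        assert row["overlap_pct"] == pytest.approx(100 * 81 / 258, abs=0.05)
        assert consensus == a & b

    def test_identical_and_disjoint(self):
        s = {"x", "y"}
        pw, cons, _ = overlap_consensus({"a": s, "b": set(s)})
        assert pw.iloc[0]["overlap_pct"] == 100.0
        pw2, cons2, _ = overlap_consensus({"a": {"x"}, "b": {"y"}})
        assert pw2.iloc[0]["overlap_pct"] == 0.0 and cons2 == set()


class TestRegionEnrichment:
    @staticmethod
    def _setup(n_genes=1000, frac_in=0.5):
        rows = [(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(n_genes)]
        genes = _genes(rows)
        k = int(n_genes * frac_in)
        regions = RegionSet(pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [k * 1000],
             "region_class": "ancestry_tract", "name": "t1"}))
        return genes, regions

    def test_textbook_chi2_formula(self):
        """Contingency (10,90 / 10,890) matches the Pearson formula."""
        genes, _ = self._setup(1000)
        background = set(genes.table["gene_id"])
        in_region = {f"g{i}" for i in range(20)}  # first 20 genes in-region
        cand = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(100, 190)}
        # candidate: 10 in / 90 out; rest: 10 in / 890 out
        regions = RegionSet(pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [20 * 1000 - 500],
             "region_class": "ancestry_tract", "name": "t"}))
        out = region_enrichment({"m": cand}, background, genes, regions)
        obs = np.array([[10, 90], [10, 890]], dtype=float)
        tot = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / tot
        chi2_hand = ((obs - exp) ** 2 / exp).sum()
        assert out.iloc[0]["chi2"] == pytest.approx(chi2_hand, abs=1e-9)
        assert out.iloc[0]["fold"] == pytest.approx((10 / 100) / (20 / 1000))

    def test_all_candidates_in_region_fold(self):
        genes, regions = self._setup(1000, frac_in=0.5)
        background = set(genes.table["gene_id"])
        cand = {f"g{i}" for i in range(30)}  # all within the in-region half
        out = region_enrichment({"m": cand}, background, genes, regions)
        assert out.iloc[0]["fold"] == pytest.approx(2.0, rel=0.05)
        assert out.iloc[0]["p"] < 1e-6

    def test_null_calibration(self):
        """Candidates drawn uniformly from the background reject at ~alpha."""
        genes, regions = self._setup(400, frac_in=0.5)
        background = set(genes.table["gene_id"])
        bg = sorted(background)
        rng = np.random.default_rng(2)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            cand = set(rng.choice(bg, size=40, replace=False))
            out = region_enrichment({"m": cand}, background, genes, regions)
            if out.iloc[0]["p"] < 0.05:
                rej += 1
        assert 0.02 <= rej / n_rep <= 0.08

    def test_zero_margin_reported_na(self):
        genes, _ = self._setup(100)
        background = set(genes.table["gene_id"])
        regions = RegionSet(pd.DataFrame(
            {"chrom": "chr9", "start": [0], "end": [10],
             "region_class": "qtl", "name": "q"}))
        out = region_enrichment({"m": {"g1", "g2"}}, background, genes, regions)
        assert np.isnan(out.iloc[0]["chi2"])


class TestQtlProximity:
    def test_slop_boundary_half_open(self):
        genes = _genes([("g1", "chr1", 1000, 2000)])
        qtl_in = RegionSet(pd.DataFrame(
            {"chrom": "chr1", "start": [101_999], "end": [102_000],
             "region_class": "qtl", "name": "q1"}))
        qtl_out = RegionSet(pd.DataFrame(
            {"chrom": "chr1", "start": [102_000], "end": [102_001],
             "region_class": "qtl", "name": "q2"}))
        assert len(qtl_proximity({"g1"}, genes, qtl_in, slop=100_000)) == 1
        assert len(qtl_proximity({"g1"}, genes, qtl_out, slop=100_000)) == 0

    def test_zero_slop_plain_overlap(self):
        genes = _genes([("g1", "chr1", 1000, 2000)])
        qtl = RegionSet(pd.DataFrame(
            {"chrom": "chr1", "start": [1999, 2000], "end": [2000, 2001],
             "region_class": ["qtl", "qtl"], "name": ["in", "out"]}))
        out = qtl_proximity({"g1"}, genes, qtl, slop=0)
        assert list(out["qtl"]) == ["in"]


class TestTermEnrichment:
    def test_extreme_terms(self):
        background = {f"g{i}" for i in range(20)}
        cand = {f"g{i}" for i in range(5)}
        g2t = pd.DataFrame({"gene_id": sorted(background) + sorted(cand),
                            "term": ["all"] * 20 + ["exact"] * 5})
        out = term_enrichment(cand, background, g2t).set_index("term")
        assert out.loc["all", "p"] == pytest.approx(1.0)
        assert out.loc["exact", "p"] == out["p"].min()

    def test_hypergeometric_matches_enumeration(self):
        """Toy: bg 20, cand 5, term hits 4/5 candidates and 4/15 others;
        p equals the exhaustive tail."""
        background = {f"g{i}" for i in range(20)}
        cand = {f"g{i}" for i in range(5)}
        term_genes = {f"g{i}" for i in range(1, 5)} | {f"g{i}" for i in range(5, 9)}
        g2t = pd.DataFrame({"gene_id": sorted(term_genes), "term": "t"})
        out = term_enrichment(cand, background, g2t)
        # enumeration oracle: over all C(20,5) candidate draws, fraction with
        # >= 4 term genes
        from math import comb
        m = 8  # term size
        total = comb(20, 5)
        tail = sum(comb(m, k) * comb(20 - m, 5 - k) for k in (4, 5)) / total
        assert out.iloc[0]["p"] == pytest.approx(tail, abs=1e-12)

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            term_enrichment({"a"}, {"a", "b"},
                            pd.DataFrame({"gene_id": [], "term": []}))


class TestBh:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    def test_bh_matches_bruteforce_stepup(self, pvals):
        """statsmodels BH (as used throughout) equals the textbook step-up."""
        from statsmodels.stats.multitest import multipletests
        p = np.array(pvals)
        adj = multipletests(p, method="fdr_bh")[1]
        n = len(p)
        order = np.argsort(p)
        brute = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            brute[i] = running
        assert np.allclose(adj, brute, atol=1e-12)
        assert (adj >= p - 1e-12).all()
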