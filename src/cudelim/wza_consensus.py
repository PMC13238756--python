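"""Gene-level aggregation of per-SNP scan statistics (weighted-Z analysis)
and the multi-method consensus machinery: top-candidate lists, pairwise
overlaps, region enrichment, QTL proximity, and generic term enrichment with
Benjamini-Hochberg correction.

The weighted-Z statistic for a gene with SNPs i is

    Z = sum(w_i z_i) / sqrt(sum(w_i^2)),    z_i = Phi^-1(1 - p_i)

with empirical per-SNP p-values from descending ranks of the statistic
(p-value inputs are used directly) and weights w_i = pbar_i (1 - pbar_i)
from the global minor-allele frequency. The sqrt(sum w^2) denominator is the
correction for the number of SNPs in the gene: under independent null SNPs,
Z is standard normal whatever the gene's SNP count.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneAnnotation, RegionSet, ScanStats, SnpTable

logger = logging.getLogger(__name__)

__all__ = ["assign_snps_to_genes", "wza", "top_candidates", "overlap_consensus",
           "region_enrichment", "qtl_proximity", "term_enrichment"]


def assign_snps_to_genes(snp_meta: pd.DataFrame, genes: GeneAnnotation,
                         min_snps: int = 5) -> tuple[pd.DataFrame, set[str]]:
    """Assign SNPs (1-based positions) to gene intervals (0-based half-open).

    A SNP at 1-based position P belongs to gene [start, end) iff
    start <= P - 1 < end; a SNP may belong to several overlapping genes.
    Genes with fewer than ``min_snps`` assigned SNPs are dropped from both
    the mapping and the background set.

    Returns ``(mapping, background)`` where mapping has columns
    snp_id / gene_id and background is the retained gene-id set.
    """
    gchroms = set(genes.table["chrom"])
    schroms = set(snp_meta["chrom"])
    if not gchroms & schroms:
        raise ValueError(
            f"no shared chromosome names between SNPs ({sorted(schroms)[:5]}...) "
            f"and genes ({sorted(gchroms)[:5]}...)"
        )
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.table.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, g) for s, e, g in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    rows = []
    for snp_id, chrom, pos in zip(snp_meta.index, snp_meta["chrom"], snp_meta["pos"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[pos - 1]:
            rows.append((snp_id, iv.data))
    mapping = pd.DataFrame(rows, columns=["snp_id", "gene_id"])
    counts = mapping["gene_id"].value_counts()
    background = set(counts[counts >= min_snps].index)
    dropped = len(counts) - len(background)
    if dropped:
        logger.info("assign_snps_to_genes: %d genes below min_snps=%d dropped",
                    dropped, min_snps)
    mapping = mapping[mapping["gene_id"].isin(background)].reset_index(drop=True)
    return mapping, background


def wza(scan: ScanStats, mapping: pd.DataFrame, weights: pd.Series,
        mode: str = "normal_tail") -> pd.DataFrame:
    """Weighted-Z aggregation of one scan's per-SNP statistics to genes.

    ``weights`` is the per-SNP pbar(1-pbar) heterozygosity (global MAF).
    ``mode`` selects the gene p-value: ``normal_tail`` (upper tail of the
    standard normal) or ``empirical`` (descending rank of Z across genes).
    """
    if mode not in ("normal_tail", "empirical"):
        raise ValueError("mode must be normal_tail or empirical")
    vals = scan.values.dropna()
    if scan.orientation == "is_p_value":
        p_snp = vals.clip(lower=np.finfo(float).tiny, upper=1.0)
    else:
        # descending ranks -> empirical p in (0, 1); ties get the average rank
        ranks = stats.rankdata(-vals.to_numpy(), method="average")
        p_snp = pd.Series(ranks / (len(vals) + 1.0), index=vals.index)
    z = pd.Series(stats.norm.isf(p_snp.to_numpy()), index=p_snp.index)
    m = mapping[mapping["snp_id"].isin(z.index)]
    rows = []
    for gene, sub in m.groupby("gene_id"):
        ids = sub["snp_id"]
        w = weights.reindex(ids).to_numpy(dtype=float)
        denom = np.sqrt((w**2).sum())
        if denom == 0:
            logger.warning("wza: gene %s has zero weight sum, skipped", gene)
            continue
        zg = float((w * z.reindex(ids).to_numpy()).sum() / denom)
        rows.append((gene, len(ids), zg))
    out = pd.DataFrame(rows, columns=["gene_id", "n_snps", "Z"])
    if mode == "normal_tail":
        out["p"] = stats.norm.sf(out["Z"])
    else:
        ranks = stats.rankdata(-out["Z"].to_numpy(), method="average")
        out["p"] = ranks / (len(out) + 1.0)
        if out["Z"].nunique() == 1:
            logger.warning("wza: all gene Z equal; empirical p degenerate")
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny, upper=1.0)
    out["method"] = scan.name
    return out.set_index("gene_id")


def top_candidates(wza_tables: dict[str, pd.DataFrame],
                   p_max: float = 0.001) -> dict[str, set[str]]:
    """Per method, the genes with WZA p strictly below ``p_max``."""
    return {name: set(t.index[t["p"] < p_max]) for name, t in wza_tables.items()}


def overlap_consensus(sets: dict[str, set[str]]):
    """Pairwise overlaps and the multi-method consensus list.

    Returns ``(pairwise, consensus, union)``: a table with overlap counts and
    the percentage relative to the pairwise union; the set of genes found by
    at least two methods; and the union of all sets.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    rows = []
    for a, b in itertools.combinations(sets, 2):
        inter = sets[a] & sets[b]
        union = sets[a] | sets[b]
        pct = 100.0 * len(inter) / len(union) if union else 0.0
        rows.append((a, b, len(sets[a]), len(sets[b]), len(inter), len(union), pct))
    pairwise = pd.DataFrame(rows, columns=["method_a", "method_b", "n_a", "n_b",
                                           "overlap", "union", "overlap_pct"])
    counts: dict[str, int] = {}
    for s in sets.values():
        for gene in s:
            counts[gene] = counts.get(gene, 0) + 1
    consensus = {g for g, c in counts.items() if c >= 2}
    union_all = set().union(*sets.values())
    return pairwise, consensus, union_all


def _genes_in_regions(genes: GeneAnnotation, regions: pd.DataFrame) -> set[str]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e) for s, e in zip(sub["start"], sub["end"])
        )
    hit = set()
    for gene_id, chrom, s, e in zip(genes.table["gene_id"], genes.table["chrom"],
                                    genes.table["start"], genes.table["end"]):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(s, e):
            hit.add(gene_id)
    return hit


def region_enrichment(candidate_sets: dict[str, set[str]], background: set[str],
                      genes: GeneAnnotation, regions: RegionSet,
                      classes: list[str] | None = None,
                      yates: bool = False) -> pd.DataFrame:
    """Chi-square enrichment of candidate genes inside classified regions.

    For each (method, region class): 2x2 Pearson chi-square (df=1, no
    continuity correction by default) on candidate/non-candidate x in/out of
    region, with fold = (candidates in / candidates) / (background in /
    background). Tests with a zero margin are reported as NA. BH correction
    is applied across the whole (method, class) family.
    """
    classes = classes or sorted(set(regions.table["region_class"]))
    rows = []
    for cls in classes:
        in_region = _genes_in_regions(genes, regions.of_class(cls)) & background
        for method, cand in candidate_sets.items():
            if not cand <= background:
                raise ValueError(f"candidates of {method!r} not within background")
            a = len(cand & in_region)
            b = len(cand) - a
            c = len((background - cand) & in_region)
            d = len(background - cand) - c
            table = np.array([[a, b], [c, d]], dtype=float)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                rows.append((method, cls, a, len(cand), c, len(background) - len(cand),
                             np.nan, np.nan, np.nan))
                continue
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)[:4]
            fold = (a / len(cand)) / (len(in_region) / len(background)) \
                if len(cand) and len(in_region) else np.nan
            rows.append((method, cls, a, len(cand), c,
                         len(background) - len(cand), chi2, p, fold))
    out = pd.DataFrame(rows, columns=["method", "region_class", "cand_in", "cand_n",
                                      "bg_in", "bg_n", "chi2", "p", "fold"])
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def qtl_proximity(candidates: set[str], genes: GeneAnnotation, qtl: RegionSet,
                  slop: int = 100_000) -> pd.DataFrame:
    """(gene, QTL) pairs where the QTL interval intersects the candidate
    gene's interval expanded by ``slop`` on both sides (half-open
    arithmetic)."""
    qt = qtl.table
    rows = []
    gt = genes.table[genes.table["gene_id"].isin(candidates)]
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in qt.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, name) for s, e, name in zip(sub["start"], sub["end"], sub["name"])
        )
    for gene_id, chrom, s, e in zip(gt["gene_id"], gt["chrom"], gt["start"], gt["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.overlap(max(0, s - slop), e + slop):
            rows.append((gene_id, iv.data, chrom, iv.begin, iv.end))
    return pd.DataFrame(rows, columns=["gene_id", "qtl", "chrom", "qtl_start", "qtl_end"])


def term_enrichment(candidates: set[str], background: set[str],
                    gene2term: pd.DataFrame) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in the candidate set.

    ``gene2term`` has columns gene_id / term. p is the upper tail of drawing
    at least the observed number of term genes among the candidates; BH
    correction across terms.
    """
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    g2t = gene2term[gene2term["gene_id"].isin(background)]
    if g2t.empty or not (set(g2t["gene_id"]) & candidates):
        raise ValueError("term map covers no candidate gene")
    n_bg, n_cand = len(background), len(candidates)
    rows = []
    for term, sub in g2t.groupby("term"):
        term_genes = set(sub["gene_id"])
        k = len(term_genes & candidates)
        m = len(term_genes)
        p = stats.hypergeom.sf(k - 1, n_bg, m, n_cand)
        rows.append((term, k, m, p))
    out = pd.DataFrame(rows, columns=["term", "n_candidates", "n_background", "p"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p").reset_index(drop=True)
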