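"""Readers, writers and dataset-level filters.

Tabular interchange is TSV (UTF-8, header row); intervals are BED 0-based
half-open; SNP positions are 1-based in VCF and TSV. VCF reading goes through
cyvcf2; the VCF writer emits minimal v4.2 text with GT fields and ``./.`` for
missing genotypes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeTable, SnpTable

logger = logging.getLogger(__name__)

__all__ = ["read_vcf_freqs", "read_popmap", "write_vcf", "apply_filters",
           "read_freqs_tsv", "write_freqs_tsv", "read_q_matrices"]


def read_popmap(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    return df.set_index("sample")["pop"]


def write_vcf(gt: GenotypeTable, path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT only (``./.`` missing).

    REF/ALT are placeholder A/T alleles; dosage counts ALT copies.
    """
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(gt.dosage.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gt.meta["chrom"]):
            ln = int(gt.meta.loc[gt.meta["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = gt.dosage.to_numpy()
        order = np.lexsort((gt.meta["pos"].to_numpy(), gt.meta["chrom"].to_numpy()))
        for j in order:
            snp = gt.meta.index[j]
            chrom, pos = gt.meta.iloc[j]["chrom"], int(gt.meta.iloc[j]["pos"])
            cells = [gtmap.get(v, "./.") if not np.isnan(v) else "./." for v in dos[:, j]]
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(cells) + "\n")


def read_vcf_freqs(vcf_path, popmap: pd.Series | str | Path) -> tuple[SnpTable, GenotypeTable]:
    """Read a VCF (GT field) into per-population allele frequencies and a
    dosage table. Multi-allelic records are skipped (counted in the log).

    Frequencies are of the ALT allele; ``SnpTable.global_maf`` folds them.
    Per-pop allele count n = 2 x individuals with a called genotype.
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, pd.Series):
        popmap = read_popmap(popmap)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in popmap.index]
    if missing:
        raise ValueError(f"samples missing from popmap: {missing[:5]}")
    pops = list(dict.fromkeys(popmap.loc[samples]))
    if not pops:
        raise ValueError("empty sample/popmap intersection")
    pop_of = popmap.loc[samples].to_numpy()
    pop_masks = {p: pop_of == p for p in pops}

    ids, chroms, poss, dosage_rows = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotypes, dtype=object)
        d = np.array([(g[0] + g[1]) if (g[0] >= 0 and g[1] >= 0) else np.nan
                      for g in gts], dtype=float)
        dosage_rows.append(d)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if n_multi:
        logger.info("read_vcf_freqs: %d multi-allelic records skipped", n_multi)
    if not ids:
        raise ValueError("no biallelic records in VCF")
    dos = np.vstack(dosage_rows).T  # individuals x SNPs
    idx = pd.Index(ids, name="snp_id")
    meta = pd.DataFrame({"chrom": chroms, "pos": poss}, index=idx)
    freq = np.full((len(ids), len(pops)), np.nan)
    n = np.zeros((len(ids), len(pops)), dtype=int)
    for jp, p in enumerate(pops):
        sub = dos[pop_masks[p]]
        called = ~np.isnan(sub)
        n[:, jp] = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            tot = np.nansum(sub, axis=0)
            freq[:, jp] = np.where(n[:, jp] > 0, tot / np.maximum(n[:, jp], 1), np.nan)
    snp = SnpTable(meta,
                   pd.DataFrame(np.nan_to_num(freq), index=idx, columns=pops),
                   pd.DataFrame(n, index=idx, columns=pops))
    samples_df = pd.DataFrame({"pop": pop_of}, index=samples)
    gt = GenotypeTable(pd.DataFrame(dos, index=samples, columns=idx), samples_df, meta)
    return snp, gt


def apply_filters(snp: SnpTable, maf_min: float = 0.01,
                  coverage_min: float = 0.75,
                  n_ind_total: int | None = None) -> SnpTable:
    """Dataset-level SNP filters: global folded MAF strictly above
    ``maf_min`` and fraction of individuals with data at least
    ``coverage_min``."""
    maf = snp.global_maf()
    keep = maf > maf_min
    if n_ind_total is None:
        n_ind_total = int(np.ceil(snp.n.sum(axis=1).max() / 2))
    cov = snp.coverage_fraction(n_ind_total)
    keep &= cov >= coverage_min
    logger.info("apply_filters: %d -> %d SNPs (maf > %g, coverage >= %g)",
                snp.n_snps, int(keep.sum()), maf_min, coverage_min)
    if not keep.any():
        raise ValueError("no SNPs pass the filters")
    return snp.subset(snp.snp_ids[keep])


def write_freqs_tsv(snp: SnpTable, path) -> None:
    snp.to_frame().to_csv(path, sep="\t", index=False)


def read_freqs_tsv(path) -> SnpTable:
    return SnpTable.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def read_q_matrices(directory, pattern: str = "*.qmatrix.tsv"):
    """Load replicate Q matrices named ``K<k>_run<r>.qmatrix.tsv`` with a
    sibling ``likelihoods.tsv`` (columns K, run, logL) in the directory."""
    from .containers import AdmixtureRun

    directory = Path(directory)
    lik = pd.read_csv(directory / "likelihoods.tsv", sep="\t")
    lik["key"] = ["K" + str(k) + "_run" + str(r) for k, r in zip(lik["K"], lik["run"])]
    ll = lik.set_index("key")["logL"]
    runs = []
    for f in sorted(directory.glob(pattern)):
        key = f.name.replace(".qmatrix.tsv", "")
        q = pd.read_csv(f, sep="\t", index_col=0)
        runs.append(AdmixtureRun(K=q.shape[1], Q=q, log_likelihood=float(ll[key]),
                                 run_id=key))
    return runs
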