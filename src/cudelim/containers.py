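"""Core in-memory containers shared across the pipeline.

All tabular data rides on pandas. Conventions:

* SNP positions are 1-based (VCF style) everywhere a user sees them;
  interval arithmetic (genes, regions, QTL) is 0-based half-open (BED style).
  Conversion happens in exactly one place (``wza_consensus.assign_snps_to_genes``).
* Site (population) identifiers are strings and order is meaningful: every
  matrix keyed by sites uses the same label order as ``SnpTable.pops``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SnpTable",
    "GenotypeTable",
    "DistMatrix",
    "AdmixtureRun",
    "ScanStats",
    "GeneAnnotation",
    "RegionSet",
]

DIST_KINDS = {
    "genetic_fst",
    "genetic_afd",
    "pdistance",
    "marine",
    "environmental",
    "ancestry",
    "residual",
}


@dataclass
class SnpTable:
    """Per-SNP, per-population minor-allele frequencies with sample counts.

    Parameters
    ----------
    meta : DataFrame with columns ``snp_id``, ``chrom``, ``pos`` (1-based int),
        indexed by ``snp_id``.
    freq : DataFrame (SNPs x populations) of allele frequencies in [0, 1].
    n : DataFrame (SNPs x populations) of allele-copy counts
        (2 x individuals with data at the SNP); non-negative integers.

    ``global_maf`` is always derived: the n-weighted mean frequency per SNP,
    folded to <= 0.5.
    """

    meta: pd.DataFrame
    freq: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.meta.index.equals(self.freq.index) and self.freq.index.equals(self.n.index)):
            raise ValueError("meta, freq and n must share the same SNP index")
        if not self.freq.columns.equals(self.n.columns):
            raise ValueError("freq and n must share the same population columns")
        f = self.freq.to_numpy()
        if np.nanmin(f, initial=0.0) < 0 or np.nanmax(f, initial=0.0) > 1:
            raise ValueError("frequencies must lie in [0, 1]")
        if (self.n.to_numpy() < 0).any():
            raise ValueError("allele counts must be non-negative")

    @property
    def pops(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def snp_ids(self) -> pd.Index:
        return self.freq.index

    @property
    def n_snps(self) -> int:
        return len(self.freq)

    def global_maf(self) -> pd.Series:
        """n-weighted mean frequency per SNP, folded to the minor allele."""
        f = self.freq.to_numpy(dtype=float)
        w = self.n.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mean = np.nansum(np.where(w > 0, f * w, 0.0), axis=1) / np.maximum(
                np.nansum(w, axis=1), 1e-300
            )
        return pd.Series(np.minimum(mean, 1.0 - mean), index=self.freq.index, name="global_maf")

    def coverage_fraction(self, n_ind_total: int) -> pd.Series:
        """Per SNP, fraction of individuals contributing data."""
        return self.n.sum(axis=1) / (2.0 * n_ind_total)

    def subset(self, snp_ids) -> "SnpTable":
        return SnpTable(self.meta.loc[snp_ids], self.freq.loc[snp_ids], self.n.loc[snp_ids])

    def to_frame(self) -> pd.DataFrame:
        """Flat table: chrom, pos, snp_id, freq_<pop>..., n_<pop>..."""
        out = self.meta[["chrom", "pos"]].copy()
        out.insert(2, "snp_id", self.meta.index)
        for p in self.pops:
            out[f"freq_{p}"] = self.freq[p]
        for p in self.pops:
            out[f"n_{p}"] = self.n[p]
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpTable":
        pops = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
        idx = pd.Index(df["snp_id"].astype(str), name="snp_id")
        meta = pd.DataFrame(
            {"chrom": df["chrom"].astype(str).values, "pos": df["pos"].astype(int).values},
            index=idx,
        )
        freq = pd.DataFrame({p: df[f"freq_{p}"].values for p in pops}, index=idx)
        n = pd.DataFrame({p: df[f"n_{p}"].astype(int).values for p in pops}, index=idx)
        return cls(meta, freq, n)


@dataclass
class GenotypeTable:
    """Individual dosage matrix (individuals x SNPs), entries 0/1/2 or NaN.

    ``samples`` carries one row per individual with its ``pop`` label;
    ``meta`` mirrors :class:`SnpTable.meta` for the SNP columns.
    """

    dosage: pd.DataFrame
    samples: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosage.index.equals(pd.Index(self.samples.index)):
            raise ValueError("dosage rows must match samples index")
        if not self.dosage.columns.equals(self.meta.index):
            raise ValueError("dosage columns must match SNP meta index")

    @property
    def n_ind(self) -> int:
        return len(self.dosage)

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.columns

    def pop_of(self) -> pd.Series:
        return self.samples["pop"]


@dataclass
class DistMatrix:
    """Labeled symmetric distance matrix.

    ``kind`` is one of {genetic_fst, genetic_afd, pdistance, marine,
    environmental, ancestry, residual}. All kinds except ``residual`` have a
    zero diagonal; the residual diagonal is ignored downstream.
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in DIST_KINDS:
            raise ValueError(f"unknown DistMatrix kind {self.kind!r}")
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if self.kind != "residual" and not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("non-residual distance matrix must have a zero diagonal")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def n(self) -> int:
        return len(self.values)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (i > j) entries as a flat vector, row-major order."""
        v = self.values.to_numpy(dtype=float)
        return v[np.tril_indices(self.n, k=-1)]

    def reorder(self, labels) -> "DistMatrix":
        return DistMatrix(self.values.loc[labels, labels], self.kind)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path, kind: str) -> "DistMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, kind)

    @classmethod
    def from_condensed(cls, labels, tril: np.ndarray, kind: str) -> "DistMatrix":
        n = len(labels)
        v = np.zeros((n, n))
        v[np.tril_indices(n, k=-1)] = tril
        v = v + v.T
        return cls(pd.DataFrame(v, index=list(labels), columns=list(labels)), kind)


@dataclass
class AdmixtureRun:
    """One replicate ancestry-proportion matrix with its log-likelihood."""

    K: int
    Q: pd.DataFrame  # individuals x K, rows sum to 1
    log_likelihood: float
    run_id: str

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.Q.shape[1] != self.K:
            raise ValueError("Q must have K columns")
        rs = self.Q.to_numpy(dtype=float).sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1 within 1e-6")


@dataclass
class ScanStats:
    """Per-SNP statistic from one scan method.

    ``orientation`` is ``higher_more_extreme`` (larger value = stronger
    signal; ranked into empirical p-values downstream) or ``is_p_value``
    (used directly).
    """

    method: str
    tag: str
    values: pd.Series  # indexed by snp_id
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_more_extreme", "is_p_value"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "is_p_value":
            v = self.values.dropna()
            if ((v <= 0) | (v > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")

    @property
    def name(self) -> str:
        return f"{self.method}:{self.tag}" if self.tag else self.method

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.values.index,
                "method": self.method,
                "tag": self.tag,
                "value": self.values.values,
                "orientation": self.orientation,
            }
        )


@dataclass
class GeneAnnotation:
    """Gene intervals, 0-based half-open, one row per gene.

    ``table`` columns: gene_id, chrom, start, end. Intervals may overlap.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] >= t["end"]).any():
            raise ValueError("gene intervals require start < end")

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene_id"], dtype={0: str, 3: str},
        )
        return cls(df[["gene_id", "chrom", "start", "end"]])

    def to_bed(self, path) -> None:
        self.table[["chrom", "start", "end", "gene_id"]].to_csv(
            path, sep="\t", header=False, index=False
        )


REGION_CLASSES = {"ancestry_tract", "local_pca_outlier", "qtl", "custom"}


@dataclass
class RegionSet:
    """Classified genomic intervals (0-based half-open).

    ``table`` columns: chrom, start, end, region_class, name (optional).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] >= t["end"]).any():
            raise ValueError("region intervals require start < end")
        bad = set(t["region_class"]) - REGION_CLASSES
        if bad:
            raise ValueError(f"unknown region classes: {sorted(bad)}")

    def of_class(self, region_class: str) -> pd.DataFrame:
        return self.table[self.table["region_class"] == region_class]

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        df = df.iloc[:, :5] if df.shape[1] >= 5 else df
        names = ["chrom", "start", "end", "region_class", "name"][: df.shape[1]]
        df.columns = names
        if "name" not in df.columns:
            df["name"] = [f"r{i}" for i in range(len(df))]
        return cls(df)

    def to_bed(self, path) -> None:
        self.table[["chrom", "start", "end", "region_class", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )
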