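"""Synthetic two-lineage coastal landscape generator.

Emulates the statistical structure the downstream analyses assume: ~30
populations strung along a one-dimensional coastline, an admixture cline
between two glacial lineages (per-site ancestry proportion ``q``),
Balding-Nichols drift around lineage allele frequencies, spatially
autocorrelated environmental variables partially confounded with ancestry, a
minority of genes carrying environment-coupled allele-frequency shifts, and
low-coverage-sequencing-like per-SNP missingness.

The generator returns both the observable tables (site metadata, marine
distances, environment, SNP frequency table, genotypes) and a ``SimTruth``
record with every latent quantity, so that parameter-recovery tests can score
the pipeline against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DistMatrix, GeneAnnotation, GenotypeTable, SnpTable

__all__ = ["SimConfig", "SimTruth", "simulate_landscape", "simulate_frequencies",
           "simulate_genotypes", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic landscape.

    ``f_div`` is the Balding-Nichols F separating the two lineages from the
    ancestral pool; ``f_drift`` the per-population F of local drift around the
    admixed base frequency. ``beta_env`` is the logit-scale allele-frequency
    shift per unit of (standardized) environmental value at adaptive SNPs.
    ``env_ancestry_corr`` is the constructed correlation between environmental
    variable 1 and the ancestry cline, emulating environment-ancestry
    confounding.
    """

    n_pops: int = 30
    n_snps: int = 20000
    n_genes: int = 1000
    n_adaptive_genes: int = 20
    n_env_vars: int = 11
    f_div: float = 0.3
    f_drift: float = 0.05
    cline_steepness: float = 4.0
    env_ancestry_corr: float = 0.5
    beta_env: float = 1.5
    n_ind_per_pop: int = 20
    missing_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_pops=self.n_pops, n_snps=self.n_snps, n_genes=self.n_genes,
                      n_adaptive_genes=self.n_adaptive_genes, n_env_vars=self.n_env_vars,
                      n_ind_per_pop=self.n_ind_per_pop)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_adaptive_genes > self.n_genes:
            raise ValueError("n_adaptive_genes must not exceed n_genes")
        for name, v in dict(f_div=self.f_div, f_drift=self.f_drift).items():
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cline_steepness <= 0:
            raise ValueError("cline_steepness must be > 0")
        if not -1 <= self.env_ancestry_corr <= 1:
            raise ValueError("env_ancestry_corr must lie in [-1, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass
class SimTruth:
    """Latent state of one simulated dataset (ground truth for recovery tests)."""

    coords: np.ndarray = field(default=None)          # per-pop coastline position
    q: np.ndarray = field(default=None)               # per-pop ancestry proportion
    env: pd.DataFrame = field(default=None)           # sites x variables, standardized
    marine: "DistMatrix" = field(default=None)
    sites: pd.DataFrame = field(default=None)
    lineage_freq_a: np.ndarray = field(default=None)  # per-SNP lineage A frequency
    lineage_freq_b: np.ndarray = field(default=None)
    ancestral_freq: np.ndarray = field(default=None)
    beta: np.ndarray = field(default=None)            # per-SNP logit effect
    snp_env_var: np.ndarray = field(default=None)     # per-SNP driver variable idx (-1 = none)
    adaptive_gene_ids: set = field(default_factory=set)
    adaptive_snp_ids: set = field(default_factory=set)
    snp_gene: pd.Series = field(default=None)         # snp_id -> gene_id
    genes: GeneAnnotation = field(default=None)

    def validate(self) -> None:
        if self.q is not None and not ((self.q >= 0) & (self.q <= 1)).all():
            raise ValueError("ancestry proportions must lie in [0, 1]")


def _gp_on_line(x: np.ndarray, length_scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a standardized Gaussian process with squared-exponential kernel."""
    d = np.abs(x[:, None] - x[None, :])
    k = np.exp(-0.5 * (d / length_scale) ** 2) + 1e-8 * np.eye(len(x))
    z = np.linalg.cholesky(k) @ rng.standard_normal(len(x))
    return (z - z.mean()) / z.std(ddof=0)


def simulate_landscape(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Place populations on a 1-D coastline; build marine distances, the
    ancestry cline and the environment table.

    Returns ``(sites, marine, env, truth)`` where ``sites`` has columns
    site_id, x, lat, lon, q, group (north/south by q threshold 0.5); ``marine``
    is the coastline path-distance matrix; ``env`` holds standardized,
    spatially autocorrelated variables, variable ``env1`` given correlation
    ``env_ancestry_corr`` with q by construction.
    """
    if cfg.n_pops < 3:
        raise ValueError("n_pops must be >= 3: distance analyses are undefined below that")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    # coastline: cumulative positive segment lengths (km-ish units)
    segments = rng.uniform(30.0, 120.0, size=cfg.n_pops - 1)
    x = np.concatenate([[0.0], np.cumsum(segments)])
    labels = [f"P{i + 1:02d}" for i in range(cfg.n_pops)]
    dist = np.abs(x[:, None] - x[None, :])
    marine = DistMatrix(pd.DataFrame(dist, index=labels, columns=labels), "marine")

    # ancestry cline: logistic in scaled position, noise on the logit scale so
    # the infinite-steepness limit is exactly two pure blocks. The midpoint
    # sits at 70% of the coastline, giving the asymmetric default cline
    # (~0 at one end to ~0.77 at the other) seen in admixed two-lineage systems.
    xs = (x - x.min()) / (x.max() - x.min() if x.max() > x.min() else 1.0)
    noise = np.clip(rng.normal(0.0, 0.15, size=cfg.n_pops), -0.45, 0.45)
    with np.errstate(over="ignore"):
        q = 1.0 / (1.0 + np.exp(-(cfg.cline_steepness * (xs - 0.7) + noise)))

    length_scale = (x.max() - x.min()) / 5.0 if x.max() > x.min() else 1.0
    env = np.column_stack(
        [_gp_on_line(x, length_scale, rng) for _ in range(cfg.n_env_vars)]
    )
    # variable 1 gets the prescribed correlation with q by construction
    rho = cfg.env_ancestry_corr
    qs = (q - q.mean()) / (q.std(ddof=0) if q.std(ddof=0) > 0 else 1.0)
    e1 = rho * qs + np.sqrt(max(0.0, 1.0 - rho**2)) * env[:, 0]
    env[:, 0] = (e1 - e1.mean()) / (e1.std(ddof=0) if e1.std(ddof=0) > 0 else 1.0)
    env_df = pd.DataFrame(env, index=labels,
                          columns=[f"env{j + 1}" for j in range(cfg.n_env_vars)])

    # nominal lat/lon: walk the coastline northeast
    lat = 58.0 + 14.0 * (x - x.min()) / max(x.max() - x.min(), 1.0)
    lon = -95.0 + 25.0 * (x - x.min()) / max(x.max() - x.min(), 1.0)
    sites = pd.DataFrame(
        {
            "site_id": labels,
            "x": x,
            "lat": lat,
            "lon": lon,
            "q": q,
            "group": np.where(q < 0.5, "north", "south"),
        }
    ).set_index("site_id", drop=False)

    truth = SimTruth(coords=x, q=q, env=env_df, marine=marine, sites=sites)
    truth.validate()
    return sites, marine, env_df, truth


def _make_genes(cfg: SimConfig, rng: np.random.Generator):
    """Lay genes on chromosomes and assign every SNP to exactly one gene."""
    n_chrom = max(1, min(10, cfg.n_genes // 20 or 1))
    gene_len = 10_000
    gap = 40_000
    rows = []
    per_chrom = int(np.ceil(cfg.n_genes / n_chrom))
    g = 0
    for c in range(n_chrom):
        pos = 0
        for _ in range(per_chrom):
            if g >= cfg.n_genes:
                break
            rows.append((f"g{g + 1:05d}", f"chr{c + 1}", pos, pos + gene_len))
            pos += gene_len + gap
            g += 1
    genes = GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]))

    # distribute SNPs round-robin so every gene gets ~n_snps/n_genes
    gene_idx = np.arange(cfg.n_snps) % cfg.n_genes
    rng.shuffle(gene_idx)
    t = genes.table
    offsets = rng.integers(0, gene_len, size=cfg.n_snps)
    chrom = t["chrom"].to_numpy()[gene_idx]
    pos1 = t["start"].to_numpy()[gene_idx] + offsets + 1  # 1-based inside [start, end)
    order = np.lexsort((pos1, chrom))
    snp_ids = pd.Index([f"s{i + 1:06d}" for i in range(cfg.n_snps)], name="snp_id")
    meta = pd.DataFrame({"chrom": chrom[order], "pos": pos1[order]}, index=snp_ids)
    snp_gene = pd.Series(t["gene_id"].to_numpy()[gene_idx][order], index=snp_ids)
    return genes, meta, snp_gene


def simulate_frequencies(cfg: SimConfig, truth: SimTruth,
                         rng: np.random.Generator | None = None) -> SnpTable:
    """Draw population allele frequencies under Balding-Nichols drift.

    Lineage frequencies ``a, b ~ Beta(x(1-F_div)/F_div, (1-x)(1-F_div)/F_div)``
    around an ancestral frequency ``x ~ U(0.05, 0.95)``; the admixed base
    frequency of population *i* at SNP *l* is ``m_il = q_i a_l + (1-q_i) b_l``.
    Adaptive SNPs get ``logit(m) += beta * env_value_i`` before local drift
    ``p_il ~ Beta(mean m_il, F = f_drift)``. Per-SNP per-pop allele-copy counts
    come from binomially thinning ``n_ind_per_pop`` at rate
    ``1 - missing_rate``.
    """
    if truth.q is None:
        raise ValueError("landscape must be simulated first")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    genes, meta, snp_gene = _make_genes(cfg, rng)
    truth.genes, truth.snp_gene = genes, snp_gene

    L, P = cfg.n_snps, cfg.n_pops
    x = rng.uniform(0.05, 0.95, size=L)
    c_div = (1.0 - cfg.f_div) / cfg.f_div
    a = rng.beta(x * c_div, (1.0 - x) * c_div)
    b = rng.beta(x * c_div, (1.0 - x) * c_div)
    eps = 1e-6
    a, b = np.clip(a, eps, 1 - eps), np.clip(b, eps, 1 - eps)

    q = truth.q
    m = q[None, :] * a[:, None] + (1.0 - q[None, :]) * b[:, None]  # L x P

    # adaptive genes: every SNP in an adaptive gene gets the env-coupled shift,
    # driver variables cycling through the environment table
    gene_ids = genes.table["gene_id"].to_numpy()
    adaptive_genes = rng.choice(gene_ids, size=cfg.n_adaptive_genes, replace=False)
    truth.adaptive_gene_ids = set(adaptive_genes)
    beta = np.zeros(L)
    snp_env_var = np.full(L, -1, dtype=int)
    env = truth.env.to_numpy()
    driver_of_gene = {g: j % cfg.n_env_vars for j, g in enumerate(adaptive_genes)}
    is_adaptive = snp_gene.isin(truth.adaptive_gene_ids).to_numpy()
    if is_adaptive.any():
        beta[is_adaptive] = cfg.beta_env
        snp_env_var[is_adaptive] = [driver_of_gene[g] for g in snp_gene.to_numpy()[is_adaptive]]
        ad = np.where(is_adaptive)[0]
        shift = beta[ad, None] * env[:, snp_env_var[ad]].T  # len(ad) x P
        logit = np.log(m[ad] / (1.0 - m[ad])) + shift
        m[ad] = 1.0 / (1.0 + np.exp(-logit))
    truth.beta, truth.snp_env_var = beta, snp_env_var
    truth.adaptive_snp_ids = set(meta.index[is_adaptive])
    truth.lineage_freq_a, truth.lineage_freq_b, truth.ancestral_freq = a, b, x

    m = np.clip(m, eps, 1 - eps)
    c_dr = (1.0 - cfg.f_drift) / cfg.f_drift
    p = rng.beta(m * c_dr, (1.0 - m) * c_dr)
    p = np.clip(p, eps, 1 - eps)

    n_ind = rng.binomial(cfg.n_ind_per_pop, 1.0 - cfg.missing_rate, size=(L, P))
    labels = list(truth.sites["site_id"])
    freq = pd.DataFrame(p, index=meta.index, columns=labels)
    n = pd.DataFrame(2 * n_ind, index=meta.index, columns=labels)
    return SnpTable(meta, freq, n)


def simulate_genotypes(snp: SnpTable, cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> GenotypeTable:
    """Draw individual dosages ``g ~ Binomial(2, p_il)`` with independent
    missingness at ``missing_rate``."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pops = snp.pops
    p = snp.freq.to_numpy().T  # P x L
    rows, pop_labels, ind_ids = [], [], []
    for i, pop in enumerate(pops):
        g = rng.binomial(2, p[i], size=(cfg.n_ind_per_pop, snp.n_snps)).astype(float)
        miss = rng.random((cfg.n_ind_per_pop, snp.n_snps)) < cfg.missing_rate
        g[miss] = np.nan
        rows.append(g)
        pop_labels += [pop] * cfg.n_ind_per_pop
        ind_ids += [f"{pop}_i{j + 1:03d}" for j in range(cfg.n_ind_per_pop)]
    dosage = pd.DataFrame(np.vstack(rows), index=ind_ids, columns=snp.snp_ids)
    samples = pd.DataFrame({"pop": pop_labels}, index=ind_ids)
    return GenotypeTable(dosage, samples, snp.meta)


def simulate_dataset(cfg: SimConfig, genotypes: bool = False):
    """Run the full generator; returns ``(snp, truth)`` or
    ``(snp, gt, truth)`` with ``genotypes=True``. Deterministic in cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    _, _, _, truth = simulate_landscape(cfg, rng)
    snp = simulate_frequencies(cfg, truth, np.random.default_rng(np.random.SeedSequence([cfg.seed, 1])))
    if genotypes:
        gt = simulate_genotypes(snp, cfg, np.random.default_rng(np.random.SeedSequence([cfg.seed, 2])))
        return snp, gt, truth
    return snp, truth
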