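"""Pairwise distances: Hudson FST, allele-frequency difference (AFD),
individual p-distance, environmental PCA distance, ancestry distance, and
BIONJ tree construction.

FST uses the Hudson/Bhatia estimator with the finite-sample correction and a
ratio-of-averages combination across SNPs: per SNP,

    N = (p_a - p_b)^2 - p_a(1-p_a)/(n_a - 1) - p_b(1-p_b)/(n_b - 1)
    D = p_a(1-p_b) + p_b(1-p_a)

and FST = sum(N) / sum(D) over SNPs passing the global MAF filter with at
least 2 allele copies in both populations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import DistMatrix, GenotypeTable, SnpTable

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fst",
    "compute_afd",
    "fst_matrix",
    "afd_matrix",
    "compute_pdistance",
    "pdistance_matrix",
    "env_distance",
    "ancestry_distance",
    "bionj_tree",
    "newick_path_lengths",
]


def _pair_mask(snp: SnpTable, pop_a: str, pop_b: str, maf_min: float,
               need_n2: bool = True) -> np.ndarray:
    maf = snp.global_maf().to_numpy()
    mask = maf > maf_min
    if need_n2:
        na = snp.n[pop_a].to_numpy()
        nb = snp.n[pop_b].to_numpy()
        low = mask & ((na <= 1) | (nb <= 1))
        if low.any():
            logger.info("FST %s-%s: %d SNPs excluded for n <= 1", pop_a, pop_b, int(low.sum()))
        mask &= (na >= 2) & (nb >= 2)
    if not mask.any():
        raise ValueError(
            f"no SNPs pass maf_min={maf_min} (and n >= 2) for pair {pop_a}-{pop_b}"
        )
    return mask


def compute_fst(snp: SnpTable, pop_a: str, pop_b: str, maf_min: float = 0.01) -> float:
    """Hudson FST between two populations, ratio of averages across SNPs."""
    for p in (pop_a, pop_b):
        if p not in snp.freq.columns:
            raise KeyError(f"population {p!r} not in table")
    mask = _pair_mask(snp, pop_a, pop_b, maf_min)
    pa = snp.freq[pop_a].to_numpy()[mask]
    pb = snp.freq[pop_b].to_numpy()[mask]
    na = snp.n[pop_a].to_numpy()[mask].astype(float)
    nb = snp.n[pop_b].to_numpy()[mask].astype(float)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    d = den.sum()
    if d <= 0:
        raise ValueError(f"zero total heterozygosity for pair {pop_a}-{pop_b}")
    return float(num.sum() / d)


def compute_afd(snp: SnpTable, pop_a: str, pop_b: str, maf_min: float = 0.01) -> float:
    """Mean absolute per-SNP allele-frequency difference, in [0, 1]."""
    mask = _pair_mask(snp, pop_a, pop_b, maf_min, need_n2=False)
    pa = snp.freq[pop_a].to_numpy()[mask]
    pb = snp.freq[pop_b].to_numpy()[mask]
    return float(np.mean(np.abs(pa - pb)))


def _pairwise(snp: SnpTable, fn, maf_min: float, kind: str) -> DistMatrix:
    pops = snp.pops
    n = len(pops)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = fn(snp, pops[i], pops[j], maf_min)
    return DistMatrix(pd.DataFrame(v, index=pops, columns=pops), kind)


def fst_matrix(snp: SnpTable, maf_min: float = 0.01) -> DistMatrix:
    return _pairwise(snp, compute_fst, maf_min, "genetic_fst")


def afd_matrix(snp: SnpTable, maf_min: float = 0.01) -> DistMatrix:
    return _pairwise(snp, compute_afd, maf_min, "genetic_afd")


def compute_pdistance(gt: GenotypeTable, ind_i: str, ind_j: str,
                      n_snps_total: int | None = None,
                      genome_length: int | None = None) -> tuple[float, float]:
    """Uncorrected p-distance between two individuals on dosage data.

    raw = mean over co-observed SNPs of |g_i - g_j| / 2; SNPs missing in
    either individual are ignored. ``scaled`` re-expresses the raw distance
    per genome site by multiplying with n_snps_total / genome_length.
    """
    gi = gt.dosage.loc[ind_i].to_numpy()
    gj = gt.dosage.loc[ind_j].to_numpy()
    ok = ~(np.isnan(gi) | np.isnan(gj))
    if not ok.any():
        raise ValueError(f"no co-observed SNPs between {ind_i} and {ind_j}")
    raw = float(np.mean(np.abs(gi[ok] - gj[ok]) / 2.0))
    if n_snps_total is None:
        n_snps_total = gt.dosage.shape[1]
    scaled = raw * n_snps_total / genome_length if genome_length else raw
    return raw, scaled


def pdistance_matrix(gt: GenotypeTable, n_snps_total: int | None = None,
                     genome_length: int | None = None) -> DistMatrix:
    """All-pairs scaled p-distance (raw if genome_length is None)."""
    g = gt.dosage.to_numpy()
    obs = ~np.isnan(g)
    gz = np.nan_to_num(g)
    n = g.shape[0]
    co = obs.astype(float) @ obs.astype(float).T
    if (co[np.triu_indices(n, 1)] == 0).any():
        raise ValueError("some individual pairs share no co-observed SNPs")
    # sum over co-observed SNPs of |gi - gj| via masked expansion
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(gz[i] - gz) / 2.0
        diff[~(obs[i] & obs)] = 0.0
        d[i] = diff.sum(axis=1)
    raw = d / co
    np.fill_diagonal(raw, 0.0)
    scale = (n_snps_total or g.shape[1]) / genome_length if genome_length else 1.0
    raw = (raw + raw.T) / 2.0  # enforce exact symmetry against float noise
    return DistMatrix(
        pd.DataFrame(raw * scale, index=gt.dosage.index, columns=gt.dosage.index),
        "pdistance",
    )


def env_distance(env: pd.DataFrame, var_threshold: float = 0.92,
                 n_axes: int | None = None) -> DistMatrix:
    """Euclidean distance between sites on retained PCA axes of the
    standardized environment table.

    Axes retained: the explicit ``n_axes`` if given, else the smallest count
    whose cumulative explained variance reaches ``var_threshold``.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise ValueError("need >= 2 sites and >= 2 variables")
    if env.isna().any().any():
        raise ValueError("environment table contains missing values")
    sd = env.std(ddof=0)
    keep = sd[sd > 0].index
    if len(keep) == 0:
        raise ValueError("all environmental variables are constant")
    if len(keep) < env.shape[1]:
        logger.warning("dropping %d constant variables", env.shape[1] - len(keep))
    z = (env[keep] - env[keep].mean()) / env[keep].std(ddof=0)
    zc = z.to_numpy() - z.to_numpy().mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    var = s**2 / (s**2).sum()
    cum = np.cumsum(var)
    if n_axes is None:
        n_axes = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_axes = min(n_axes, len(s))
    scores = u[:, :n_axes] * s[:n_axes]
    logger.info("env_distance: %d axes retained, cumulative variance %.3f",
                n_axes, cum[n_axes - 1])
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(scores))
    out = DistMatrix(pd.DataFrame(d, index=env.index, columns=env.index), "environmental")
    out.n_axes, out.cum_variance = n_axes, float(cum[n_axes - 1])
    return out


def ancestry_distance(sites: pd.DataFrame) -> DistMatrix:
    """|q_i - q_j| on per-site average ancestry proportions."""
    if "q" not in sites.columns or sites["q"].isna().any():
        raise ValueError("every site needs an ancestry proportion q")
    q = sites["q"].to_numpy(dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q must lie in [0, 1]")
    d = np.abs(q[:, None] - q[None, :])
    labels = list(sites["site_id"] if "site_id" in sites.columns else sites.index)
    return DistMatrix(pd.DataFrame(d, index=labels, columns=labels), "ancestry")


# ---------------------------------------------------------------------------
# BIONJ (Gascuel 1997): neighbor joining with variance-weighted reduction.
# ---------------------------------------------------------------------------

def bionj_tree(d: DistMatrix) -> str:
    """Build an unrooted BIONJ tree; returns a Newick string.

    Branch lengths are reported as computed (negative lengths are kept so
    that additive matrices are reproduced exactly). Agglomeration ties are
    broken by label order, making the topology invariant to input ordering.
    """
    labels = d.labels
    n = len(labels)
    if n < 3:
        raise ValueError("BIONJ needs at least 3 taxa")
    order = np.argsort(np.array(labels, dtype=object))
    labels = [labels[i] for i in order]
    dm = d.values.to_numpy(dtype=float)[np.ix_(order, order)].copy()
    if not np.isfinite(dm).all():
        raise ValueError("distance matrix entries must be finite")
    vm = dm.copy()  # variance estimates, initialized to the distances
    nodes = list(labels)  # newick fragment per active node
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qm, np.inf)
        # deterministic argmin: smallest Q, ties by (i, j) index order
        i_loc, j_loc = divmod(int(np.argmin(qm)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = dm[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        # BIONJ lambda minimizing the variance of the reduced distances
        others = [a for a in active if a not in (i, j)]
        vij = vm[i, j]
        if vij > 0:
            lam = 0.5 + sum(vm[j, k] - vm[i, k] for k in others) / (2.0 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        for k in others:
            dm_new = lam * (dm[i, k] - li) + (1.0 - lam) * (dm[j, k] - lj)
            vm_new = lam * vm[i, k] + (1.0 - lam) * vm[j, k] - lam * (1.0 - lam) * vij
            dm[i, k] = dm[k, i] = dm_new
            vm[i, k] = vm[k, i] = vm_new
        nodes[i] = f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"
        active.remove(j)

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    return f"({nodes[a]}:{la:.12g},{nodes[b]}:{lb:.12g},{nodes[c]}:{lc:.12g});"


def newick_path_lengths(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path lengths of a Newick tree (internal helper for
    additivity checks and tree summaries)."""
    import io

    from Bio import Phylo

    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = tree.get_terminals()
    names = [t.name for t in leaves]
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tree.distance(leaves[i], leaves[j])
    return pd.DataFrame(out, index=names, columns=names)
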