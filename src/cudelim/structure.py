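"""Hierarchical-structure summaries: PCA, LD estimation and graph-based
pruning, replicate-admixture mode clustering, and the Evanno delta-K.

The admixture post-processing mirrors the replicate-run workflow used with
EM admixture programs: replicate Q matrices at one K are aligned over column
permutations, grouped into modes at a similarity threshold, and the major
(largest) mode is averaged. Admixture inference itself is out of scope; this
module consumes Q matrices, simulated or external.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import AdmixtureRun, GenotypeTable, SnpTable

logger = logging.getLogger(__name__)

__all__ = ["pca_freq", "compute_ld", "ld_prune", "cluster_runs", "evanno_delta_k",
           "LdPair", "ModeResult"]


@dataclass(frozen=True)
class LdPair:
    snp_i: str
    snp_j: str
    bp_distance: int
    r2: float


def pca_freq(data: SnpTable | GenotypeTable, n_axes: int = 10):
    """PCA on a frequency table (rows = populations, centered only) or a
    genotype table (rows = individuals, Patterson-standardized by
    sqrt(2 p(1-p)) with per-SNP mean imputation of missing dosages).

    Returns ``(scores, loadings, variance_fractions)``; the sign of each axis
    is fixed by making its largest-magnitude loading positive.
    """
    if isinstance(data, SnpTable):
        x = data.freq.to_numpy(dtype=float).T  # pops x SNPs
        rows = data.pops
        xc = x - x.mean(axis=0)
    else:
        g = data.dosage.to_numpy(dtype=float)
        rows = list(data.dosage.index)
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean[None, :], g)
        pbar = col_mean / 2.0
        scale = np.sqrt(np.maximum(2.0 * pbar * (1.0 - pbar), 1e-12))
        xc = (g - col_mean[None, :]) / scale[None, :]
    if not np.any(xc):
        raise ValueError("zero-variance input: PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (s**2).sum()
    n_axes = min(n_axes, len(s))
    # sign convention: largest-|loading| positive
    for a in range(n_axes):
        k = int(np.argmax(np.abs(vt[a])))
        if vt[a, k] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    scores = pd.DataFrame(u[:, :n_axes] * s[:n_axes], index=rows,
                          columns=[f"PC{a + 1}" for a in range(n_axes)])
    snp_index = data.snp_ids if isinstance(data, SnpTable) else data.dosage.columns
    loadings = pd.DataFrame(vt[:n_axes].T, index=snp_index, columns=scores.columns)
    return scores, loadings, var


def compute_ld(gt: GenotypeTable, window_bp: int = 500_000) -> list[LdPair]:
    """Composite r-squared (squared Pearson correlation of dosages over
    co-observed individuals) for all same-chromosome SNP pairs within
    ``window_bp``."""
    pairs: list[LdPair] = []
    meta = gt.meta
    g = gt.dosage.to_numpy(dtype=float)
    ids = np.array(gt.dosage.columns)
    n_skipped = 0
    for chrom, sub in meta.groupby("chrom", sort=False):
        idx = meta.index.get_indexer(sub.sort_values("pos").index)
        pos = meta["pos"].to_numpy()[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                bp = int(pos[b] - pos[a])
                if bp > window_bp:
                    break
                gi, gj = g[:, idx[a]], g[:, idx[b]]
                ok = ~(np.isnan(gi) | np.isnan(gj))
                x, y = gi[ok], gj[ok]
                if len(x) < 2 or x.std() == 0 or y.std() == 0:
                    n_skipped += 1
                    continue
                r = np.corrcoef(x, y)[0, 1]
                pairs.append(LdPair(ids[idx[a]], ids[idx[b]], bp, float(r * r)))
    if n_skipped:
        logger.info("compute_ld: %d monomorphic/short pairs skipped", n_skipped)
    return pairs


def ld_prune(pairs: list[LdPair], snps, positions: dict | None = None,
             max_bp: int = 200_000, r2_max: float = 0.1) -> list[str]:
    """Graph-based LD pruning: link SNPs whose pair has bp_distance <= max_bp
    and r2 > r2_max; iteratively delete the highest-degree node (ties: larger
    incident r2 sum, then larger position) until the graph is edgeless.

    Returns surviving SNP ids, in the input order. The postcondition (no
    surviving pair within max_bp with r2 > r2_max) is asserted.
    """
    snps = list(snps)
    positions = positions or {}
    g = nx.Graph()
    g.add_nodes_from(snps)
    for p in pairs:
        if p.bp_distance <= max_bp and p.r2 > r2_max:
            if g.has_edge(p.snp_i, p.snp_j):
                g[p.snp_i][p.snp_j]["r2"] = max(g[p.snp_i][p.snp_j]["r2"], p.r2)
            else:
                g.add_edge(p.snp_i, p.snp_j, r2=p.r2)
    while g.number_of_edges() > 0:
        best = max(
            g.nodes,
            key=lambda s: (
                g.degree(s),
                sum(e["r2"] for e in g[s].values()),
                positions.get(s, 0),
                s,  # final deterministic fallback
            ),
        )
        g.remove_node(best)
    kept = set(g.nodes)
    for p in pairs:  # asserted postcondition
        if p.snp_i in kept and p.snp_j in kept and p.bp_distance <= max_bp:
            assert p.r2 <= r2_max, "ld_prune postcondition violated"
    return [s for s in snps if s in kept]


def _align_cost(qa: np.ndarray, qb: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal column matching of Q matrices; returns (permutation, sum |diff|)."""
    k = qa.shape[1]
    cost = np.zeros((k, k))
    for a in range(k):
        cost[a] = np.abs(qa[:, [a]] - qb).sum(axis=0)
    ri, ci = linear_sum_assignment(cost)
    perm = np.empty(k, dtype=int)
    perm[ri] = ci
    return perm, float(cost[ri, ci].sum())


def similarity(run_a: AdmixtureRun, run_b: AdmixtureRun) -> float:
    """1 - (1/2N) sum |Q - Q'| maximized over column permutations."""
    qa, qb = run_a.Q.to_numpy(dtype=float), run_b.Q.to_numpy(dtype=float)
    _, total = _align_cost(qa, qb)
    return 1.0 - total / (2.0 * qa.shape[0])


@dataclass
class ModeResult:
    modes: list[list[str]]          # run ids per mode, largest (major) first
    major_q: pd.DataFrame           # averaged, row-renormalized Q of the major mode
    similarities: pd.DataFrame      # pairwise similarity matrix


def cluster_runs(runs: list[AdmixtureRun], sim_threshold: float = 0.85) -> ModeResult:
    """Group replicate runs into modes by pairwise aligned similarity.

    Runs are linked when similarity >= ``sim_threshold``; modes are the
    connected components; the major mode is the largest (ties broken by the
    higher mean log-likelihood, then by sorted run ids for determinism). The
    major-mode Q is the element-wise mean of member Qs after aligning each to
    the mode's highest-likelihood member, rows re-normalized.
    """
    if not runs:
        raise ValueError("no runs given")
    ks = {r.K for r in runs}
    if len(ks) > 1:
        raise ValueError(f"mixed K across runs: {sorted(ks)}")
    runs = sorted(runs, key=lambda r: r.run_id)
    ids = [r.run_id for r in runs]
    n = len(runs)
    sim = np.ones((n, n))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = similarity(runs[i], runs[j])
            if sim[i, j] >= sim_threshold:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c),
                              -float(np.mean([runs[i].log_likelihood for i in c])),
                              tuple(ids[i] for i in c)))
    major = comps[0]
    ref = max(major, key=lambda i: (runs[i].log_likelihood, ids[i]))
    qr = runs[ref].Q.to_numpy(dtype=float)
    acc = np.zeros_like(qr)
    for i in major:
        qi = runs[i].Q.to_numpy(dtype=float)
        perm, _ = _align_cost(qr, qi)
        acc += qi[:, perm]
    acc /= len(major)
    acc /= acc.sum(axis=1, keepdims=True)
    major_q = pd.DataFrame(acc, index=runs[ref].Q.index,
                           columns=[f"cluster{c + 1}" for c in range(qr.shape[1])])
    return ModeResult(
        modes=[[ids[i] for i in c] for c in comps],
        major_q=major_q,
        similarities=pd.DataFrame(sim, index=ids, columns=ids),
    )


def evanno_delta_k(likelihoods: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno delta-K: |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) on mean
    log-likelihoods over replicate runs; undefined (NaN) at the endpoints.
    """
    ks = sorted(likelihoods)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(likelihoods[k]) < 2:
            raise ValueError(f"need >= 2 runs at K={k} for a standard deviation")
    mean = {k: float(np.mean(likelihoods[k])) for k in ks}
    sd = {k: float(np.std(likelihoods[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            rows.append((k, mean[k], sd[k], np.nan))
            continue
        second = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
        if sd[k] == 0:
            logger.warning("evanno_delta_k: sd = 0 at K=%d, delta-K infinite", k)
            rows.append((k, mean[k], sd[k], np.inf))
        else:
            rows.append((k, mean[k], sd[k], second / sd[k]))
    return pd.DataFrame(rows, columns=["K", "mean_logL", "sd_logL", "delta_k"]).set_index("K")
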