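"""Per-SNP selection scans and gene-environment association statistics.

* ``pcadapt_scan``: PCA-based outlier scan on standardized genotypes;
  multi-dimensional z-scores are converted to robust Mahalanobis distances
  with the orthogonalized Gnanadesikan-Kettenring (OGK) covariance, rescaled
  by the genomic inflation factor (median D^2 over the chi-square median),
  and converted to upper-tail chi-square p-values.
* ``rda_fit``: redundancy analysis (and partial RDA via residualization on a
  covariate) of the site x SNP frequency matrix on standardized predictors,
  with Ezekiel-adjusted R^2, permutation tests of canonical axes, and squared
  per-SNP loadings exported as scan statistics.
* ``vif_prune`` / ``backward_select``: predictor pruning by variance
  inflation and by drop-one permutation tests.
* ``variance_partition``: three-set inclusion-exclusion decomposition of the
  adjusted R^2.
* ``univariate_gea``: per-SNP |Spearman| correlation with each environmental
  variable — a univariate stand-in statistic, labelled ``bf_analog``, for
  external Bayesian association scores the pipeline can also ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable, ScanStats, SnpTable

logger = logging.getLogger(__name__)

__all__ = ["pcadapt_scan", "ogk_covariance", "vif_prune", "rda_fit", "RdaModel",
           "backward_select", "variance_partition", "univariate_gea",
           "write_baypass_counts"]


# ---------------------------------------------------------------------------
# OGK robust covariance
# ---------------------------------------------------------------------------

def _mad_scale(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return stats.median_abs_deviation(x, axis=axis, scale="normal")


def ogk_covariance(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonalized Gnanadesikan-Kettenring location/scatter estimate.

    Robust scale is the normal-consistent MAD; pairwise covariances come from
    the Gnanadesikan-Kettenring identity cov(x,y) = (s(x+y)^2 - s(x-y)^2)/4;
    one orthogonalization pass re-estimates scales on the decorrelated
    projections. Returns ``(location, scatter)``.
    """
    k = z.shape[1]
    d = _mad_scale(z)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("degenerate robust scale")
    y = z / d
    u = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            sp = _mad_scale(y[:, a] + y[:, b])
            sm = _mad_scale(y[:, a] - y[:, b])
            u[a, b] = u[b, a] = 0.25 * (sp**2 - sm**2)
    evals, e = np.linalg.eigh(u)
    proj = y @ e
    gam = _mad_scale(proj)
    if np.any(gam <= 0):
        raise np.linalg.LinAlgError("degenerate projected scale")
    mu_p = np.median(proj, axis=0)
    a_mat = d[:, None] * e  # maps projected coords back to original scale
    cov = a_mat @ np.diag(gam**2) @ a_mat.T
    loc = a_mat @ mu_p
    return loc, cov


def pcadapt_scan(gt: GenotypeTable, k: int, maf_min: float = 0.05,
                 df: int | None = None, seed: int | None = None) -> ScanStats:
    """PCA-outlier genome scan on individual dosages.

    Genotypes are filtered to global MAF > ``maf_min``, Patterson-standardized
    and mean-imputed; per-SNP z-scores are the regressions of the SNP on each
    of the first ``k`` components scaled by the residual standard deviation.
    Robust Mahalanobis distances (OGK) are divided by the genomic inflation
    factor lambda = median(D^2)/median(chi2_df) and converted to upper-tail
    chi-square p-values with ``df`` degrees of freedom (default ``k``).

    SNPs excluded by the MAF filter are absent from the output.
    """
    g = gt.dosage.to_numpy(dtype=float)
    n = g.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_individuals={n}")
    df = k if df is None else df
    pbar = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(pbar, 1 - pbar)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError("no SNPs pass the MAF filter")
    g = g[:, keep]
    snp_ids = gt.dosage.columns[keep]
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean[None, :], g)
    p2 = col_mean / 2.0
    x = (g - col_mean[None, :]) / np.sqrt(np.maximum(2 * p2 * (1 - p2), 1e-12))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k]  # orthonormal columns
    b = scores.T @ x                       # k x L regression coefficients
    ss_tot = (x**2).sum(axis=0)
    ss_res = np.maximum(ss_tot - (b**2).sum(axis=0), 1e-12)
    sigma = np.sqrt(ss_res / max(n - k, 1))
    z = (b / sigma[None, :]).T             # L x k
    try:
        loc, cov = ogk_covariance(z)
    except np.linalg.LinAlgError:
        logger.warning("pcadapt_scan: degenerate robust covariance, "
                       "falling back to classical covariance")
        loc, cov = z.mean(axis=0), np.cov(z, rowvar=False).reshape(k, k)
    zc = z - loc
    d2 = np.einsum("ij,jk,ik->i", zc, np.linalg.inv(cov), zc)
    lam = np.median(d2) / stats.chi2.median(df)
    logger.info("pcadapt_scan: genomic inflation lambda = %.3f (df=%d)", lam, df)
    p = stats.chi2.sf(d2 / lam, df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = ScanStats("pcadapt", "", pd.Series(p, index=snp_ids), "is_p_value")
    out.inflation = float(lam)
    return out


# ---------------------------------------------------------------------------
# RDA / pRDA
# ---------------------------------------------------------------------------

@dataclass
class RdaModel:
    predictors: list[str]
    site_scores: pd.DataFrame        # sites x retained axes
    loadings: pd.DataFrame           # SNPs x retained axes
    r2: float
    adj_r2: float
    axis_p: list[float]              # sequential permutation p per tested axis
    n_retained: int
    covariate: str | None = None
    eigenvalues: np.ndarray = field(default=None)

    def scan_stats(self, prefix: str | None = None) -> list[ScanStats]:
        """Squared per-SNP loadings on each retained axis."""
        prefix = prefix or ("prda" if self.covariate else "rda")
        out = []
        for a in range(self.n_retained):
            col = self.loadings.columns[a]
            out.append(ScanStats(prefix, col,
                                 self.loadings[col] ** 2, "higher_more_extreme"))
        return out


def _residual_on(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(c)), c])
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


def _fit_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares fit of centered response on design; returns (R^2, Yfit)."""
    q, _ = np.linalg.qr(x)
    yfit = q @ (q.T @ y)
    ss_tot = float((y**2).sum())
    return float((yfit**2).sum() / ss_tot), yfit


def _ezekiel(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        raise ValueError(f"too few sites (n={n}) for m={m} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda_fit(freq: SnpTable, env: pd.DataFrame, covariate: pd.Series | None = None,
            n_perm: int = 999, alpha_axis: float = 0.05,
            seed: int | None = None) -> RdaModel:
    """Redundancy analysis of population frequencies on environmental
    predictors; with ``covariate`` given, a partial RDA where response and
    predictors are first residualized on the covariate.

    Canonical axes come from the SVD of the fitted values; each axis is
    tested sequentially by a pseudo-F permutation test (free row permutation
    of the residualized response), retaining axes while p < ``alpha_axis``.
    """
    sites = freq.pops
    if list(env.index) != sites:
        env = env.loc[sites]
    y = freq.freq.to_numpy(dtype=float).T  # sites x SNPs
    y = y - y.mean(axis=0)
    x = env.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    n, m = x.shape
    if m >= n - 1:
        raise ValueError(f"m={m} predictors with n={n} sites: model saturated")
    cov_name = None
    if covariate is not None:
        c = covariate.loc[sites].to_numpy(dtype=float)
        if np.std(c) > 0:
            y = _residual_on(y, c)
            x = _residual_on(x, c)
        cov_name = getattr(covariate, "name", "covariate") or "covariate"
    r2, yfit = _fit_r2(y, x)
    adj = _ezekiel(r2, n, m)
    uu, ss, vvt = np.linalg.svd(yfit, full_matrices=False)
    eig = ss**2
    n_axes = min(m, n - 1, int((eig > eig[0] * 1e-12).sum()) if eig.size else 0)
    ss_res = float((y**2).sum()) - float(eig.sum())
    dof_res = max(n - m - 1, 1)

    rng = np.random.default_rng(seed)
    axis_p: list[float] = []
    n_retained = 0
    if n_perm > 0 and n_axes > 0:
        # permutation null eigenvalues: free row permutation of the response
        perm_eigs = np.empty((n_perm, n_axes))
        q, _ = np.linalg.qr(x)
        for bcount in range(n_perm):
            yp = y[rng.permutation(n)]
            proj = q.T @ yp
            sv = np.linalg.svd(proj, compute_uv=False)
            ev = np.zeros(n_axes)
            ev[: min(n_axes, len(sv))] = (sv**2)[:n_axes]
            perm_eigs[bcount] = ev
        for a in range(n_axes):
            f_obs = eig[a] / (ss_res / dof_res)
            # residual SS under permutation differs; compare eigenvalue F-ratios
            ssr_perm = float((y**2).sum()) - perm_eigs.sum(axis=1)
            f_perm = perm_eigs[:, a] / (ssr_perm / dof_res)
            p = (1.0 + np.sum(f_perm >= f_obs)) / (n_perm + 1.0)
            axis_p.append(float(p))
            if p < alpha_axis:
                n_retained += 1
            else:
                break
    else:
        n_retained = n_axes
    if n_retained == 0:
        logger.warning("rda_fit: no significant axes retained")
    cols = [f"{'pRDA' if cov_name else 'RDA'}{a + 1}" for a in range(max(n_retained, 1))]
    site_scores = pd.DataFrame(uu[:, :n_retained] * ss[:n_retained], index=sites,
                               columns=cols[:n_retained])
    loadings = pd.DataFrame(vvt[:n_retained].T, index=freq.snp_ids,
                            columns=cols[:n_retained])
    return RdaModel(list(env.columns), site_scores, loadings, r2, adj,
                    axis_p, n_retained, cov_name, eig[:n_axes])


def vif_prune(env: pd.DataFrame, vif_max: float = 10.0) -> list[str]:
    """Iteratively remove the variable with the highest variance inflation
    factor until all VIF < ``vif_max`` (ties: remove the later column)."""
    if env.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    cols = list(env.columns)
    x = env.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    live = list(range(len(cols)))
    while len(live) >= 2:
        vifs = []
        for j in live:
            others = [c for c in live if c != j]
            xo = np.column_stack([np.ones(len(x)), x[:, others]])
            beta, res, *_ = np.linalg.lstsq(xo, x[:, j], rcond=None)
            ss_res = float(((x[:, j] - xo @ beta) ** 2).sum())
            ss_tot = float((x[:, j] ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        worst = max(vifs)
        if worst < vif_max:
            break
        # ties -> later column: scan from the end
        drop_pos = len(vifs) - 1 - int(np.argmax(np.isclose(vifs[::-1], worst)))
        removed = live.pop(drop_pos)
        logger.info("vif_prune: removed %s (VIF=%.2f)", cols[removed], worst)
    return [cols[j] for j in live]


def backward_select(freq: SnpTable, env: pd.DataFrame,
                    covariate: pd.Series | None = None, p_stay: float = 0.1,
                    n_perm: int = 199, seed: int | None = None) -> list[str]:
    """Backward elimination of predictors by drop-one marginal pseudo-F
    permutation tests: while the least useful predictor has p >= ``p_stay``
    (and more than one predictor remains), remove it."""
    rng = np.random.default_rng(seed)
    sites = freq.pops
    y = freq.freq.to_numpy(dtype=float).T
    y = y - y.mean(axis=0)
    env = env.loc[sites]
    xall = env.to_numpy(dtype=float)
    xall = (xall - xall.mean(axis=0)) / np.where(xall.std(axis=0) > 0, xall.std(axis=0), 1.0)
    if covariate is not None:
        c = covariate.loc[sites].to_numpy(dtype=float)
        y = _residual_on(y, c)
        xall = _residual_on(xall, c)
    n = len(sites)
    cols = list(env.columns)
    live = list(range(len(cols)))
    while len(live) > 1:
        ss_tot = float((y**2).sum())
        r2_full, _ = _fit_r2(y, xall[:, live])
        dof = max(n - len(live) - 1, 1)
        ps = []
        for j in live:
            others = [c2 for c2 in live if c2 != j]
            r2_red, yfit_red = _fit_r2(y, xall[:, others])
            gain_obs = (r2_full - r2_red) * ss_tot
            f_obs = gain_obs / ((1 - r2_full) * ss_tot / dof)
            count = 0
            resid = y - yfit_red
            for _ in range(n_perm):
                yp = yfit_red + resid[rng.permutation(n)]
                yp = yp - yp.mean(axis=0)
                stp = float((yp**2).sum())
                r2f, _ = _fit_r2(yp, xall[:, live])
                r2r, _ = _fit_r2(yp, xall[:, others])
                f_p = (r2f - r2r) * stp / ((1 - r2f) * stp / dof)
                if f_p >= f_obs:
                    count += 1
            ps.append((1.0 + count) / (n_perm + 1.0))
        worst = max(ps)
        if worst < p_stay:
            break
        drop_pos = len(ps) - 1 - int(np.argmax(np.isclose(ps[::-1], worst)))
        removed = live.pop(drop_pos)
        logger.info("backward_select: removed %s (p=%.3f)", cols[removed], worst)
    return [cols[j] for j in live]


def variance_partition(freq: SnpTable, sets: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Three-set variance partitioning of adjusted R^2 by inclusion-exclusion.

    ``sets`` maps three set names to predictor tables (sites x variables).
    Returns unique fractions, pairwise joints, the three-way joint, the full
    adjusted R^2 and the residual; the seven signed components sum to the
    full-model adjusted R^2 by construction (asserted within 1e-10).
    """
    if len(sets) != 3:
        raise ValueError("variance_partition needs exactly 3 predictor sets")
    names = list(sets)
    for k, v in sets.items():
        if v.shape[1] == 0:
            raise ValueError(f"predictor set {k!r} is empty")

    def adj(of: list[str]) -> float:
        x = pd.concat([sets[k] for k in of], axis=1)
        model = rda_fit(freq, x, n_perm=0)
        return model.adj_r2

    a_, b_, c_ = names
    r = {
        "A": adj([a_]), "B": adj([b_]), "C": adj([c_]),
        "AB": adj([a_, b_]), "AC": adj([a_, c_]), "BC": adj([b_, c_]),
        "ABC": adj([a_, b_, c_]),
    }
    ua = r["ABC"] - r["BC"]
    ub = r["ABC"] - r["AC"]
    uc = r["ABC"] - r["AB"]
    jab = r["ABC"] - ua - ub - r["C"]
    jbc = r["ABC"] - ub - uc - r["A"]
    jac = r["ABC"] - ua - uc - r["B"]
    jabc = r["ABC"] - ua - ub - uc - jab - jbc - jac
    out = {
        f"unique_{a_}": ua, f"unique_{b_}": ub, f"unique_{c_}": uc,
        f"joint_{a_}_{b_}": jab, f"joint_{b_}_{c_}": jbc, f"joint_{a_}_{c_}": jac,
        f"joint_{a_}_{b_}_{c_}": jabc,
        "full_adj_r2": r["ABC"],
        "residual": 1.0 - r["ABC"],
    }
    total = ua + ub + uc + jab + jbc + jac + jabc
    assert abs(total - r["ABC"]) < 1e-10, "variance partition identity violated"
    return out


def univariate_gea(freq: SnpTable, env: pd.DataFrame) -> list[ScanStats]:
    """|Spearman| correlation of each SNP's population frequencies with each
    environmental variable across sites. A univariate association stand-in,
    tagged ``bf_analog:<variable>``."""
    sites = freq.pops
    if len(sites) < 4:
        raise ValueError("univariate GEA needs >= 4 sites")
    env = env.loc[sites]
    f = freq.freq.to_numpy(dtype=float)  # L x P
    fr = stats.rankdata(f, axis=1)
    fr = (fr - fr.mean(axis=1, keepdims=True))
    fnorm = np.maximum(np.linalg.norm(fr, axis=1), 1e-300)
    out = []
    for var in env.columns:
        v = env[var].to_numpy(dtype=float)
        if np.std(v) == 0:
            logger.warning("univariate_gea: variable %s constant, skipped", var)
            vals = pd.Series(np.nan, index=freq.snp_ids)
        else:
            vr = stats.rankdata(v)
            vr = vr - vr.mean()
            rho = (fr @ vr) / (fnorm * np.linalg.norm(vr))
            vals = pd.Series(np.abs(rho), index=freq.snp_ids)
        out.append(ScanStats("bf_analog", var, vals, "higher_more_extreme"))
    return out


def write_baypass_counts(freq: SnpTable, path) -> None:
    """Write a genotype-count matrix: per SNP per population the pair
    (minor count, major count) = (round(p n), round((1-p) n)), rounding
    half-to-even, space-delimited, one SNP per line. The two counts may
    differ from n by at most 1 because each is rounded independently."""
    p = freq.freq.to_numpy(dtype=float)
    n = freq.n.to_numpy(dtype=float)
    minor = np.round(p * n).astype(int)
    major = np.round((1 - p) * n).astype(int)
    with open(path, "w") as fh:
        for row_minor, row_major in zip(minor, major):
            fields = []
            for a, b in zip(row_minor, row_major):
                fields += [str(a), str(b)]
            fh.write(" ".join(fields) + "\n")
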