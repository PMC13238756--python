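"""Mantel machinery and the residual-substitution decomposition of
isolation-by-distance (IBD), isolation-by-environment (IBE) and
isolation-by-colonization (IBC).

The decomposition regresses genetic distance on ancestry distance plus a
categorical term for the population-pair category (north-north, south-south,
north-south, by each site's position on the ancestry cline), then substitutes
the residuals for genetic distance in partial Mantel tests against marine or
environmental distance. All Mantel tests are one-sided (positive
association) with the (1 + b) / (1 + B) permutation p-value convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DistMatrix

__all__ = ["mantel", "partial_mantel", "pair_categories", "residualize_genetic",
           "ibe_by_variable"]


def _tril_vectors(*mats: DistMatrix) -> tuple[list[str], list[np.ndarray]]:
    labels = mats[0].labels
    for m in mats[1:]:
        if set(m.labels) != set(labels):
            raise ValueError("distance matrices must share labels")
    return labels, [m.reorder(labels).condensed() for m in mats]


def _check_var(v: np.ndarray, what: str) -> None:
    if np.std(v) == 0:
        raise ValueError(f"zero-variance lower triangle in {what}: Mantel r undefined")


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Row/column permutations of an n x n matrix expressed as index arrays
    into the condensed lower triangle."""
    il, jl = np.tril_indices(n, k=-1)
    flat = np.full((n, n), -1, dtype=int)
    flat[il, jl] = np.arange(len(il))
    flat[jl, il] = flat[il, jl]
    out = np.empty((n_perm, len(il)), dtype=int)
    for b in range(n_perm):
        p = rng.permutation(n)
        out[b] = flat[p[il], p[jl]]
    return out


def mantel(x: DistMatrix, y: DistMatrix, n_perm: int = 999,
           seed: int | None = None) -> tuple[float, float]:
    """Simple Mantel test: Pearson r of the vectorized lower triangles,
    one-sided p from joint row/column permutations of ``x``."""
    labels, (vx, vy) = _tril_vectors(x, y)
    if len(labels) < 4:
        raise ValueError("Mantel test needs >= 4 labels")
    _check_var(vx, f"x ({x.kind})")
    _check_var(vy, f"y ({y.kind})")
    r_obs = float(np.corrcoef(vx, vy)[0, 1])
    rng = np.random.default_rng(seed)
    idx = _perm_indices(len(labels), n_perm, rng)
    xp = vx[idx]  # n_perm x n_pairs
    xp = xp - xp.mean(axis=1, keepdims=True)
    yc = vy - vy.mean()
    r_perm = (xp @ yc) / (np.linalg.norm(xp, axis=1) * np.linalg.norm(yc))
    p = (1.0 + np.sum(r_perm >= r_obs)) / (n_perm + 1.0)
    return r_obs, float(p)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, z] by least squares."""
    x = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_mantel(x: DistMatrix, y: DistMatrix, z: DistMatrix,
                   n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Partial Mantel: Pearson r of the residuals of x and y after each is
    regressed on z (lower triangles); permutations act on x's label order and
    the residual correlation is recomputed per permutation."""
    labels, (vx, vy, vz) = _tril_vectors(x, y, z)
    if len(labels) < 5:
        raise ValueError("partial Mantel needs >= 5 labels")
    _check_var(vx, f"x ({x.kind})")
    _check_var(vy, f"y ({y.kind})")
    ry = _residualize(vy, vz)
    rx = _residualize(vx, vz)
    # fully explained by the covariate: residuals are numerical zero and the
    # partial correlation is defined as 0
    tol_y = 1e-10 * max(np.abs(vy).max(), 1.0)
    tol_x = 1e-10 * max(np.abs(vx).max(), 1.0)
    if np.abs(ry).max() < tol_y or np.abs(rx).max() < tol_x:
        return 0.0, 1.0
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    idx = _perm_indices(len(labels), n_perm, rng)
    zdes = np.column_stack([np.ones_like(vz), vz])
    # hat-complement projector is shared by all permutations of x
    q, _ = np.linalg.qr(zdes)
    xp = vx[idx]
    rxp = xp - (xp @ q) @ q.T
    rxp = rxp - rxp.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    r_perm = (rxp @ ryc) / (np.linalg.norm(rxp, axis=1) * np.linalg.norm(ryc))
    p = (1.0 + np.sum(r_perm >= r_obs)) / (n_perm + 1.0)
    return r_obs, float(p)


def pair_categories(sites: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered site pair with its category
    (north-north / south-south / north-south) from the sites' group flags."""
    if "group" not in sites.columns:
        raise ValueError("sites table needs a 'group' column (north/south)")
    ids = list(sites["site_id"] if "site_id" in sites.columns else sites.index)
    grp = dict(zip(ids, sites["group"]))
    rows = []
    for i in range(len(ids)):
        for j in range(i):  # (i > j) matches DistMatrix.condensed order
            a, b = ids[i], ids[j]
            cats = sorted([grp[a], grp[b]])
            cat = f"{cats[0]}-{cats[1]}" if cats[0] != cats[1] else f"{cats[0]}-{cats[0]}"
            rows.append((a, b, cat))
    return pd.DataFrame(rows, columns=["site_a", "site_b", "category"])


def residualize_genetic(genetic: DistMatrix, ancestry: DistMatrix,
                        sites: pd.DataFrame, interaction: bool = False) -> DistMatrix:
    """OLS of genetic distance on ancestry distance with a per-category
    intercept (optionally an ancestry x category interaction); residuals are
    refolded into a symmetric matrix of kind ``residual`` with a zero,
    ignored, diagonal."""
    labels, (vg, va) = _tril_vectors(genetic, ancestry)
    cats = pair_categories(sites.loc[labels])["category"].to_numpy()
    levels = sorted(set(cats))
    dummies = np.column_stack([(cats == c).astype(float) for c in levels])
    cols = [dummies]
    if interaction:
        cols.append(dummies * va[:, None])
    else:
        cols.append(va[:, None])
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design for the residual model "
            f"(rank {rank} < {design.shape[1]} columns); check that ancestry "
            "distance varies within categories"
        )
    beta, *_ = np.linalg.lstsq(design, vg, rcond=None)
    resid = vg - design @ beta
    return DistMatrix.from_condensed(labels, resid, "residual")


def ibe_by_variable(residual: DistMatrix, env: pd.DataFrame, marine: DistMatrix,
                    sites: pd.DataFrame, subset: str = "all",
                    n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Per-environmental-variable IBE: partial Mantel of the residual genetic
    distance against |v_i - v_j| with marine distance as covariate, on all
    sites or the north/south subset. Zero-variance variables are reported
    with NaN rather than aborting the table."""
    if subset not in ("all", "north", "south"):
        raise ValueError("subset must be all, north or south")
    ids = list(sites["site_id"] if "site_id" in sites.columns else sites.index)
    if subset != "all":
        ids = [s for s in ids if sites.loc[s, "group"] == subset]
    if len(ids) < 4:
        raise ValueError(f"subset {subset!r} has {len(ids)} sites; need >= 4")
    res = residual.reorder(ids)
    mar = marine.reorder(ids)
    rows = []
    for var in env.columns:
        v = env.loc[ids, var].to_numpy(dtype=float)
        d = np.abs(v[:, None] - v[None, :])
        dmat = DistMatrix(pd.DataFrame(d, index=ids, columns=ids), "environmental")
        try:
            r, p = partial_mantel(res, dmat, mar, n_perm=n_perm, seed=seed)
        except ValueError:
            r, p = np.nan, np.nan
        rows.append((var, subset, r, p, n_perm))
    return pd.DataFrame(rows, columns=["variable", "subset", "r", "p", "n_perm"])
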