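"""Genome scans, RDA/pRDA, variance partitioning and GEA statistics."""

import numpy as np
import pandas as pd
import pytest

from cudelim.containers import GenotypeTable
from cudelim.scans_gea import (backward_select, ogk_covariance, pcadapt_scan,
                               rda_fit, univariate_gea, variance_partition,
                               vif_prune, write_baypass_counts)

from conftest import make_snp_table


def _gt(arr, chrom="chr1"):
    arr = np.asarray(arr, dtype=float)
    cols = pd.Index([f"s{i}" for i in range(arr.shape[1])], name="snp_id")
    meta = pd.DataFrame({"chrom": chrom, "pos": (np.arange(arr.shape[1]) + 1) * 50},
                        index=cols)
    inds = [f"i{j}" for j in range(arr.shape[0])]
    return GenotypeTable(pd.DataFrame(arr, index=inds, columns=cols),
                         pd.DataFrame({"pop": "X"}, index=inds), meta)


class TestOgk:
    def test_matches_sample_covariance_on_clean_gaussian(self):
        rng = np.random.default_rng(0)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        z = rng.multivariate_normal([1.0, -2.0], cov, size=20000)
        loc, scat = ogk_covariance(z)
        assert np.allclose(loc, [1.0, -2.0], atol=0.1)
        assert np.allclose(scat, cov, rtol=0.15)

    def test_resists_gross_outliers(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((5000, 2))
        z[:100] += 50.0  # 2% contamination
        _, scat = ogk_covariance(z)
        assert np.all(np.diag(scat) < 2.0)  # classical covariance would be ~26


class TestPcadapt:
    def test_planted_outlier_attains_minimum_p(self):
        """Against a background of mild two-population drift, a near-fixed
        difference SNP is the top hit."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, L, f_bg = 120, 400, 0.02
            x = rng.uniform(0.2, 0.8, L)
            c = (1 - f_bg) / f_bg
            pa = rng.beta(x * c, (1 - x) * c)
            pb = rng.beta(x * c, (1 - x) * c)
            pa[0], pb[0] = 0.02, 0.98  # planted strong differentiation
            grp = np.repeat([0, 1], n // 2)
            p_ind = np.where(grp[:, None] == 0, pa[None, :], pb[None, :])
            g = rng.binomial(2, p_ind).astype(float)
            sc = pcadapt_scan(_gt(g), k=2, maf_min=0.01)
            if sc.values.idxmin() == "s0":
                hits += 1
        assert hits >= 19

    def test_duplicated_individual_preserves_ranking(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(80, 200)).astype(float)
        s1 = pcadapt_scan(_gt(g), k=2)
        s2 = pcadapt_scan(_gt(np.vstack([g, g])), k=2)
        r1 = s1.values.rank()
        r2 = s2.values.rank()
        assert np.corrcoef(r1, r2)[0, 1] > 0.99

    def test_k_too_large_errors(self):
        g = np.random.default_rng(3).binomial(2, 0.5, size=(10, 50)).astype(float)
        with pytest.raises(ValueError, match="k"):
            pcadapt_scan(_gt(g), k=10)


class TestVif:
    def test_orthogonal_variables_untouched(self):
        q, _ = np.linalg.qr(np.random.default_rng(20).standard_normal((20, 4)))
        env = pd.DataFrame(q, columns=list("abcd"))
        assert vif_prune(env) == list("abcd")

    def test_duplicate_column_one_removed(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(20)
        env = pd.DataFrame({"a": v, "b": v, "c": rng.standard_normal(20)})
        kept = vif_prune(env)
        assert len(kept) == 2 and "c" in kept

    def test_constructed_collinearity_resolved(self):
        rng = np.random.default_rng(5)
        v1, v2 = rng.standard_normal(30), rng.standard_normal(30)
        env = pd.DataFrame({"v1": v1, "v2": v2,
                            "v3": v1 + v2 + rng.normal(0, 0.01, 30)})
        kept = vif_prune(env, vif_max=10)
        assert len(kept) == 2
        # remaining VIFs all under the ceiling: re-running removes nothing
        assert vif_prune(env[kept], vif_max=10) == kept


class TestRda:
    @staticmethod
    def _random_snp(rng, n_sites=20, n_snps=120):
        return make_snp_table(rng.uniform(0.05, 0.95, size=(n_snps, n_sites)), 40)

    def test_exact_linear_response_r2_one(self):
        rng = np.random.default_rng(6)
        n, m, L = 12, 3, 30
        x = rng.standard_normal((n, m))
        b = rng.standard_normal((m, L))
        y = x @ b
        y = (y - y.min()) / (y.max() - y.min()) * 0.9 + 0.05
        # make the response exactly linear in x after centering
        snp = make_snp_table(y.T, 40, pops=[f"P{j + 1}" for j in range(n)])
        env = pd.DataFrame(x, index=snp.pops, columns=[f"e{j}" for j in range(m)])
        mod = rda_fit(snp, env, n_perm=0)
        assert mod.r2 == pytest.approx(1.0, abs=1e-9)
        assert mod.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_fitted_values_match_per_column_regression(self):
        """RDA fitted values equal brute-force per-SNP OLS on the predictors."""
        rng = np.random.default_rng(7)
        snp = self._random_snp(rng, n_sites=10, n_snps=50)
        env = pd.DataFrame(rng.standard_normal((10, 3)), index=snp.pops,
                           columns=list("abc"))
        mod = rda_fit(snp, env, n_perm=0)
        y = snp.freq.to_numpy().T
        y = y - y.mean(axis=0)
        x = env.to_numpy()
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        xd = np.column_stack([np.ones(10), x])
        yfit = np.column_stack([xd @ np.linalg.lstsq(xd, y[:, j], rcond=None)[0]
                                for j in range(y.shape[1])])
        ss_fit = (yfit**2).sum()
        assert mod.r2 * (y**2).sum() == pytest.approx(ss_fit, rel=1e-9)
        # reconstruction through retained axes spans the same fitted space
        recon = mod.site_scores.to_numpy() @ mod.loadings.to_numpy().T
        assert np.abs(recon - yfit).max() < 1e-9 or mod.n_retained < len(mod.axis_p)

    def test_constant_covariate_equals_plain_rda(self):
        rng = np.random.default_rng(8)
        snp = self._random_snp(rng)
        env = pd.DataFrame(rng.standard_normal((20, 3)), index=snp.pops,
                           columns=list("abc"))
        const = pd.Series(2.5, index=snp.pops, name="const")
        m1 = rda_fit(snp, env, n_perm=0)
        m2 = rda_fit(snp, env, covariate=const, n_perm=0)
        assert m2.r2 == pytest.approx(m1.r2, abs=1e-9)
        for a in range(min(3, m1.loadings.shape[1], m2.loadings.shape[1])):
            l1 = m1.loadings.iloc[:, a].to_numpy()
            l2 = m2.loadings.iloc[:, a].to_numpy()
            assert min(np.abs(l1 - l2).max(), np.abs(l1 + l2).max()) < 1e-9

    def test_null_adjusted_r2_centers_on_zero(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            snp = make_snp_table(rng.uniform(0.05, 0.95, (100, 30)), 40)
            env = pd.DataFrame(rng.standard_normal((30, 5)), index=snp.pops,
                               columns=list("abcde"))
            vals.append(rda_fit(snp, env, n_perm=0).adj_r2)
        assert abs(np.mean(vals)) < 0.05

    def test_saturated_model_errors(self):
        rng = np.random.default_rng(9)
        snp = self._random_snp(rng, n_sites=5, n_snps=20)
        env = pd.DataFrame(rng.standard_normal((5, 6)), index=snp.pops)
        env.columns = [f"e{j}" for j in range(6)]
        with pytest.raises(ValueError, match="saturated"):
            rda_fit(snp, env, n_perm=0)


class TestBackwardSelect:
    def test_true_predictor_retained(self):
        kept_true = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, L = 25, 80
            driver = rng.standard_normal(n)
            y = np.outer(driver, rng.standard_normal(L)) + rng.normal(0, 0.6, (n, L))
            f = 1 / (1 + np.exp(-y / 2))
            snp = make_snp_table(f.T, 40, pops=[f"P{j + 1}" for j in range(n)])
            env = pd.DataFrame(rng.standard_normal((n, 5)), index=snp.pops,
                               columns=[f"noise{j}" for j in range(4)] + ["driver"])
            env["driver"] = driver
            kept = backward_select(snp, env, p_stay=0.1, n_perm=99, seed=seed)
            if "driver" in kept:
                kept_true += 1
        assert kept_true >= 18

    def test_same_seed_same_selection(self):
        rng = np.random.default_rng(10)
        snp = make_snp_table(rng.uniform(0.2, 0.8, (60, 15)), 40)
        env = pd.DataFrame(rng.standard_normal((15, 4)), index=snp.pops,
                           columns=list("abcd"))
        k1 = backward_select(snp, env, n_perm=49, seed=3)
        k2 = backward_select(snp, env, n_perm=49, seed=3)
        assert k1 == k2


class TestVariancePartition:
    @staticmethod
    def _freq_env(rng, n=25, L=80):
        snp = make_snp_table(rng.uniform(0.05, 0.95, (L, n)), 40)
        return snp

    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(11)
        snp = self._freq_env(rng)
        sets = {"A": pd.DataFrame(rng.standard_normal((25, 3)), index=snp.pops),
                "B": pd.DataFrame(rng.standard_normal((25, 2)), index=snp.pops),
                "C": pd.DataFrame(rng.standard_normal((25, 2)), index=snp.pops)}
        for s in sets.values():
            s.columns = [f"{id(s)}_{j}" for j in range(s.shape[1])]
        out = variance_partition(snp, sets)
        total = sum(v for k, v in out.items()
                    if k.startswith("unique_") or k.startswith("joint_"))
        assert total == pytest.approx(out["full_adj_r2"], abs=1e-10)

    def test_duplicated_sets_share_all_variance(self):
        rng = np.random.default_rng(12)
        n, L = 25, 120
        driver = rng.standard_normal((n, 2))
        y = driver @ rng.standard_normal((2, L)) + rng.normal(0, 0.4, (n, L))
        f = 1 / (1 + np.exp(-y / 2))
        snp = make_snp_table(f.T, 40, pops=[f"P{j + 1}" for j in range(n)])
        a = pd.DataFrame(driver, index=snp.pops, columns=["d1", "d2"])
        b = a.copy()
        b.columns = ["e1", "e2"]
        c = pd.DataFrame(rng.standard_normal((n, 2)), index=snp.pops,
                         columns=["n1", "n2"])
        out = variance_partition(snp, {"A": a, "B": b, "C": c})
        assert abs(out["unique_A"]) < 0.02 and abs(out["unique_B"]) < 0.02
        assert out["joint_A_B"] > 0.2

    def test_noise_sets_leave_unique_fraction(self):
        rng = np.random.default_rng(13)
        n, L = 40, 120
        driver = rng.standard_normal((n, 2))
        y = driver @ rng.standard_normal((2, L)) + rng.normal(0, 0.4, (n, L))
        f = 1 / (1 + np.exp(-y / 2))
        snp = make_snp_table(f.T, 40, pops=[f"P{j + 1}" for j in range(n)])
        a = pd.DataFrame(driver, index=snp.pops, columns=["d1", "d2"])
        b = pd.DataFrame(rng.standard_normal((n, 2)), index=snp.pops,
                         columns=["x1", "x2"])
        c = pd.DataFrame(rng.standard_normal((n, 2)), index=snp.pops,
                         columns=["y1", "y2"])
        out = variance_partition(snp, {"A": a, "B": b, "C": c})
        ra = rda_fit(snp, a, n_perm=0).adj_r2
        # noise sets absorb a little residual variance, so the match is
        # approximate: unique_A within 0.1 of the A-only adjusted R^2
        assert out["unique_A"] == pytest.approx(ra, abs=0.1)
        assert abs(out["unique_B"]) < 0.05 and abs(out["unique_C"]) < 0.05


class TestUnivariateGea:
    def test_rank_identical_variable_scores_one(self):
        n = 8
        v = np.arange(n, dtype=float)
        f = np.tile((v + 1) / (n + 2), (5, 1))
        f[2] = f[2][::-1]  # perfectly anti-correlated SNP
        snp = make_snp_table(f, 40, pops=[f"P{j + 1}" for j in range(n)])
        env = pd.DataFrame({"v": v}, index=snp.pops)
        env["w"] = np.random.default_rng(14).standard_normal(n)
        (sv, _) = univariate_gea(snp, env)[:2]
        assert sv.values.iloc[0] == pytest.approx(1.0)
        assert sv.values.iloc[2] == pytest.approx(1.0)  # |rho| folds the sign

    def test_joint_site_permutation_invariance(self):
        rng = np.random.default_rng(15)
        snp = make_snp_table(rng.uniform(0.1, 0.9, (30, 10)), 40)
        env = pd.DataFrame(rng.standard_normal((10, 3)), index=snp.pops,
                           columns=list("abc"))
        s1 = univariate_gea(snp, env)[0]
        perm = list(np.array(snp.pops)[rng.permutation(10)])
        snp2 = make_snp_table(snp.freq[perm].to_numpy(), 40, pops=perm)
        s2 = univariate_gea(snp2, env.loc[perm])[0]
        assert np.allclose(s1.values.to_numpy(), s2.values.to_numpy(), atol=1e-12)


class TestBaypassCounts:
    def test_rounding_examples(self, tmp_path):
        freq = np.array([[0.5, 0.26], [0.0, 1.0]])
        n = np.array([[10, 7], [5, 4]])
        snp = make_snp_table(freq, n)
        path = tmp_path / "counts.txt"
        write_baypass_counts(snp, path)
        lines = path.read_text().strip().split("\n")
        # p=0.5, n=10 -> (5, 5); p=0.26, n=7 -> (2, 5) by round-half-even
        assert lines[0].split() == ["5", "5", "2", "5"]
        # p=0 -> (0, n); p=1 -> (n, 0)
        assert lines[1].split() == ["0", "5", "4", "0"]
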