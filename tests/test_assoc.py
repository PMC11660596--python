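import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

import statsmodels.api as sm

from ailhap._mixed import KinshipEigen, fit_variance_components
from ailhap.assoc import block_lrt, fdr_and_regions, haplotype_gwas, marker_scan, reml_fit
from ailhap.blocks import build_blocks
from ailhap.relmat import gamma_to_h, haplotype_gamma

from conftest import make_genotypes, make_variants


def random_kinship(n, m, rng):
    """GRM-like PSD matrix from random standardized dosages."""
    p = rng.uniform(0.1, 0.9, size=m)
    x = rng.binomial(2, p, size=(n, m)).astype(float)
    keep = x.std(axis=0) > 0
    z = (x[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    return z @ z.T / keep.sum(), x


def polygenic_y(q, alpha, k, sg2, se2, rng):
    n = k.shape[0]
    cov = sg2 * k + se2 * np.eye(n)
    l = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    return q @ alpha + l @ rng.standard_normal(n)


class TestRemlFit:
    def test_identity_kinship_reduces_to_ols(self):
        """With K = I the whitened marker test must equal plain OLS."""
        rng = np.random.default_rng(0)
        n = 80
        q = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = q @ [2.0, 1.0] + rng.standard_normal(n)
        dosages = rng.integers(0, 3, size=(30, n)).astype(float)
        table = marker_scan(y, q, np.eye(n), dosages)
        for j in range(30):
            ols = sm.OLS(y, np.column_stack([q, dosages[j]])).fit()
            assert table["p"].iloc[j] == pytest.approx(ols.pvalues[-1], abs=1e-6)
            assert table["beta"].iloc[j] == pytest.approx(ols.params[-1], abs=1e-8)

    def test_variance_component_recovery(self):
        """Mean REML estimates over seeds within 3 standard errors of truth."""
        rng = np.random.default_rng(1)
        n, n_rep = 200, 30
        k, _ = random_kinship(n, 400, rng)
        eig = KinshipEigen.from_kinship(k)
        q = np.ones((n, 1))
        sg_hat, se_hat = [], []
        for _ in range(n_rep):
            y = polygenic_y(q, np.array([5.0]), k, 1.0, 1.0, rng)
            fit = fit_variance_components(y, q, eig)
            sg_hat.append(fit.sigma_g2)
            se_hat.append(fit.sigma_e2)
        for est, truth in ((sg_hat, 1.0), (se_hat, 1.0)):
            mean = np.mean(est)
            sem = np.std(est, ddof=1) / np.sqrt(n_rep)
            assert abs(mean - truth) < 3 * sem + 0.05

    def test_constant_phenotype_rejected(self):
        n = 30
        with pytest.raises(ValueError, match="zero variance"):
            reml_fit(np.full(n, 3.0), np.ones((n, 1)), np.eye(n))


class TestMarkerScan:
    def test_planted_effect_is_genome_minimum(self):
        rng = np.random.default_rng(2)
        n, m = 300, 200
        k, x = random_kinship(n, m, rng)
        q = np.ones((n, 1))
        causal = 77
        y = polygenic_y(q, np.array([0.0]), k, 0.3, 1.0, rng) + 1.2 * x[:, causal]
        table = marker_scan(y, q, k, x.T)
        assert int(np.nanargmin(table["p"].to_numpy())) == causal

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        n, m = 200, 500
        k, x = random_kinship(n, m, rng)
        q = np.ones((n, 1))
        y = polygenic_y(q, np.array([0.0]), k, 0.5, 1.0, rng)
        y = rng.permutation(y)  # break any marker-phenotype link
        table = marker_scan(y, q, k, x.T)
        p = table["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monomorphic_marker_gets_na_row(self):
        rng = np.random.default_rng(4)
        n = 50
        dos = rng.integers(0, 3, size=(3, n)).astype(float)
        dos[1] = 2.0
        table = marker_scan(rng.standard_normal(n), np.ones((n, 1)), np.eye(n), dos)
        assert np.isnan(table["p"].iloc[1])
        assert np.isfinite(table["p"].iloc[0])

    def test_invalid_dosage_rejected(self):
        n = 20
        with pytest.raises(ValueError, match="0, 1, 2"):
            marker_scan(np.random.default_rng(0).standard_normal(n), np.ones((n, 1)), np.eye(n), np.full((1, n), 3.0))


def _direct_ml_loglik(y, x, k):
    """Independent ML oracle: joint optimization of (log σ²_g, log σ²_e)."""
    n = len(y)

    def nll(theta):
        sg2, se2 = np.exp(theta)
        v = sg2 * k + se2 * np.eye(n)
        try:
            l = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return 1e10
        vi_y = np.linalg.solve(v, y)
        vi_x = np.linalg.solve(v, x)
        beta = np.linalg.solve(x.T @ vi_x, x.T @ vi_y)
        r = y - x @ beta
        vi_r = np.linalg.solve(v, r)
        logdet = 2 * np.sum(np.log(np.diag(l)))
        return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ vi_r)

    best = np.inf
    for start in ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0], [-3.0, 0.0]):
        res = minimize(nll, start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return -best


class TestBlockLrt:
    def _toy(self, seed=5, n=40):
        rng = np.random.default_rng(seed)
        vt = make_variants(4)
        haps = rng.integers(0, 2, size=(2 * n, 4))
        pg = make_genotypes(haps.tolist())
        hbs = build_blocks(vt, pg, block_size=2)
        h = gamma_to_h(haplotype_gamma(hbs)).values
        q = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        y = polygenic_y(q, np.array([10.0, 1.0]), h, 0.5, 1.0, rng)
        return y, q, h, hbs

    def test_single_combination_level_untestable(self):
        vt = make_variants(2)
        pg = make_genotypes([[0, 1], [0, 1]] * 20)
        hbs = build_blocks(vt, pg, block_size=2)
        n = 20
        rng = np.random.default_rng(0)
        y = rng.standard_normal(n)
        lrt, dof, p = block_lrt(y, np.ones((n, 1)), np.eye(n), hbs, 0)
        assert np.isnan(lrt) and dof == 0 and np.isnan(p)

    def test_lrt_nonnegative_across_blocks(self, small_sim):
        hbs = small_sim.hbs
        h = gamma_to_h(haplotype_gamma(hbs))
        pt = small_sim.phenotypes
        table = haplotype_gwas(pt.trait, pt.covariate_design(), h, hbs, min_count=5)
        tested = table[table["df"] > 0]
        assert len(tested) > 10
        assert (tested["stat"] >= 0).all()
        assert tested["p"].between(0, 1).all()

    def test_planted_combination_effect_detected(self):
        rng = np.random.default_rng(6)
        n = 300
        vt = make_variants(2)
        haps = rng.integers(0, 2, size=(2 * n, 2))
        pg = make_genotypes(haps.tolist())
        hbs = build_blocks(vt, pg, block_size=2)
        q = np.ones((n, 1))
        y = rng.standard_normal(n)
        # shift one haplotype combination by 3 residual SDs
        combo = [tuple(sorted(hbs.assignments[0, s])) for s in range(n)]
        target = pd.Series(combo).value_counts().index[1]
        y = y + 3.0 * np.array([c == target for c in combo])
        lrt, dof, p = block_lrt(y, q, np.eye(n), hbs, 0)
        assert p < 1e-6

    def test_ml_lrt_matches_direct_optimizer(self):
        """Profile-ML via eigendecomposition vs a joint 2-parameter optimizer."""
        y, q, h, hbs = self._toy()
        eig = KinshipEigen.from_kinship(h)
        null = fit_variance_components(y, q, eig, method="ml")
        from ailhap.assoc import _combination_design

        dummies, _ = _combination_design(hbs, 0, min_count=1)
        alt = fit_variance_components(y, np.column_stack([q, dummies]), eig, method="ml")
        lrt_pkg = 2 * (alt.loglik - null.loglik)
        ll_null = _direct_ml_loglik(y, q, h)
        ll_alt = _direct_ml_loglik(y, np.column_stack([q, dummies]), h)
        assert lrt_pkg == pytest.approx(2 * (ll_alt - ll_null), abs=1e-4)


class TestFdrAndRegions:
    def test_bh_by_hand(self):
        table = pd.DataFrame(
            {"chrom": ["c"] * 3, "block_id": [0, 5, 9], "p": [0.001, 0.5, 0.9]}
        )
        out, _ = fdr_and_regions(table)
        np.testing.assert_allclose(out["q"], [0.003, 0.75, 0.9])

    def test_all_p_one_nothing_significant(self):
        table = pd.DataFrame({"chrom": ["c"] * 4, "block_id": range(4), "p": [1.0] * 4})
        out, regions = fdr_and_regions(table)
        assert not out["significant"].any()
        assert regions.empty

    def test_contiguous_blocks_merge_into_one_region(self):
        ids = list(range(21, 34))  # contiguous run
        table = pd.DataFrame(
            {"chrom": ["GGA12"] * 13, "block_id": ids, "p": [1e-8] * 13}
        )
        out, regions = fdr_and_regions(table)
        assert len(regions) == 1
        assert regions["first"].iloc[0] == 21
        assert regions["last"].iloc[0] == 33
        assert regions["n_blocks"].iloc[0] == 13

    def test_gap_splits_regions(self):
        table = pd.DataFrame(
            {"chrom": ["c"] * 4, "block_id": [0, 1, 5, 6], "p": [1e-8] * 4}
        )
        _, regions = fdr_and_regions(table, gap=1)
        assert len(regions) == 2
        _, regions3 = fdr_and_regions(table, gap=4)
        assert len(regions3) == 1

    def test_na_pvalues_never_significant(self):
        table = pd.DataFrame({"chrom": ["c"] * 3, "block_id": [0, 1, 2], "p": [np.nan, 1e-9, 0.2]})
        out, _ = fdr_and_regions(table)
        assert not out["significant"].iloc[0]
        assert out["significant"].iloc[1]
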