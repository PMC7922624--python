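"""Mixed-model GWAS, conditional scans, meta-analysis, FDR and LD windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import svgblup as sg
from tests.conftest import grm_phenotype, hwe_genotypes


@pytest.fixture(scope="module")
def null_scan_setup():
    """Phenotype from a polygenic model plus a null fitted spec."""
    rng = np.random.default_rng(77)
    n = 400
    g1 = sg.build_grm(hwe_genotypes(rng, n, 600))
    y = grm_phenotype(rng, [g1], [0.5, 0.5], n)
    spec = sg.make_spec(y, [(g1, "snp")])
    vc = sg.reml_fit(spec)
    return rng, n, y, spec, vc


class TestMlmaScan:
    def test_effect_matches_ols_under_identity_v(self, rng):
        import statsmodels.api as sm

        n = 200
        y = rng.normal(size=n)
        marker = rng.binomial(2, 0.4, n).astype(float)
        spec = sg.make_spec(y, [(np.zeros((n, n)), "snp")])
        vc = sg.VarianceComponents(
            labels=["snp", "residual"],
            components={"snp": 0.0, "residual": 1.0},
            se={}, loglik=0.0, converged=True, n_iter=0,
        )
        tab = sg.mlma_scan(spec, marker[:, None], vc)
        ols = sm.OLS(y, sm.add_constant(marker)).fit()
        assert tab.b[0] == pytest.approx(ols.params[1], abs=1e-10)
        # with sigma_e fixed at the OLS residual variance the t match is exact
        vc.components["residual"] = float(ols.mse_resid)
        tab2 = sg.mlma_scan(spec, marker[:, None], vc)
        assert tab2.t[0] == pytest.approx(ols.tvalues[1], rel=1e-6)

    def test_marker_aliased_with_covariate_gives_na(self, rng):
        n = 100
        y = rng.normal(size=n)
        breed = rng.integers(0, 2, n).astype(float)
        spec = sg.make_spec(y, [(np.zeros((n, n)), "g")], covariates=breed)
        vc = sg.VarianceComponents(
            labels=["g", "residual"], components={"g": 0.0, "residual": 1.0},
            se={}, loglik=0.0, converged=True, n_iter=0,
        )
        tab = sg.mlma_scan(spec, (2.0 * breed)[:, None], vc)  # exact alias
        assert tab.note[0] == "aliased" and np.isnan(tab.p[0])

    def test_type_one_error_near_nominal(self, null_scan_setup):
        rng, n, y, spec, vc = null_scan_setup
        markers = rng.binomial(2, 0.3, (n, 300))
        tab = sg.mlma_scan(spec, markers, vc)
        assert 0.03 <= (tab.p < 0.05).mean() <= 0.07

    def test_monomorphic_marker_is_na(self, null_scan_setup):
        _, n, y, spec, vc = null_scan_setup
        tab = sg.mlma_scan(spec, np.zeros((n, 1)), vc)
        assert tab.note[0] == "monomorphic" and np.isnan(tab.p[0])

    def test_causal_sv_is_top_hit(self):
        # a single causal SV explaining 1% of phenotypic variance should top
        # the SV ranking in most replicates
        hits = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(900 + seed)
            n = 1000
            snp = hwe_genotypes(rng, n, 300)
            sv = hwe_genotypes(rng, n, 50)
            g1 = sg.build_grm(snp)
            causal = 7
            x = sv[:, causal] - sv[:, causal].mean()
            x = x / x.std()
            y = grm_phenotype(rng, [g1], [0.3, 0.69], n) + np.sqrt(0.01) * x
            spec = sg.make_spec(y, [(g1, "snp")])
            vc = sg.reml_fit(spec)
            tab = sg.mlma_scan(spec, sv, vc)
            if tab.p.idxmin() == causal:
                hits += 1
        assert hits >= 8


class TestConditionalScan:
    def test_perfect_ld_conditioning_aliases_marker(self, null_scan_setup):
        rng, n, y, spec, vc = null_scan_setup
        marker = rng.binomial(2, 0.4, n).astype(float)
        tab = sg.conditional_scan(spec, marker[:, None], vc, conditioning_dosage=marker)
        assert tab.note[0] == "aliased" and np.isnan(tab.p[0])

    def test_independent_conditioning_barely_moves_p(self, null_scan_setup):
        rng, n, y, spec, vc = null_scan_setup
        markers = rng.binomial(2, 0.4, (n, 200))
        cond = rng.binomial(2, 0.5, n).astype(float)
        p0 = sg.mlma_scan(spec, markers, vc).p.to_numpy()
        p1 = sg.conditional_scan(spec, markers, vc, conditioning_dosage=cond).p.to_numpy()
        assert np.median(np.abs(np.log10(p1) - np.log10(p0))) < 0.1

    def test_conditioning_on_perfect_tag_removes_signal(self):
        # mirrors the conditional analysis at a major known gene: once its
        # genotype is in the fixed design the linked variant loses significance
        rng = np.random.default_rng(5150)
        n = 2000
        snp = hwe_genotypes(rng, n, 200)
        g1 = sg.build_grm(snp)
        causal = rng.binomial(2, 0.4, n).astype(float)
        xc = (causal - causal.mean()) / causal.std()
        y = grm_phenotype(rng, [g1], [0.3, 0.65], n) + np.sqrt(0.05) * xc
        spec = sg.make_spec(y, [(g1, "snp")])
        vc = sg.reml_fit(spec)
        p_uncond = sg.mlma_scan(spec, causal[:, None], vc).p[0]
        tag = causal.copy()  # perfect tag of the causal variant
        p_cond = sg.conditional_scan(spec, causal[:, None], vc, conditioning_dosage=tag).p[0]
        assert p_uncond < 1e-8
        assert np.isnan(p_cond) or p_cond > 1e-3


def _fake_table(t, cohort, trait, ids=None):
    ids = ids if ids is not None else [f"m{i}" for i in range(len(t))]
    return pd.DataFrame({"id": ids, "t": t, "cohort": cohort, "trait": trait})


class TestTCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = rng.normal(size=100)
        V = sg.t_correlation([_fake_table(t, "bulls", "my"), _fake_table(t, "cows", "my")])
        assert np.allclose(V.to_numpy(), 1.0)

    def test_independent_traits_near_zero(self, rng):
        m = 4000
        V = sg.t_correlation(
            [_fake_table(rng.normal(size=m), "bulls", "a"), _fake_table(rng.normal(size=m), "bulls", "b")]
        )
        assert abs(V.iloc[0, 1]) < 3 / np.sqrt(m)

    def test_too_few_shared_markers_raises(self, rng):
        a = _fake_table(rng.normal(size=5), "bulls", "a")
        b = _fake_table(rng.normal(size=5), "cows", "a")
        with pytest.raises(ValueError, match="shared markers"):
            sg.t_correlation([a, b])


class TestMultiTraitChi2:
    def test_identity_v_reduces_to_sum_of_squares(self):
        res = sg.multi_trait_chi2(np.array([[1.0, 2, 3, 0, 0, 0]]), np.eye(6))
        assert res.table.chi2[0] == pytest.approx(14.0)
        assert res.df == 6

    def test_single_cohort_matches_normal_p(self):
        t = np.array([[1.7], [-2.3]])
        res = sg.multi_trait_chi2(t, np.eye(1))
        assert np.allclose(res.table.chi2, t.ravel() ** 2)
        assert np.allclose(res.table.p, 2 * stats.norm.sf(np.abs(t.ravel())))

    def test_null_mean_matches_df(self, rng):
        k, m = 6, 10000
        A = rng.normal(size=(k, k))
        V = A @ A.T
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
        T = rng.multivariate_normal(np.zeros(k), V, size=m)
        res = sg.multi_trait_chi2(T, V)
        assert res.table.chi2.mean() == pytest.approx(k, abs=0.2)

    def test_permutation_invariance(self, rng):
        k = 4
        T = rng.normal(size=(50, k))
        V = np.corrcoef(rng.normal(size=(k, 200)))
        perm = rng.permutation(k)
        a = sg.multi_trait_chi2(T, V).table.chi2
        b = sg.multi_trait_chi2(T[:, perm], V[np.ix_(perm, perm)]).table.chi2
        assert np.allclose(a, b)

    def test_missing_t_gives_na(self):
        T = np.array([[1.0, np.nan], [1.0, 1.0]])
        res = sg.multi_trait_chi2(T, np.eye(2))
        assert np.isnan(res.table.chi2[0]) and np.isfinite(res.table.chi2[1])

    def test_singular_v_uses_pseudoinverse(self):
        V = np.ones((3, 3))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            res = sg.multi_trait_chi2(np.array([[1.0, 1.0, 1.0]]), V)
        assert np.isfinite(res.table.chi2[0]) and res.table.chi2[0] >= 0


class TestMetaSingleTrait:
    def test_two_cohort_sum_of_squares_under_identity(self, rng):
        ta, tb = rng.normal(size=300), rng.normal(size=300)
        res = sg.meta_single_trait(_fake_table(ta, "bulls", "my"), _fake_table(tb, "cows", "my"))
        assert res.df == 2
        # independent simulated cohorts: V ~ I so chi2 tracks ta^2+tb^2
        assert np.corrcoef(res.table.chi2, ta**2 + tb**2)[0, 1] > 0.99
        # and with V forced to exact identity the reduction is exact
        exact = sg.multi_trait_chi2(np.column_stack([ta, tb]), np.eye(2))
        assert np.allclose(exact.table.chi2, ta**2 + tb**2)


class TestFDR:
    @pytest.mark.parametrize(
        "P, S, expected_pct",
        [(1e-7, 1, 0.04), (1e-5, 1, 4.49), (1e-4, 3, 14.95), (1e-5, 2, 2.24), (1e-7, 4, 0.01)],
    )
    def test_reported_values(self, P, S, expected_pct):
        assert round(100 * sg.fdr(P=P, S=S, T=4489), 2) == expected_pct

    def test_all_significant_gives_zero(self):
        assert sg.fdr(P=1e-7, S=4489, T=4489) == 0.0

    def test_zero_significant_undefined(self):
        assert np.isnan(sg.fdr(P=1e-7, S=0, T=4489))

    def test_monotone_in_p_and_s(self):
        T = 1000
        grid_p = [1e-7, 1e-6, 1e-5, 1e-4, 1e-3]
        for s in (1, 5, 20):
            vals = [sg.fdr(P=p, S=s, T=T) for p in grid_p]
            assert all(a < b for a, b in zip(vals, vals[1:]))
        for p in grid_p:
            vals = [sg.fdr(P=p, S=s, T=T) for s in (1, 2, 5, 10, 50)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            sg.FDRQuery(P=0.0, S=1, T=10)
        with pytest.raises(ValueError):
            sg.FDRQuery(P=0.5, S=11, T=10)


class TestThresholds:
    def test_bonferroni_for_full_marker_set(self):
        thr = sg.significance_thresholds(583488)
        assert thr.bonferroni == pytest.approx(0.05 / 583488)
        assert thr.bonferroni < 1e-7  # below the strictest ladder rung

    def test_small_n(self):
        assert sg.significance_thresholds(5).bonferroni == pytest.approx(0.01)

    def test_ladder_sorted_ascending(self):
        lad = sg.significance_thresholds(100).ladder
        assert list(lad) == sorted(lad)


class TestLDWindow:
    def make_maps(self, n_snp, spacing=1000):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_snp) * spacing,
                "end": np.arange(n_snp) * spacing + 1,
                "id": [f"snp{i}" for i in range(n_snp)],
                "type": "SNP",
            }
        )

    def test_identical_dosage_gives_r2_one(self, rng):
        snps = rng.binomial(2, 0.4, (200, 10)).astype(float)
        tab = sg.ld_window(snps[:, 3], ("chr1", 3000, 3001), snps, self.make_maps(10), 5000)
        assert tab.loc[tab.snp_id == "snp3", "r2"].iloc[0] == pytest.approx(1.0)
        assert tab.loc[tab.snp_id == "snp3", "high_ld"].iloc[0]

    def test_matches_covariance_formula_oracle(self, rng):
        snps = rng.binomial(2, 0.4, (300, 8)).astype(float)
        sv = rng.binomial(2, 0.3, 300).astype(float)
        tab = sg.ld_window(sv, ("chr1", 0, 2), snps, self.make_maps(8), 10**6)
        for i in range(8):
            cov = np.cov(sv, snps[:, i])
            expected = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
            assert tab.r2.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_window_limits_and_monomorphic_na(self, rng):
        snps = np.column_stack([rng.binomial(2, 0.4, 100), np.zeros(100)])
        tab = sg.ld_window(rng.binomial(2, 0.4, 100).astype(float), ("chr1", 0, 10), snps,
                           self.make_maps(2, spacing=600), window_bp=500)
        assert len(tab) == 1  # second SNP outside the window
        tab2 = sg.ld_window(rng.binomial(2, 0.4, 100).astype(float), ("chr1", 0, 10), snps,
                            self.make_maps(2, spacing=100), window_bp=500)
        assert np.isnan(tab2.r2.iloc[1])

    def test_independent_pair_r2_small(self):
        low = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.5, 1000).astype(float)
            b = rng.binomial(2, 0.5, (1000, 1)).astype(float)
            tab = sg.ld_window(a, ("chr1", 0, 2), b, self.make_maps(1), 10**6)
            low += tab.r2.iloc[0] < 0.01
        assert low / reps >= 0.9
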