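"""Kinship, mixed-model association, meta-analysis, and variant QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pleioscan as ps
from pleioscan.io import PleioscanError


def _random_dosages(rng, n, m, p=None):
    p = rng.uniform(0.1, 0.5, m) if p is None else p
    return rng.binomial(2, p, size=(n, m)).astype(float)


def _phenotype_vector(geno, records):
    return (
        ps.average_records(records)
        .set_index("animal_id")
        .loc[geno.samples["sample_id"].to_numpy(), "value"]
        .to_numpy()
    )


class TestIBS:
    def test_identical_rows_share_everything(self):
        X = np.tile([0.0, 1.0, 2.0, 1.0], (2, 1))
        K = ps.ibs_matrix(X)
        assert K[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_share_nothing(self):
        X = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        assert ps.ibs_matrix(X)[0, 1] == pytest.approx(0.0)

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(0)
        X = _random_dosages(rng, 5, 10)
        K = ps.ibs_matrix(X)
        for i in range(5):
            for j in range(5):
                expect = np.mean(1.0 - np.abs(X[i] - X[j]) / 2.0) if i != j else 1.0
                assert K[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variants_rejected(self):
        with pytest.raises(PleioscanError):
            ps.ibs_matrix(np.empty((4, 0)))


class TestNullModel:
    def test_identity_kinship_matches_ols_residual_variance(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(200)
        fit = ps.fit_null_mixed_model(y, np.ones((200, 1)), np.eye(200))
        ols_var = float(np.var(y, ddof=1))
        assert fit.sigma2_g + fit.sigma2_e == pytest.approx(ols_var, rel=1e-3)

    def test_heritability_recovery(self):
        """y simulated at h2 = 0.5 on a genomic kinship is recovered."""
        h2s = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            X = _random_dosages(rng, 500, 400)
            K = ps.grm_matrix(X)
            b = rng.standard_normal(400)
            u = (X - X.mean(0)) @ b
            u *= np.sqrt(0.5) / u.std()
            y = u + rng.standard_normal(500) * np.sqrt(0.5)
            h2s.append(ps.fit_null_mixed_model(y, np.ones((500, 1)), K).h2)
        assert abs(np.mean(h2s) - 0.5) < 0.08

    def test_no_signal_gives_near_zero_h2(self):
        h2s = []
        for rep in range(5):
            rng = np.random.default_rng(200 + rep)
            X = _random_dosages(rng, 300, 300)
            y = rng.standard_normal(300)
            h2s.append(
                ps.fit_null_mixed_model(y, np.ones((300, 1)), ps.grm_matrix(X)).h2
            )
        assert np.mean(h2s) < 0.1

    def test_singular_covariates_rejected(self):
        y = np.random.default_rng(3).standard_normal(50)
        X = np.ones((50, 2))
        with pytest.raises(PleioscanError):
            ps.fit_null_mixed_model(y, X, np.eye(50))


class TestEmmaxScan:
    def test_identity_kinship_equals_ols_t(self):
        rng = np.random.default_rng(4)
        n, m = 300, 120
        X = _random_dosages(rng, n, m)
        y = rng.standard_normal(n)
        null = ps.fit_null_mixed_model(y, np.ones((n, 1)), np.eye(n))
        res = ps.emmax_scan(X, null, y)
        for j in [0, 17, 63, 119]:
            A = np.column_stack([np.ones(n), X[:, j]])
            bh = np.linalg.lstsq(A, y, rcond=None)[0]
            r = y - A @ bh
            s2 = r @ r / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
            assert res["t_stat"].iloc[j] == pytest.approx(bh[1] / se, abs=1e-8)

    def test_effect_estimate_unbiased(self):
        """Mean estimated beta over replicates matches the planted effect."""
        betas = []
        a = 0.3
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            X = _random_dosages(rng, 500, 30)
            y = a * (X[:, 7] - X[:, 7].mean()) + rng.standard_normal(500)
            null = ps.fit_null_mixed_model(y, np.ones((500, 1)), np.eye(500))
            betas.append(ps.emmax_scan(X, null, y)["beta"].iloc[7])
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert np.mean(betas) == pytest.approx(a, abs=2 * mc_se)

    def test_monomorphic_variant_flagged_not_tested(self):
        rng = np.random.default_rng(5)
        X = _random_dosages(rng, 100, 5)
        X[:, 2] = 1.0
        y = rng.standard_normal(100)
        null = ps.fit_null_mixed_model(y, np.ones((100, 1)), np.eye(100))
        res = ps.emmax_scan(X, null, y)
        assert not res["tested"].iloc[2]
        assert np.isnan(res["p_value"].iloc[2])
        assert res["tested"].drop(index=2).all()

    def test_missing_conditioning_variant_rejected(self, small_cohort):
        rng = np.random.default_rng(6)
        y = rng.standard_normal(small_cohort.n_samples)
        null = ps.fit_null_mixed_model(
            y, np.ones((len(y), 1)), np.eye(len(y))
        )
        with pytest.raises(PleioscanError):
            ps.emmax_scan(small_cohort, null, y, condition_on=["absent"])

    def test_family_structure_calibration(self):
        """Mixed-model p-values stay uniform under a polygenic null with
        half-sib structure while naive OLS inflates badly."""
        cfg = ps.PopulationConfig(
            n_sires=8, daughters_per_sire=70, n_unrelated=40, n_variants=600,
            chrom_length_bp=60_000_000, seed=21,
        )
        g = ps.simulate_genotypes(cfg)
        tm = ps.TraitModel(
            trait_names=("null",), polygenic_h2=(0.4,), pe_var_fraction=(0.0,),
            hys_var_fraction=(0.0,), n_records=1,
        )
        rec, _ = ps.simulate_phenotypes(g, tm, seed=2)
        y = _phenotype_vector(g, rec)
        ones = np.ones((len(y), 1))
        K = ps.ibs_matrix(g)
        p_mm = ps.emmax_scan(g, ps.fit_null_mixed_model(y, ones, K), y)[
            "p_value"
        ].to_numpy()
        p_ols = ps.emmax_scan(
            g, ps.fit_null_mixed_model(y, ones, np.eye(len(y))), y
        )["p_value"].to_numpy()
        assert sps.kstest(p_mm, "uniform").pvalue > 0.01
        assert (p_mm < 0.05).mean() < 0.10
        assert (p_ols < 0.05).mean() > 0.20  # inflation without correction


class TestMeta:
    def test_zero_statistics(self):
        res = ps.multi_trait_meta([[0.0, 0.0]])
        assert res["stat"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_chi2_two_df_closed_form(self):
        res = ps.multi_trait_meta([[1.0, 2.0]])
        assert res["stat"].iloc[0] == pytest.approx(5.0)
        assert res["df"].iloc[0] == 2
        assert res["p_value"].iloc[0] == pytest.approx(np.exp(-2.5), rel=1e-12)

    def test_single_analysis_equals_two_sided_normal(self):
        t = 1.7
        res = ps.multi_trait_meta([[t]])
        assert res["p_value"].iloc[0] == pytest.approx(2 * sps.norm.sf(t), rel=1e-12)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(7)
        T = rng.standard_normal((40, 3))
        flipped = T * rng.choice([-1.0, 1.0], size=T.shape)
        a = ps.multi_trait_meta(T)["stat"].to_numpy()
        b = ps.multi_trait_meta(flipped)["stat"].to_numpy()
        assert np.allclose(a, b)

    def test_empty_rejected(self):
        with pytest.raises(PleioscanError):
            ps.multi_trait_meta(np.empty((0, 0)))

    def test_two_cohort_null_type1_control(self):
        """Separate cohorts with different residual variances, combined by
        sum(t^2), keep type-I error at the nominal level."""
        rng = np.random.default_rng(8)
        m = 400
        ts = []
        for n, sd in ((300, 1.0), (150, 2.0)):
            X = _random_dosages(rng, n, m)
            y = rng.standard_normal(n) * sd
            null = ps.fit_null_mixed_model(y, np.ones((n, 1)), np.eye(n))
            ts.append(ps.emmax_scan(X, null, y, use_t=False)["t_stat"].to_numpy())
        res = ps.multi_trait_meta(np.column_stack(ts))
        assert abs((res["p_value"] < 0.05).mean() - 0.05) < 0.03


class TestVariantQC:
    def _table(self, m):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(m)],
                "chrom": "1",
                "pos": np.arange(m) + 1,
                "ref": "A",
                "alt": "C",
            }
        )

    def test_low_maf_removed(self):
        rng = np.random.default_rng(9)
        X = _random_dosages(rng, 2000, 4, p=np.array([0.3, 0.4, 0.2, 0.25]))
        rare = np.zeros((2000, 1))
        rare[0, 0] = 1.0  # MAF 0.00025
        X = np.hstack([X, rare])
        out, keep, logd = ps.variant_qc(self._table(5), X, maf_min=0.001)
        assert len(out) == 4 and not keep[4]
        assert logd["removed"]["maf"] == 1

    def test_disabled_filters_identity(self):
        rng = np.random.default_rng(10)
        X = _random_dosages(rng, 50, 6)
        out, keep, _ = ps.variant_qc(
            self._table(6), X, maf_min=None, r2_min=None, hwe_p_min=None
        )
        assert keep.all() and len(out) == 6

    def test_hwe_hand_example_retained(self):
        """Genotype counts (AA=10, Aa=10, aa=0): chi2 ~ 2.222, p ~ 0.136."""
        X = np.array([0.0] * 10 + [1.0] * 10)[:, None]
        p = ps.hwe_test(X)[0]
        chi2 = sps.chi2.isf(p, df=1)
        assert chi2 == pytest.approx(20.0 / 9.0, abs=1e-6)
        assert p == pytest.approx(0.136, abs=0.002)
        _, keep, _ = ps.variant_qc(self._table(1), X, maf_min=None, hwe_p_min=1e-10)
        assert keep[0]

    def test_imputation_r2_filter(self):
        rng = np.random.default_rng(11)
        X = _random_dosages(rng, 100, 3)
        tbl = self._table(3)
        tbl["imputation_r2"] = [0.95, 0.5, 0.8]
        out, keep, logd = ps.variant_qc(tbl, X, maf_min=None, r2_min=0.70)
        assert list(keep) == [True, False, True]
        assert logd["removed"]["imputation_r2"] == 1

    def test_filters_order_independent(self):
        rng = np.random.default_rng(12)
        X = _random_dosages(rng, 300, 20)
        X[:, 3] = 0.0
        X[0, 3] = 1.0
        tbl = self._table(20)
        tbl["imputation_r2"] = rng.uniform(0.5, 1.0, 20)
        _, joint, _ = ps.variant_qc(tbl, X, maf_min=0.001, r2_min=0.7, hwe_p_min=1e-10)
        _, k1, _ = ps.variant_qc(tbl, X, maf_min=0.001)
        _, k2, _ = ps.variant_qc(tbl, X, maf_min=None, r2_min=0.7)
        _, k3, _ = ps.variant_qc(tbl, X, maf_min=None, hwe_p_min=1e-10)
        assert np.array_equal(joint, k1 & k2 & k3)
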