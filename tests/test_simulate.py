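"""Generator checks: family structure, LD, frequencies, variance budget."""

import itertools

import numpy as np
import pytest

import pleioscan as ps
from pleioscan.io import PleioscanError


def _phenotype_vector(geno, records, trait=None):
    ph = ps.average_records(records)
    if trait is not None:
        ph = ph[ph["trait"] == trait]
    return (
        ph.set_index("animal_id")
        .loc[geno.samples["sample_id"].to_numpy(), "value"]
        .to_numpy()
    )


class TestGenotypes:
    def test_deterministic_given_seed(self):
        cfg = ps.PopulationConfig(n_variants=50, seed=3)
        a = ps.simulate_genotypes(cfg)
        b = ps.simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)
        c = ps.simulate_genotypes(ps.PopulationConfig(n_variants=50, seed=4))
        assert not np.array_equal(a.dosages, c.dosages)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_sires": -1},
            {"n_variants": 0},
            {"ld_rho": 0.0},
            {"ld_rho": 1.0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"n_sires": 0, "daughters_per_sire": 0, "n_unrelated": 0},
        ],
    )
    def test_config_validation(self, bad):
        with pytest.raises(PleioscanError):
            ps.PopulationConfig(**bad)

    def test_allele_frequencies_converge(self):
        """Realized frequencies approach the generating ones at large n."""
        cfg = ps.PopulationConfig(
            n_sires=0,
            daughters_per_sire=0,
            n_unrelated=2500,
            n_variants=40,
            seed=11,
        )
        g = ps.simulate_genotypes(cfg)
        p_hat = g.allele_freq()
        p = g.variants["freq"].to_numpy()
        se = np.sqrt(p * (1 - p) / (2 * cfg.n_unrelated))
        assert (np.abs(p_hat - p) < 3 * se + 1e-9).mean() > 0.9

    def test_ld_vanishes_as_rho_goes_to_zero(self):
        cfg = ps.PopulationConfig(
            n_sires=0,
            daughters_per_sire=0,
            n_unrelated=800,
            n_variants=80,
            ld_rho=1e-6,
            seed=5,
        )
        g = ps.simulate_genotypes(cfg)
        r = np.corrcoef(g.dosages.T)
        adj_r2 = np.array([r[j, j + 1] ** 2 for j in range(79)])
        assert adj_r2.mean() < 0.01

    def test_ld_present_at_high_rho(self):
        cfg = ps.PopulationConfig(
            n_sires=0, n_unrelated=800, n_variants=80, ld_rho=0.9, seed=5
        )
        g = ps.simulate_genotypes(cfg)
        r = np.corrcoef(g.dosages.T)
        adj_r2 = np.array([r[j, j + 1] ** 2 for j in range(79)])
        assert adj_r2.mean() > 0.2

    def test_half_sib_relationship_structure(self):
        """Daughter-sire pairs average ~0.5, half-sib pairs ~0.25 on the GRM
        centered at the generating frequencies."""
        cfg = ps.PopulationConfig(
            n_sires=8,
            daughters_per_sire=50,
            n_unrelated=0,
            n_variants=500,
            chrom_length_bp=50_000_000,
            seed=2,
        )
        g = ps.simulate_genotypes(cfg)
        G = ps.grm_matrix(g, freqs=g.variants["freq"].to_numpy())
        ids = g.samples["sample_id"].to_numpy()
        sire_of = g.samples["sire_id"].to_numpy()
        sire_pos = {s: np.flatnonzero(ids == s)[0] for s in set(sire_of) if s}
        po = [G[i, sire_pos[sire_of[i]]] for i in range(400)]
        hs = [
            G[i, j]
            for i, j in itertools.combinations(range(0, 400, 7), 2)
            if sire_of[i] == sire_of[j]
        ]
        assert abs(np.mean(po) - 0.5) < 0.06
        assert abs(np.mean(hs) - 0.25) < 0.05

    def test_focal_variant_frequency_pinned(self):
        cfg = ps.PopulationConfig(
            n_unrelated=1500, n_sires=0, n_variants=30, focal_variant=15,
            focal_freq=0.3, seed=9,
        )
        g = ps.simulate_genotypes(cfg)
        assert g.variants["freq"].iloc[15] == 0.3
        assert abs(g.allele_freq()[15] - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 3000)


class TestPhenotypes:
    def test_residual_only_model(self, small_cohort):
        tm = ps.TraitModel(
            trait_names=("t",),
            polygenic_h2=(0.0,),
            pe_var_fraction=(0.0,),
            hys_var_fraction=(0.0,),
            residual_var=(1.0,),
            n_records=1,
        )
        rec, _ = ps.simulate_phenotypes(small_cohort, tm, seed=1)
        assert abs(rec["value"].var(ddof=1) - 1.0) < 0.45

    def test_variance_budget_of_averaged_phenotype(self):
        """With derived residual variance, the record-averaged phenotype has
        variance ~ sigma2_P and components match their configured shares."""
        cfg = ps.PopulationConfig(
            n_sires=8, daughters_per_sire=250, n_variants=100, seed=13
        )
        g = ps.simulate_genotypes(cfg)
        tm = ps.TraitModel(
            trait_names=("t",),
            polygenic_h2=(0.3,),
            pe_var_fraction=(0.2,),
            hys_var_fraction=(0.1,),
            sigma2_P=(2.0,),
        )
        rec, truth = ps.simulate_phenotypes(g, tm, seed=2)
        y = _phenotype_vector(g, rec)
        assert abs(y.var(ddof=1) / 2.0 - 1.0) < 0.15
        comp = truth["traits"]["t"]
        assert abs(comp["pe"].var(ddof=1) - 0.4) < 0.1
        assert abs(comp["polygenic"].var(ddof=1) - 0.6) < 0.1
        # residual per record is n_records * (1 - sum of fractions) * sigma2P
        assert comp["sigma2_e"] == pytest.approx(2 * 0.4 * 2.0)

    def test_planted_variant_explains_configured_fraction(self):
        """Mean single-variant regression R2 recovers the planted 0.11."""
        r2s = []
        for s in range(50):
            cfg = ps.PopulationConfig(focal_variant=100, seed=3000 + s)
            g = ps.simulate_genotypes(cfg)
            pos = int(g.variants["pos"].iloc[100])
            tm = ps.TraitModel(
                trait_names=("p",),
                qtl_positions=(pos,),
                qtl_var_fraction=[[0.11]],
            )
            rec, _ = ps.simulate_phenotypes(g, tm, seed=s)
            y = _phenotype_vector(g, rec)
            x = g.dosages[:, 100]
            r2s.append(np.corrcoef(x, y)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.11) < 0.02

    def test_overbudget_fractions_rejected(self):
        with pytest.raises(PleioscanError):
            ps.TraitModel(
                trait_names=("t",),
                qtl_positions=(1,),
                qtl_var_fraction=[[0.5]],
                polygenic_h2=(0.4,),
                pe_var_fraction=(0.2,),
            )

    def test_single_record_fraction_feeds_filter(self, small_cohort):
        tm = ps.TraitModel(trait_names=("t",), frac_single_record=0.4)
        rec, _ = ps.simulate_phenotypes(small_cohort, tm, seed=4)
        counts = rec.groupby("animal_id").size()
        assert set(counts.unique()) == {1, 2}
        kept = ps.filter_min_records(rec, min_records=2)
        assert set(kept.groupby("animal_id").size().unique()) == {2}
        assert kept["animal_id"].nunique() == (counts == 2).sum()

    def test_record_weights_attached(self, small_cohort):
        tm = ps.TraitModel(trait_names=("t",), record_weight=2.5)
        rec, _ = ps.simulate_phenotypes(small_cohort, tm, seed=5)
        assert (rec["weight"] == 2.5).all()


class TestExpression:
    def test_unknown_variant_raises(self, small_cohort):
        em = ps.ExpressionModel(eqtl_variant="nope")
        with pytest.raises(PleioscanError):
            ps.simulate_expression(small_cohort, em, seed=1)

    def test_null_beta_gives_uniform_scan_pvalues(self):
        from scipy import stats as sps

        cfg = ps.PopulationConfig(
            n_sires=4, daughters_per_sire=50, n_unrelated=100, n_variants=150,
            seed=17,
        )
        g = ps.simulate_genotypes(cfg)
        em = ps.ExpressionModel(eqtl_variant=None, eqtl_beta=0.0)
        expr = ps.simulate_expression(g, em, seed=2)
        res = ps.eqtl_scan(expr, g, mds=None, gene_id="geneA")
        ks = sps.kstest(res["p_value"].dropna().to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_expression_deterministic(self, small_cohort):
        em = ps.ExpressionModel(
            eqtl_variant=small_cohort.variants["variant_id"].iloc[0]
        )
        a = ps.simulate_expression(small_cohort, em, seed=3)
        b = ps.simulate_expression(small_cohort, em, seed=3)
        assert np.array_equal(a["value"].to_numpy(), b["value"].to_numpy())
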