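"""Ground-truth recovery and invariants of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from abomics.haplotypes import default_panel
from abomics.ogtt import compute_traits
from abomics.synthetic import (
    AbundanceSpec,
    CohortConfig,
    MediationSpec,
    WHITE_HAPLOTYPE_FREQS,
    generate_cohort,
    generate_genotypes,
    generate_metabolites,
    generate_microbiome,
    generate_ogtt,
)


def _ols_beta_se(y, x):
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return fit.params[1], fit.bse[1]


class TestGenotypes:
    def test_degenerate_pool_all_o1(self, panel):
        cfg = CohortConfig(
            n_subjects=5, seed=1, haplotype_freqs={"O1": 1.0}, mediation=None
        )
        geno, truth = generate_genotypes(cfg, panel)
        assert all(d == ("O1", "O1") for d in truth.diplotypes)
        expected = [2 * b for b in panel.bits("O1")]
        assert (geno.to_numpy() == expected).all()

    def test_unknown_haplotype_label_rejected(self, panel):
        with pytest.raises(ValueError, match="not in panel"):
            cfg = CohortConfig(
                n_subjects=5, seed=1, haplotype_freqs={"Z9": 1.0}, mediation=None
            )
            generate_genotypes(cfg, panel)

    def test_truth_frequencies_recover_pool(self, panel):
        cfg = CohortConfig(n_subjects=5000, seed=42, mediation=None)
        _, truth = generate_genotypes(cfg, panel)
        counts = truth.dosages.sum(axis=0) / (2 * cfg.n_subjects)
        for hap, f in WHITE_HAPLOTYPE_FREQS.items():
            assert counts[hap] == pytest.approx(f, abs=0.02)

    def test_heterozygote_fraction_follows_hardy_weinberg(self, panel):
        # two haplotypes at 0.5/0.5 differ at rs2519093; expect 2pq = 0.5 hets
        cfg = CohortConfig(
            n_subjects=10000,
            seed=9,
            haplotype_freqs={"O1": 0.5, "A1": 0.5},
            mediation=None,
        )
        geno, _ = generate_genotypes(cfg, panel)
        het = (geno["rs2519093"] == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)

    def test_same_seed_bit_identical(self, panel):
        cfg = CohortConfig(n_subjects=200, seed=77, mediation=None)
        a, _ = generate_genotypes(cfg, panel)
        b, _ = generate_genotypes(cfg, panel)
        pd.testing.assert_frame_equal(a, b)

    def test_dosage_rows_sum_to_two(self, panel):
        cfg = CohortConfig(n_subjects=100, seed=3, mediation=None)
        _, truth = generate_genotypes(cfg, panel)
        assert (truth.dosages.sum(axis=1) == 2.0).all()

    def test_missingness_masks_entries(self, panel):
        cfg = CohortConfig(n_subjects=500, seed=4, missing_rate=0.1, mediation=None)
        geno, _ = generate_genotypes(cfg, panel)
        frac = geno.isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.03)


class TestOGTT:
    def test_zero_effects_zero_noise_identical_traits(self, panel):
        cfg = CohortConfig(
            n_subjects=20, seed=5, trait_noise_sd=1e-12, mediation=None,
            covariate_effects={},
        )
        _, truth = generate_genotypes(cfg, panel)
        ogtt = generate_ogtt(truth, cfg)
        traits = compute_traits(ogtt)
        assert traits["isi"].std() == pytest.approx(0.0, abs=1e-8)
        assert traits["secretion"].std() == pytest.approx(0.0, abs=1e-8)

    def test_curves_realise_trait_targets_exactly(self, panel):
        cfg = CohortConfig(n_subjects=50, seed=6, mediation=None)
        _, truth = generate_genotypes(cfg, panel)
        ogtt = generate_ogtt(truth, cfg)
        traits = compute_traits(ogtt)
        # identity DI30 = ISI * secretion and positivity by construction
        assert np.allclose(traits["di30"], traits["isi"] * traits["secretion"])
        assert (ogtt > 0).all().all()

    def test_planted_isi_effect_recovered_by_ols(self, panel):
        cfg = CohortConfig(
            n_subjects=5000,
            seed=8,
            trait_effects={("A1", "isi"): 0.132},
            mediation=None,
            covariate_effects={},
        )
        _, truth = generate_genotypes(cfg, panel)
        ogtt = generate_ogtt(truth, cfg)
        log_isi = np.log(compute_traits(ogtt)["isi"])
        beta, se = _ols_beta_se(log_isi, truth.dosages["A1"])
        assert abs(beta - 0.132) < 3 * se

    def test_doubling_outcome_noise_doubles_residual_sd(self, panel):
        sds = []
        for sd_y in (0.2, 0.4):
            cfg = CohortConfig(
                n_subjects=4000,
                seed=10,
                mediation=MediationSpec(noise_sd_y=sd_y, noise_sd_m=0.3),
                covariate_effects={},
            )
            cohort = generate_cohort(cfg, panel)
            log_isi = np.log(compute_traits(cohort.ogtt)["isi"])
            X = sm.add_constant(
                pd.concat(
                    [cohort.truth.dosages["A1"], cohort.mediator_log], axis=1
                ).to_numpy()
            )
            fit = sm.OLS(log_isi.to_numpy(), X).fit()
            sds.append(np.std(fit.resid))
        assert sds[1] / sds[0] == pytest.approx(2.0, abs=0.1)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            CohortConfig(n_subjects=10, seed=1, trait_noise_sd=0.0, mediation=None)


class TestMicrobiome:
    def test_no_zero_inflation_no_zeros_and_equal_means(self):
        cfg = CohortConfig(
            n_subjects=2000,
            seed=12,
            mediation=None,
            abundance=AbundanceSpec(n_species=5, zero_inflation=0.0, log_mean=0.0),
        )
        table = generate_microbiome(cfg)
        assert (table > 0).all().all()
        means = table.mean(axis=0)
        assert means.max() - means.min() < 0.02

    def test_rows_close_to_one_exactly(self):
        cfg = CohortConfig(n_subjects=100, seed=13, mediation=None)
        table = generate_microbiome(cfg)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_zero_fraction_observed(self):
        cfg = CohortConfig(
            n_subjects=1000,
            seed=14,
            mediation=None,
            abundance=AbundanceSpec(
                n_species=3, zero_inflation=(0.8, 0.1, 0.0), log_mean=0.0
            ),
        )
        table = generate_microbiome(cfg)
        zero_frac = (table.iloc[:, 0] == 0).mean()
        assert zero_frac == pytest.approx(0.8, abs=0.04)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match="n_species"):
            CohortConfig(
                n_subjects=10, seed=1, mediation=None,
                abundance=AbundanceSpec(n_species=1),
            ).abundance.resolved()


class TestMetabolites:
    def test_null_a_gives_uncorrelated_mediator(self, panel):
        cfg = CohortConfig(
            n_subjects=3000,
            seed=15,
            mediation=MediationSpec(a=0.0),
        )
        _, truth = generate_genotypes(cfg, panel)
        metab = generate_metabolites(truth, cfg)
        r = np.corrcoef(np.log(metab["lactate"]), truth.dosages["A1"])[0, 1]
        assert abs(r) < 0.05

    def test_structural_coefficients_recovered(self, panel):
        cfg = CohortConfig(n_subjects=5000, seed=16, covariate_effects={})
        cohort = generate_cohort(cfg, panel)
        x = cohort.truth.dosages["A1"]
        m = cohort.mediator_log
        y = np.log(compute_traits(cohort.ogtt)["isi"])
        a_hat, a_se = _ols_beta_se(m, x)
        assert abs(a_hat - 0.4) < 3 * a_se
        X = sm.add_constant(pd.concat([x, m], axis=1).to_numpy())
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert abs(fit.params[1] - 0.2) < 3 * fit.bse[1]  # c'
        assert abs(fit.params[2] - 0.3) < 3 * fit.bse[2]  # b

    def test_planted_proportion_closed_form(self):
        spec = MediationSpec(a=0.4, b=0.3, c_prime=0.2)
        assert spec.proportion_mediated == pytest.approx(0.375)

    def test_structural_residuals_mean_zero(self, panel):
        cfg = CohortConfig(n_subjects=4000, seed=17, covariate_effects={})
        cohort = generate_cohort(cfg, panel)
        x = cohort.truth.dosages["A1"].to_numpy()
        m = cohort.mediator_log.to_numpy()
        resid = m - 0.4 * x
        tol = 3 * resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < tol


class TestConfig:
    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            CohortConfig(
                n_subjects=10, seed=1, haplotype_freqs={"O1": 0.5, "A1": 0.4},
                mediation=None,
            )

    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(
            n_subjects=50,
            seed=19,
            trait_effects={("A1", "isi"): 0.132, ("A2", "clearance"): 0.066},
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = CohortConfig.from_yaml(path)
        assert back.trait_effects == cfg.trait_effects
        assert back.mediation == cfg.mediation
        assert back.haplotype_freqs == cfg.haplotype_freqs

    def test_full_cohort_regeneration_identical(self, panel):
        cfg = CohortConfig(n_subjects=150, seed=20)
        a = generate_cohort(cfg, panel)
        b = generate_cohort(cfg, panel)
        pd.testing.assert_frame_equal(a.ogtt, b.ogtt)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.abundances, b.abundances)
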