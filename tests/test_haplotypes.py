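"""Panel classification, EM frequency estimation, diplotypes, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from abomics.haplotypes import (
    apply_frequency_floor,
    blood_type,
    bloodtype_counts,
    brute_force_frequencies,
    classify_haplotype,
    diplotype_posteriors,
    em_haplotype_frequencies,
    hwe_exact_test,
    ld_r_squared,
    panel_diagnostics,
)
from abomics.synthetic import CohortConfig, generate_genotypes

from conftest import genotype_frame


class TestClassification:
    @pytest.mark.parametrize(
        "alleles,label",
        [
            (("C", "C", "G", "delG", "C", "T"), "O1"),
            (("C", "C", "G", "G", "T", "C"), "A1"),
            (("C", "C", "A", "G", "C", "T"), "A2"),
            (("C", "T", "G", "G", "C", "T"), "B"),
            (("T", "C", "G", "delG", "C", "T"), "O2"),
            (("C", "C", "G", "G", "C", "T"), "unknown"),
        ],
    )
    def test_allele_vectors_map_to_haplotype_labels(self, panel, alleles, label):
        assert panel.classify(alleles) == label
        assert classify_haplotype(alleles, panel) == label

    def test_invalid_allele_rejected(self, panel):
        with pytest.raises(ValueError, match="allele"):
            panel.classify(("X", "C", "G", "delG", "C", "T"))

    def test_wrong_length_rejected(self, panel):
        with pytest.raises(ValueError):
            panel.classify(("C", "C"))


class TestEM:
    def test_degenerate_homozygous_cohort(self, panel):
        bits = panel.bits("O1")
        geno = genotype_frame([[2 * b for b in bits]] * 4, panel.snp_ids)
        freqs = em_haplotype_frequencies(geno, panel)
        assert freqs.frequencies["O1"] == pytest.approx(1.0, abs=1e-12)

    def test_all_missing_rejected(self, panel):
        geno = pd.DataFrame(np.nan, index=["a", "b"], columns=panel.snp_ids)
        with pytest.raises(ValueError, match="complete"):
            em_haplotype_frequencies(geno, panel)

    def test_two_snp_toy_matches_phase_enumeration_ml(self):
        # one double-heterozygote plus a symmetry-breaking homozygote: the
        # ML solution phases the double-het as (10, 01)
        geno = genotype_frame([[1, 1], [2, 0]])
        em = em_haplotype_frequencies(geno)
        bf = brute_force_frequencies(geno)
        for lab in set(em.frequencies) | set(bf.frequencies):
            assert em.frequencies.get(lab, 0.0) == pytest.approx(
                bf.frequencies.get(lab, 0.0), abs=1e-6
            )
        # analytic optimum of 2*x*y^3 with x + y = 1: y = 3/4
        assert em.frequencies["10"] == pytest.approx(0.75, abs=1e-6)
        assert em.frequencies["01"] == pytest.approx(0.25, abs=1e-6)

    def test_loglik_monotone_and_convergence_flag(self, panel):
        cfg = CohortConfig(n_subjects=300, seed=5, mediation=None)
        geno, _ = generate_genotypes(cfg, panel)
        # a decrease raises inside the EM loop, so finishing implies monotone
        freqs = em_haplotype_frequencies(geno, panel)
        assert freqs.converged
        assert sum(freqs.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        with pytest.warns(RuntimeWarning, match="converge"):
            em_haplotype_frequencies(geno, panel, tol=0.0, max_iter=3)

    def test_frequency_floor_keeps_most_frequent_reference(self, panel):
        cfg = CohortConfig(n_subjects=1000, seed=11, mediation=None)
        geno, _ = generate_genotypes(cfg, panel)
        freqs = em_haplotype_frequencies(geno, panel)
        retained = apply_frequency_floor(freqs, 0.05)
        assert "O1" in retained


class TestDiplotypes:
    def test_full_homozygote_is_unambiguous(self, panel):
        bits = panel.bits("A1")
        geno = genotype_frame([[2 * b for b in bits]], panel.snp_ids)
        freqs = em_haplotype_frequencies(geno, panel)
        post = diplotype_posteriors(geno, freqs, panel)
        subj = geno.index[0]
        assert post.unambiguous[subj]
        assert post.posteriors[subj][0] == (("A1", "A1"), pytest.approx(1.0))

    def test_posteriors_match_hand_computed_frequency_products(self, panel):
        # subject heterozygous A1/A2: consistent pairs are (A1, A2) and the
        # two residual phasings; with frequencies concentrated on the panel
        # haplotypes the posterior is freq-product weighted
        gen_a1 = panel.bits("A1")
        gen_a2 = panel.bits("A2")
        row = [a + b for a, b in zip(gen_a1, gen_a2)]
        geno = genotype_frame([row], panel.snp_ids)
        f = {"A1": 0.5, "A2": 0.3}
        # build a frequency object via EM on a cohort that pins these labels
        freqs = em_haplotype_frequencies(geno, panel)
        freqs.frequencies = {
            lab: f.get(lab.split("[")[0], 0.2 / (len(freqs.frequencies) - 2))
            for lab in freqs.frequencies
        }
        # renormalise leftover mass over residual haplotypes
        resid = [l for l in freqs.frequencies if l not in ("A1", "A2")]
        for l in resid:
            freqs.frequencies[l] = 0.2 / len(resid)
        post = diplotype_posteriors(geno, freqs, panel)
        dist = dict(post.posteriors[geno.index[0]])
        # hand computation: pairs (A1,A2): 2*0.5*0.3; residual pairs share the rest
        expected_top = 2 * 0.5 * 0.3
        total = sum(
            2 * freqs.frequencies[l1] * freqs.frequencies[l2]
            for (l1, l2) in dist
        )
        assert dist[("A1", "A2")] == pytest.approx(expected_top / total, abs=1e-12)

    def test_dosages_sum_to_two(self, panel):
        cfg = CohortConfig(n_subjects=200, seed=2, mediation=None)
        geno, _ = generate_genotypes(cfg, panel)
        freqs = em_haplotype_frequencies(geno, panel)
        post = diplotype_posteriors(geno, freqs, panel)
        assert np.allclose(post.dosages.sum(axis=1), 2.0, atol=1e-9)
        for subj, dist in post.posteriors.items():
            assert sum(p for _, p in dist) == pytest.approx(1.0, abs=1e-9)

    def test_unambiguous_fraction_decreases_with_heterozygosity(self, panel):
        # a pool concentrated on one haplotype yields mostly homozygotes;
        # a balanced pool yields more multi-het, more ambiguous subjects
        low = CohortConfig(
            n_subjects=800,
            seed=3,
            haplotype_freqs={"O1": 0.9, "A1": 0.05, "A2": 0.05},
            mediation=None,
        )
        high = CohortConfig(
            n_subjects=800,
            seed=3,
            haplotype_freqs={"O1": 0.4, "A1": 0.3, "A2": 0.3},
            mediation=None,
        )
        fractions = []
        for cfg in (low, high):
            geno, _ = generate_genotypes(cfg, panel)
            freqs = em_haplotype_frequencies(geno, panel)
            post = diplotype_posteriors(geno, freqs, panel)
            fractions.append(post.fraction_unambiguous)
        assert fractions[0] >= fractions[1]


class TestBloodTypes:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            (("O1", "O1"), "O"),
            (("O1", "O2"), "O"),
            (("A1", "O1"), "A"),
            (("A2", "A1"), "A"),
            (("B", "O2"), "B"),
            (("A2", "B"), "AB"),
            (("A1", "B"), "AB"),
        ],
    )
    def test_abo_dominance(self, pair, expected):
        assert blood_type(pair) == expected

    def test_unknown_haplotype_is_untypeable(self):
        assert blood_type(("unknown[C,C,G,G,C,T]", "O1")) is None

    def test_counting_skips_untypeable(self):
        counts = bloodtype_counts(
            [("O1", "O1"), ("A1", "B"), ("unknown", "O1"), ("B", "O1")]
        )
        assert counts == {"O": 1, "A": 0, "B": 1, "AB": 1}
        assert sum(counts.values()) == 3


def _hwe_oracle(n_het, n_hom_1, n_hom_2):
    """Independent exact HWE p-value via direct comb enumeration."""
    n = n_het + n_hom_1 + n_hom_2
    rare = 2 * min(n_hom_1, n_hom_2) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # direct multinomial form: P(x) = n!/(na! x! nb!) * 2^x * rare!(2n-rare)!/(2n)!
    def p_exact(x):
        na = (rare - x) // 2
        nb = n - na - x
        if nb < 0:
            return 0.0
        return (
            math.factorial(n)
            // (math.factorial(na) * math.factorial(x) * math.factorial(nb))
            * 2**x
            * math.factorial(rare)
            * math.factorial(2 * n - rare)
            / math.factorial(2 * n)
        )
    obs = p_exact(n_het)
    return min(1.0, sum(
        p_exact(x)
        for x in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
        if p_exact(x) <= obs * (1 + 1e-12)
    ))


class TestDiagnostics:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (10, 20, 5), (3, 1, 0), (0, 4, 4), (7, 0, 2)],
    )
    def test_hwe_exact_matches_enumeration_oracle(self, counts):
        n_hom_ref, n_het, n_hom_alt = counts
        got = hwe_exact_test(n_het, n_hom_alt, n_hom_ref)
        want = _hwe_oracle(n_het, n_hom_alt, n_hom_ref)
        assert got == pytest.approx(want, rel=1e-9)

    def test_balanced_genotypes_have_maf_half_and_high_hwe_p(self):
        geno = genotype_frame(
            [[0]] * 25 + [[1]] * 50 + [[2]] * 25, columns=["snp1"]
        )
        per_snp, _ = panel_diagnostics(geno)
        assert per_snp.loc["snp1", "maf"] == pytest.approx(0.5)
        assert per_snp.loc["snp1", "hwe_p"] > 0.5

    def test_maf_hand_count(self):
        geno = genotype_frame([[0], [1], [2], [1]], columns=["snp1"])
        per_snp, _ = panel_diagnostics(geno)
        assert per_snp.loc["snp1", "maf"] == pytest.approx(0.5)

    def test_duplicated_snp_has_r2_one(self):
        col = [0, 1, 2, 1, 0, 2, 1, 1]
        geno = genotype_frame([[a, a] for a in col])
        _, r2 = panel_diagnostics(geno)
        assert r2.loc["snp1", "snp2"] == pytest.approx(1.0, abs=1e-6)

    def test_monomorphic_snp_reports_missing_r2_and_p_one(self):
        geno = genotype_frame([[0, 1], [0, 2], [0, 1], [0, 0]])
        per_snp, r2 = panel_diagnostics(geno)
        assert per_snp.loc["snp1", "maf"] == 0.0
        assert per_snp.loc["snp1", "hwe_p"] == 1.0
        assert np.isnan(r2.loc["snp1", "snp2"])

    def test_ld_r2_independent_snps_near_zero(self, rng):
        a = rng.binomial(2, 0.4, size=4000).astype(float)
        b = rng.binomial(2, 0.3, size=4000).astype(float)
        r2 = ld_r_squared(pd.Series(a), pd.Series(b))
        assert r2 < 0.01
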