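"""Haplotype counting/EM, LD statistics, association, consistency checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import aeikit as ak
from aeikit import haplotype_ld as hl
from aeikit.io_formats import GenotypeMatrix, SnpDef


def _matrix_from_haplotypes(haps, phased=True):
    """Build a two-SNP GenotypeMatrix from explicit per-subject haplotype pairs.

    ``haps`` is a list of (hap1, hap2) two-letter strings over alleles G/A.
    """
    snps = [SnpDef("loc1", "chr4", 100, "G", "A"),
            SnpDef("loc2", "chr4", 200, "G", "A")]
    n = len(haps)
    a1 = np.zeros((n, 2), dtype=np.int8)
    a2 = np.zeros((n, 2), dtype=np.int8)
    for i, (h1, h2) in enumerate(haps):
        for j in range(2):
            a1[i, j] = 1 if h1[j] == "A" else 0
            a2[i, j] = 1 if h2[j] == "A" else 0
    ph = np.full((n, 2), phased)
    gm = GenotypeMatrix([f"S{i}" for i in range(n)], snps, a1, a2, ph)
    return gm if phased else gm.unphased()


def _table(freqs):
    return hl.HaplotypeTable(("loc1", "loc2"), freqs, 200, "counted", None,
                             (("G", "A"), ("G", "A")))


class TestEstimateHaplotypes:
    def test_phased_direct_counting_matches_table2_frequencies(self):
        # 100 chromosomes: 60 GG, 24 AG, 16 GA, 0 AA
        haps = [("GG", "GG")] * 22 + [("GG", "AG")] * 12 + \
               [("GG", "GA")] * 6 + [("AG", "AG")] * 6 + [("GA", "GA")] * 5
        # chromosome counts: GG 22*2+12+6 = 62... build exactly instead
        pool = ["GG"] * 60 + ["AG"] * 24 + ["GA"] * 16
        haps = [(pool[2 * i], pool[2 * i + 1]) for i in range(50)]
        gm = _matrix_from_haplotypes(haps)
        t = hl.estimate_haplotypes(gm, ("loc1", "loc2"))
        assert t.method == "counted"
        assert t.n_chromosomes == 100
        assert t.freqs["GG"] == pytest.approx(0.60)
        assert t.freqs["AG"] == pytest.approx(0.24)
        assert t.freqs["GA"] == pytest.approx(0.16)
        assert t.freqs["AA"] == 0.0

    def test_em_equals_counting_without_double_heterozygotes(self):
        pool = ["GG"] * 6 + ["GA"] * 2 + ["AA"] * 2
        haps = [(pool[2 * i], pool[2 * i + 1]) for i in range(5)]
        gm_ph = _matrix_from_haplotypes(haps, phased=True)
        # no AG haplotype and loc1-het implies... ensure no double hets:
        counted = hl.estimate_haplotypes(gm_ph, ("loc1", "loc2"))
        d1 = gm_ph.dosage("loc1")
        d2 = gm_ph.dosage("loc2")
        if not np.any((d1 == 1) & (d2 == 1)):
            em = hl.estimate_haplotypes(gm_ph.unphased(), ("loc1", "loc2"))
            assert em.method == "EM"
            for h in counted.freqs:
                assert em.freqs[h] == pytest.approx(counted.freqs[h], abs=1e-6)

    def test_em_matches_brute_force_grid(self, rng):
        """EM frequencies equal the brute-force multinomial-ML grid optimum."""
        for _ in range(10):
            probs = rng.dirichlet([2.0, 1.0, 1.0, 0.5])
            hap_labels = ["GG", "GA", "AG", "AA"]
            pool = rng.choice(4, size=200, p=probs)
            haps = [(hap_labels[pool[2 * i]], hap_labels[pool[2 * i + 1]])
                    for i in range(100)]
            gm = _matrix_from_haplotypes(haps, phased=False)
            em = hl.estimate_haplotypes(gm, ("loc1", "loc2"))
            grid = hl.grid_ml_frequencies(gm.dosage("loc1"), gm.dosage("loc2"))
            assert np.abs(em.freq_array() - grid).max() < 1e-4

    def test_em_recovers_phased_counts_on_cohort(self, gwas_cohort):
        cfg, cohort = gwas_cohort
        counted = hl.estimate_haplotypes(cohort.genotypes,
                                         ("rsEXP01", "rsAPA01"))
        em = hl.estimate_haplotypes(cohort.genotypes.unphased(),
                                    ("rsEXP01", "rsAPA01"))
        # AA is (nearly) absent, so the double-het ambiguity resolves and EM
        # tracks the counted truth closely
        for h in counted.freqs:
            assert em.freqs[h] == pytest.approx(counted.freqs[h], abs=0.01)

    def test_frequencies_sum_to_one(self, gwas_cohort):
        cfg, cohort = gwas_cohort
        t = hl.estimate_haplotypes(cohort.genotypes.unphased(),
                                   ("rsEXP01", "rsAPA01"))
        assert sum(t.freqs.values()) == pytest.approx(1.0, abs=1e-9)


class TestLDStats:
    def test_independence_gives_zero(self):
        pA, pB = 0.3, 0.6
        t = _table({"GG": (1 - pA) * (1 - pB), "GA": (1 - pA) * pB,
                    "AG": pA * (1 - pB), "AA": pA * pB})
        s = hl.ld_stats(t)
        assert s.D == pytest.approx(0.0, abs=1e-12)
        assert s.D_prime == pytest.approx(0.0, abs=1e-9)
        assert s.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_table2_frequencies_give_high_dprime_low_r2(self):
        # AG .24, GA .16, GG .60, AA 0: D = -0.0384, D' = 1, r2 ~ 0.060
        t = _table({"GG": 0.60, "GA": 0.16, "AG": 0.24, "AA": 0.0})
        s = hl.ld_stats(t)
        assert s.D == pytest.approx(-0.0384, abs=1e-10)
        assert s.D_prime == pytest.approx(1.0)
        assert s.r_squared == pytest.approx(
            0.0384 ** 2 / (0.24 * 0.76 * 0.16 * 0.84), rel=1e-9)
        assert 0.05 <= s.r_squared <= 0.09

    def test_absent_haplotype_class_means_dprime_one(self):
        t = _table({"GG": 0.5, "GA": 0.3, "AG": 0.2, "AA": 0.0})
        assert hl.ld_stats(t).D_prime == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        t = _table({"GG": 0.7, "GA": 0.3, "AG": 0.0, "AA": 0.0})
        with pytest.raises(ValueError, match="monomorphic"):
            hl.ld_stats(t)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_bounds_and_weighted_covariance_oracle(self, ws):
        """0<=r2<=1, 0<=D'<=1, and r2 equals an independent weighted-
        covariance computation on the 2x2 haplotype distribution."""
        w = np.array(ws) / sum(ws)
        t = _table({"GG": w[0], "GA": w[1], "AG": w[2], "AA": w[3]})
        pA = w[2] + w[3]
        pB = w[1] + w[3]
        if not (1e-6 < pA < 1 - 1e-6 and 1e-6 < pB < 1 - 1e-6):
            return
        s = hl.ld_stats(t)
        assert 0.0 <= s.r_squared <= 1.0 + 1e-12
        assert 0.0 <= s.D_prime <= 1.0 + 1e-9
        # oracle: correlation of allele indicators X,Y under the haplotype
        # distribution, via generic weighted moments
        x = np.array([0, 0, 1, 1]); y = np.array([0, 1, 0, 1])
        ex, ey = (w * x).sum(), (w * y).sum()
        cov = (w * (x - ex) * (y - ey)).sum()
        vx = (w * (x - ex) ** 2).sum()
        vy = (w * (y - ey) ** 2).sum()
        assert s.r_squared == pytest.approx(cov * cov / (vx * vy), rel=1e-9)
        assert s.D == pytest.approx(cov, rel=1e-9, abs=1e-12)


class TestAssociation:
    def test_noiseless_phenotype_recovers_effects_exactly(self):
        cfg = ak.preset_config("gwas_like", n_subjects=400, seed=5)
        cfg.sigma_pheno = 0.0
        cohort = ak.simulate_cohort(cfg)
        t = hl.estimate_haplotypes(cohort.genotypes, ("rsEXP01", "rsAPA01"))
        dos = hl.haplotype_dosages(cohort.genotypes, t)
        pheno = cohort.phenotypes.set_index("sample_id")["immediate_recall"]
        out = hl.haplotype_association(dos, pheno, t).set_index("haplotype")
        assert out.loc["GG", "baseline_flag"]
        assert out.loc["AG", "effect"] == pytest.approx(-0.21, abs=1e-9)
        assert out.loc["GA", "effect"] == pytest.approx(-0.09, abs=1e-9)

    def test_null_phenotype_p_uniform_across_seeds(self):
        ps = []
        for seed in range(200):
            cfg = ak.preset_config("gwas_like", n_subjects=150,
                                   seed=20_000 + seed)
            cfg.pheno_effects = {"score": {}}
            cohort = ak.simulate_cohort(cfg)
            t = hl.estimate_haplotypes(cohort.genotypes, ("rsEXP01", "rsAPA01"))
            dos = hl.haplotype_dosages(cohort.genotypes, t)
            pheno = cohort.phenotypes.set_index("sample_id")["score"]
            out = hl.haplotype_association(dos, pheno, t).set_index("haplotype")
            ps.append(out.loc["AG", "p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_identical_haplotypes_not_testable(self):
        haps = [("GG", "GG")] * 10
        gm = _matrix_from_haplotypes(haps)
        t = _table({"GG": 1.0, "GA": 0.0, "AG": 0.0, "AA": 0.0})
        dos = hl.haplotype_dosages(gm, t)
        pheno = pd.Series(np.arange(10.0), index=gm.samples)
        with pytest.raises(ValueError, match="not testable"):
            hl.haplotype_association(dos, pheno, t)


class TestConsistencyCheck:
    def test_consistent_cohort_has_no_flags(self, gwas_cohort):
        cfg, cohort = gwas_cohort
        t = hl.estimate_haplotypes(cohort.genotypes, ("rsEXP01", "rsAPA01"))
        out = hl.haplotype_consistency_check(cohort.genotypes, t)
        assert out.empty

    def test_planted_rare_haplotype_subject_flagged(self):
        pool = ["GG"] * 70 + ["AG"] * 16 + ["GA"] * 13 + ["AA"]
        haps = [(pool[2 * i], pool[2 * i + 1]) for i in range(50)]
        # plant a subject that is homozygous for both minor alleles: it
        # cannot be built without two AA haplotypes
        haps[0] = ("AA", "AA")
        gm = _matrix_from_haplotypes(haps)
        t = _table({"GG": 0.60, "GA": 0.16, "AG": 0.24, "AA": 0.0})
        out = hl.haplotype_consistency_check(gm, t)
        assert len(out) >= 1
        assert "S0" in set(out["sample_id"])
        assert "AA" in out.set_index("sample_id").loc["S0", "required_haplotype"]

    def test_empty_cohort(self):
        gm = _matrix_from_haplotypes([("GG", "GG")])
        t = _table({"GG": 0.60, "GA": 0.16, "AG": 0.24, "AA": 0.0})
        out = hl.haplotype_consistency_check(
            gm, _table({"GG": 0.25, "GA": 0.25, "AG": 0.25, "AA": 0.25}))
        assert out.empty
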