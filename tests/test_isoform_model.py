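"""Forward-model algebra, inversion, concordance, and delta-delta-Ct."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aeikit as ak
from aeikit import isoform_model as iso

params_st = st.builds(
    iso.APAParams,
    T1=st.floats(0.05, 20.0), T2=st.floats(0.05, 20.0),
    f1=st.floats(0.01, 0.99), f2=st.floats(0.01, 0.99))


@pytest.mark.parametrize("p,expected", [
    (iso.APAParams(1, 1, 0.5, 0.5), (1.0, 1.0, 1.0)),
    (iso.APAParams(1, 1, 0.2, 0.5), (1.0, 1.6, 0.4)),
    # pure transcription effect moves every ratio identically
    (iso.APAParams(2, 1, 0.3, 0.3), (2.0, 2.0, 2.0)),
])
def test_forward_model_arithmetic(p, expected):
    r = iso.apa_forward(p)
    assert (r.R_total, r.R_long, r.R_short) == pytest.approx(expected)


@given(params_st)
def test_long_total_identity(p):
    r = iso.apa_forward(p)
    assert r.R_long == pytest.approx(
        r.R_total * (1 - p.f1) / (1 - p.f2), rel=1e-12)


@given(params_st)
def test_roundtrip_recovers_usage_ratio(p):
    r = iso.apa_forward(p)
    U = iso.infer_distal_usage_ratio(r.R_total, r.R_long)
    assert U == pytest.approx((1 - p.f1) / (1 - p.f2), rel=1e-12)


@given(params_st, st.floats(0.05, 20.0), st.floats(0.05, 20.0))
def test_model_separates_the_two_variant_signatures(p, t1, t2):
    """R_total ignores (f1,f2); R_long/R_short ignores (T1,T2)."""
    r = iso.apa_forward(p)
    moved_f = iso.apa_forward(iso.APAParams(p.T1, p.T2, 0.37, 0.61))
    assert moved_f.R_total == pytest.approx(r.R_total, rel=1e-12)
    moved_t = iso.apa_forward(iso.APAParams(t1, t2, p.f1, p.f2))
    assert (moved_t.R_long / moved_t.R_short
            == pytest.approx(r.R_long / r.R_short, rel=1e-9))


@pytest.mark.parametrize("Rt,Rl,expected", [
    (1.0, 1.6, 1.6),
    (2.0, 2.0, 1.0),   # pure expression effect: no usage shift
])
def test_usage_ratio_inference(Rt, Rl, expected):
    assert iso.infer_distal_usage_ratio(Rt, Rl) == pytest.approx(expected)


class TestSolveFShift:
    def test_identity(self):
        assert iso.solve_f_shift(1.0, 0.3) == pytest.approx((0.3, 0.3))

    def test_hand_algebra(self):
        f1, f2 = iso.solve_f_shift(1.75, 0.6)
        assert (f1, f2) == pytest.approx((0.3, 0.6))
        # cross-check by pushing back through the forward model
        r = iso.apa_forward(iso.APAParams(1, 1, f1, f2))
        assert r.R_long == pytest.approx(1.75)

    def test_infeasible_bound(self):
        with pytest.raises(ValueError, match="infeasible"):
            iso.solve_f_shift(4.0, 0.5)


class TestDualMarkerConcordance:
    def test_identical_pairs(self):
        x = np.array([0.2, 0.5, 0.9, 1.1])
        r2, slope = iso.dual_marker_concordance(x, x)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_unflipped_orientation_gives_negative_slope(self, rng):
        # markers with minor alleles on opposite haplotypes: forgetting the
        # flip shows up as slope ~ -1
        signal = rng.normal(0, 0.5, size=30)
        m1 = signal + rng.normal(0, 0.1, size=30)
        m2 = -signal + rng.normal(0, 0.1, size=30)   # opposite orientation
        r2, slope = iso.dual_marker_concordance(m1, m2, flip_second=False)
        assert slope < -0.5
        r2f, slope_f = iso.dual_marker_concordance(m1, m2, flip_second=True)
        assert slope_f > 0.5
        assert r2f == pytest.approx(r2)

    def test_noiseless_compound_hets_fully_concordant(self):
        from dataclasses import replace
        cfg = ak.preset_config("paper_like", n_subjects=60, seed=2)
        cfg = replace(cfg, sigma_peak=0.0)
        cohort = ak.simulate_cohort(cfg)
        aei = ak.aei_quant.usable_aei(
            ak.quantify(cohort.peaks, cohort.genotypes, cfg.amplicons))
        lng = aei[aei["amplicon_id"] == "ampLong"]
        m1 = lng[lng["snp_id"] == "rsAPA01"].set_index("sample_id")["log2_ratio"]
        m2 = lng[lng["snp_id"] == "rsEXP01"].set_index("sample_id")["log2_ratio"]
        common = m1.index.intersection(m2.index)
        assert len(common) >= 3
        r2, slope = iso.dual_marker_concordance(
            m1[common], m2[common], flip_second=True)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert abs(slope) == pytest.approx(1.0, abs=1e-6)

    def test_paper_like_concordance_envelope(self):
        # ~14 compound-het pairs with measurement noise: R^2 centers in the
        # tissue-panel range around ~0.6
        r2s = []
        for seed in range(30):
            cfg = ak.preset_config("paper_like", seed=100 + seed)
            cohort = ak.simulate_cohort(cfg)
            aei = ak.aei_quant.usable_aei(
                ak.quantify(cohort.peaks, cohort.genotypes, cfg.amplicons))
            lng = aei[aei["amplicon_id"] == "ampLong"]
            m1 = lng[lng["snp_id"] == "rsAPA01"].set_index("sample_id")["log2_ratio"]
            m2 = lng[lng["snp_id"] == "rsEXP01"].set_index("sample_id")["log2_ratio"]
            common = m1.index.intersection(m2.index)
            if len(common) < 5:
                continue
            r2s.append(iso.dual_marker_concordance(
                m1[common], m2[common], flip_second=True)[0])
        mean_r2 = float(np.mean(r2s))
        assert 0.4 <= mean_r2 <= 0.9
        assert np.mean([(0.3 <= v <= 0.95) for v in r2s]) >= 0.7


class TestRelativeLongFraction:
    def _ct(self, long_ct, total_ct, pgk=20.0):
        return pd.DataFrame({
            "sample_id": "S1",
            "assay": ["LONG_3UTR", "TOTAL_SNCA", "PGK1"],
            "ct": [long_ct, total_ct, pgk],
            "replicate_id": "q1"})

    def test_equal_ct_gives_unity(self):
        assert iso.relative_long_fraction(self._ct(24.0, 24.0)) == pytest.approx(1.0)

    def test_one_cycle_is_twofold(self):
        assert iso.relative_long_fraction(self._ct(25.0, 24.0)) == pytest.approx(0.5)

    def test_missing_assay_flagged(self):
        df = self._ct(24.0, 24.0)
        with pytest.raises(ValueError, match="PGK1"):
            iso.relative_long_fraction(df[df["assay"] != "PGK1"])

    def test_recovers_true_fraction_under_ct_noise(self, rng):
        true_frac = 0.4
        ests = []
        for _ in range(200):
            noise = rng.normal(0, 0.1, size=(3, 3))   # 3 replicates per assay
            df = pd.DataFrame({
                "sample_id": "S1",
                "assay": ["LONG_3UTR"] * 3 + ["TOTAL_SNCA"] * 3 + ["PGK1"] * 3,
                "ct": np.r_[24.0 - math.log2(true_frac) + noise[0],
                            24.0 + noise[1], 20.0 + noise[2]],
                "replicate_id": ["q1", "q2", "q3"] * 3})
            ests.append(iso.relative_long_fraction(df))
        assert np.mean(ests) == pytest.approx(true_frac, abs=0.02)

    def test_efficiency_parameter(self):
        # 90% efficiency: one cycle is a 1.9-fold, not 2-fold, difference
        v = iso.relative_long_fraction(self._ct(25.0, 24.0), efficiency=1.9)
        assert v == pytest.approx(1 / 1.9)


class TestLongFractionByGenotype:
    def test_identical_groups(self):
        df = pd.DataFrame({"genotype": ["GG", "GA"] * 3,
                           "long_fraction": [0.5] * 6})
        out = iso.long_fraction_by_genotype(df)
        assert out["p"] == pytest.approx(1.0)

    def test_direction_matches_usage_shift(self):
        # minor allele shifts usage proximal -> GG keeps more long isoform
        from dataclasses import replace
        hits = 0
        for seed in range(40):
            cfg = ak.preset_config("paper_like", n_subjects=20, seed=200 + seed)
            cohort = ak.simulate_cohort(cfg)
            dos = cohort.genotypes.dosage("rsAPA01")
            frac = [{"sample_id": s,
                     "long_fraction": iso.relative_long_fraction(
                         cohort.ct[cohort.ct["sample_id"] == s])}
                    for s in cohort.genotypes.samples]
            df = pd.DataFrame(frac)
            df["genotype"] = np.where(dos == 0, "GG",
                                      np.where(dos == 1, "GA", "AA"))
            df = df[df["genotype"].isin(["GG", "GA"])]
            if df["genotype"].nunique() < 2:
                continue
            out = iso.long_fraction_by_genotype(df)
            hits += out["higher_group"] == "GG"
        assert hits >= 0.9 * 40

    def test_low_n_flag_and_df(self):
        df = pd.DataFrame({"genotype": ["GG"] * 3 + ["GA"],
                           "long_fraction": [0.5, 0.6, 0.55, 0.3]})
        out = iso.long_fraction_by_genotype(df)
        assert out["df"] == 2
        assert out["low_n"]
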