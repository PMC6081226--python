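"""Genotype association scan for cis-acting variants driving AEI.

Each candidate SNP's genotype groups are compared on the magnitude of the
samples' log2 AEI ratios with a one-way ANOVA F test, Bonferroni-corrected
over the tests actually performed.  The default grouping is heterozygous
vs homozygous carriers, which is phase-free: in unphased tissue data the
marker heterozygote's phase relative to the candidate allele is unknown,
so the magnitude |log2 ratio| is the response and a candidate in cis shows
up as elevated AEI in its heterozygotes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

#: Smallest p-value ever reported; exact zeros are floored here and flagged.
P_FLOOR = 5e-324

GROUPINGS = ("het_vs_hom", "three_genotypes")


@dataclass(frozen=True)
class ScanResult:
    snp_id: str
    n_per_group: tuple[int, ...]
    F_stat: float
    p_value: float
    p_bonferroni: float
    rank: int


def aei_anova(values, labels, grouping: str = "het_vs_hom") -> tuple[float, float]:
    """One-way ANOVA of AEI magnitude across genotype groups.

    ``values`` are (magnitudes of) log2 AEI ratios, ``labels`` the group
    label per sample.  With two groups F equals the square of the
    pooled-variance t statistic.  All values identical across groups gives
    (F=0, p=1); zero within-group variance with differing means is
    reported at the p floor.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty genotype groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need total n >= 3")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if within == 0.0:
        return math.inf, P_FLOOR
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m*p)."""
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return min(1.0, m * p)


def _genotype_labels(dosage: np.ndarray, grouping: str) -> np.ndarray:
    if grouping == "het_vs_hom":
        lab = np.where(dosage == 1, "het", "hom")
    elif grouping == "three_genotypes":
        lab = np.array([f"g{int(d)}" for d in dosage])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return lab


def sample_response(aei: pd.DataFrame, response_amplicon_class: str,
                    magnitude: bool = True) -> pd.Series:
    """Per-sample AEI response: mean (|)log2 ratio(|) over records of a class."""
    sub = aei[(aei["isoform_class"] == response_amplicon_class)
              & aei["log2_ratio"].notna()]
    vals = sub["log2_ratio"].astype(float)
    if magnitude:
        vals = vals.abs()
    return vals.groupby(sub["sample_id"]).mean()


def scan(aei: pd.DataFrame, genotypes: GenotypeMatrix, candidates: list[str],
         response_amplicon_class: str = "LONG_ONLY",
         grouping: str = "het_vs_hom",
         magnitude: bool = True) -> pd.DataFrame:
    """Associate AEI magnitude with each candidate SNP's genotype.

    One row per *testable* candidate (>= 2 non-empty genotype groups among
    the samples that have AEI records of the requested amplicon class);
    monomorphic candidates are omitted, and the Bonferroni multiplier m is
    the number of tests actually performed.  Rows are sorted by ascending
    p and ranked.  Duplicate candidate IDs are collapsed (a repeated ID
    refers to the same genotype vector and is one test).
    """
    response = sample_response(aei, response_amplicon_class, magnitude)
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    keep = [s for s in response.index if s in sample_pos]
    response = response.loc[keep]
    rows = []
    seen = set()
    for snp_id in candidates:
        if snp_id in seen:
            continue
        seen.add(snp_id)
        dosage = genotypes.dosage(snp_id)
        d = np.array([dosage[sample_pos[s]] for s in response.index])
        ok = ~np.isnan(d)
        vals = response.to_numpy()[ok]
        labels = _genotype_labels(d[ok], grouping)
        counts = pd.Series(labels).value_counts()
        if len(counts) < 2 or vals.size < 3:
            continue  # monomorphic / untestable in this response set
        F, p = aei_anova(vals, labels, grouping)
        rows.append({"snp_id": snp_id, "n": int(vals.size),
                     "n_per_group": tuple(int(c) for c in counts.sort_index()),
                     "F_stat": F, "p_value": max(p, P_FLOOR)})
    if not rows:
        return pd.DataFrame(columns=["snp_id", "n", "n_per_group", "F_stat",
                                     "p_value", "p_bonferroni", "rank"])
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = [bonferroni(p, m) for p in out["p_value"]]
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def covariate_test(values, covariate) -> float:
    """Test a covariate (sex-like binary or age-like continuous) against AEI.

    Binary covariates get a two-sample t-test, continuous ones a simple
    linear-regression slope test.  A constant covariate is untestable.
    """
    values = np.asarray(values, dtype=float)
    cov = np.asarray(covariate)
    if values.size != cov.size:
        raise ValueError("values and covariate must align")
    if values.size < 3:
        raise ValueError("need >= 3 samples")
    levels = pd.unique(cov)
    if len(levels) < 2:
        raise ValueError("constant covariate is not testable")
    if len(levels) == 2:
        a = values[cov == levels[0]]
        b = values[cov == levels[1]]
        _, p = stats.ttest_ind(a, b, equal_var=True)
        return float(p)
    res = stats.linregress(cov.astype(float), values)
    return float(res.pvalue)


def paired_gdna_cdna_test(gdna_ratios, cdna_ratios,
                          sample_ids=None, exclusions=()) -> dict:
    """Paired comparison of gDNA vs cDNA allelic ratios at one marker.

    A significant paired t-test on the per-sample log2 ratios establishes
    AEI beyond assay bias (the gDNA ratio is the sample's own 1:1
    reference).  ``exclusions`` removes samples by id before testing —
    e.g. heterozygotes for a known large-effect variant, to isolate a
    second, moderate signal.

    Returns p, mean log2 difference (cDNA - gDNA) and the n used.
    """
    g = np.asarray(gdna_ratios, dtype=float)
    c = np.asarray(cdna_ratios, dtype=float)
    if g.shape != c.shape:
        raise ValueError("paired arrays must align")
    if sample_ids is not None:
        keep = np.array([s not in set(exclusions) for s in sample_ids])
        g, c = g[keep], c[keep]
    elif exclusions:
        raise ValueError("exclusions given without sample_ids")
    if g.size < 3:
        raise ValueError("need >= 3 paired samples after exclusions")
    lg, lc = np.log2(g), np.log2(c)
    diff = lc - lg
    if np.ptp(diff) == 0 and diff.mean() == 0:
        return {"p": 1.0, "mean_log2_diff": 0.0, "n": int(g.size)}
    t, p = stats.ttest_rel(lc, lg)
    return {"p": float(p), "mean_log2_diff": float(diff.mean()), "n": int(g.size)}
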