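"""Two-polyadenylation-site isoform model for allelic expression ratios.

A diploid locus transcribes each haplotype ``h`` at rate ``T_h``; each
transcript then commits to the proximal polyadenylation site with
probability ``f_h`` (short 3'UTR) or to the distal site with probability
``1 - f_h`` (long 3'UTR).  An amplicon that amplifies all isoforms sees
the allelic ratio of total transcription,

    R_total = T1 / T2,

while an amplicon specific to long-3'UTR isoforms sees

    R_long = T1 (1 - f1) / (T2 (1 - f2)),

so that R_long / R_total = (1 - f1) / (1 - f2) isolates the allelic shift
in polyadenylation-site usage, independent of any transcription effect.
A pure transcription variant moves R_total and R_long together; a pure
usage variant moves R_long (and R_short, in the opposite direction) while
leaving R_total at 1.  Equal turnover of short and long isoforms is
assumed throughout.

Haplotype indexing convention: haplotype 1 carries the marker's reference
allele after orientation reconciliation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class APAParams:
    """Per-haplotype transcription rates and proximal polyA usage fractions."""

    T1: float
    T2: float
    f1: float
    f2: float

    def __post_init__(self):
        if not (self.T1 > 0 and self.T2 > 0):
            raise ValueError(f"transcription rates must be > 0, got {self.T1}, {self.T2}")
        if not (0 < self.f1 < 1 and 0 < self.f2 < 1):
            raise ValueError(f"usage fractions must be in (0,1), got {self.f1}, {self.f2}")


@dataclass(frozen=True)
class AmpliconRatios:
    """Allelic ratios seen by each amplicon class (haplotype 1 / haplotype 2)."""

    R_total: float
    R_long: float
    R_short: float   # model-internal; not directly measurable


def apa_forward(params: APAParams) -> AmpliconRatios:
    """Forward model: haplotype parameters -> amplicon-class allelic ratios."""
    return AmpliconRatios(
        R_total=params.T1 / params.T2,
        R_long=params.T1 * (1.0 - params.f1) / (params.T2 * (1.0 - params.f2)),
        R_short=params.T1 * params.f1 / (params.T2 * params.f2),
    )


def infer_distal_usage_ratio(R_total: float, R_long: float) -> float:
    """Allelic distal-usage ratio U = (1-f1)/(1-f2) from two measured ratios.

    U > 1 means haplotype 1 routes a larger share of its transcripts to the
    distal (long-3'UTR) polyadenylation site.
    """
    if not (R_total > 0 and R_long > 0):
        raise ValueError("ratios must be > 0")
    return R_long / R_total


def solve_f_shift(U: float, f_baseline: float) -> tuple[float, float]:
    """Anchor the usage ratio U to an absolute pair (f1, f2 = f_baseline).

    Solves (1-f1)/(1-f2) = U with f2 fixed, i.e. f1 = 1 - U (1 - f_baseline).
    """
    if not 0 < f_baseline < 1:
        raise ValueError(f"f_baseline must be in (0,1), got {f_baseline}")
    f1 = 1.0 - U * (1.0 - f_baseline)
    if not 0 < f1 < 1:
        raise ValueError(
            f"infeasible: U={U} with f_baseline={f_baseline} gives f1={f1:.4g}; "
            f"require U*(1-f_baseline) in (0,1)")
    return f1, f_baseline


def dual_marker_concordance(log2_marker1: np.ndarray,
                            log2_marker2: np.ndarray,
                            flip_second: bool = False) -> tuple[float, float]:
    """Concordance of AEI measured at two marker SNPs on the same amplicon.

    In a compound heterozygote both markers tag the same two transcript
    pools, so after orientation reconciliation their log2 allelic ratios
    should agree.  When the two markers' minor alleles reside on opposite
    haplotypes, pass ``flip_second=True`` to negate the second marker's
    log2 ratios before regressing; a slope near -1 instead of +1 is the
    classic symptom of a missed flip.

    Returns ``(R_squared, slope)`` of the least-squares regression of
    marker 2 on marker 1.
    """
    x = np.asarray(log2_marker1, dtype=float)
    y = np.asarray(log2_marker2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired arrays must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 compound-heterozygous pairs")
    if flip_second:
        y = -y
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.slope)


def relative_long_fraction(ct: pd.DataFrame, sample_id: str | None = None,
                           efficiency: float = 2.0) -> float:
    """Relative long-3'UTR expression for one sample from qPCR Ct values.

    Expects replicate rows with assays LONG_3UTR, TOTAL_SNCA and PGK1
    (housekeeping).  Replicates are averaged per assay; the value is

        eff^-[(Ct_long - Ct_PGK1) - (Ct_total - Ct_PGK1)] = eff^-(Ct_long - Ct_total)

    i.e. the housekeeping terms cancel algebraically, but all three assays
    are still required so that a sample without its reference is flagged
    rather than silently computed.  ``efficiency`` is the per-cycle
    amplification factor (default 2.0 = 100% efficiency).
    """
    df = ct if sample_id is None else ct[ct["sample_id"] == sample_id]
    means = df.groupby("assay")["ct"].mean()
    for assay in ("LONG_3UTR", "TOTAL_SNCA", "PGK1"):
        if assay not in means.index:
            raise ValueError(
                f"sample {sample_id!r}: missing Ct replicates for assay {assay}")
    ddct = (means["LONG_3UTR"] - means["PGK1"]) - (means["TOTAL_SNCA"] - means["PGK1"])
    return float(efficiency ** (-ddct))


def long_fraction_by_genotype(fractions: pd.DataFrame,
                              group_col: str = "genotype",
                              value_col: str = "long_fraction"
                              ) -> dict:
    """Compare relative long-isoform expression between two genotype groups.

    Two-sample t-test (Welch) on log2 fractions, e.g. homozygous-major GG
    vs heterozygous GA at the polyadenylation variant.  Returns group
    means (on the natural scale), the difference direction, p-value and
    per-group n; groups of n < 3 are flagged low-n but still tested.
    """
    groups = {k: np.log2(g[value_col].to_numpy(dtype=float))
              for k, g in fractions.groupby(group_col)}
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 genotype groups, got {sorted(groups)}")
    (ga, va), (gb, vb) = sorted(groups.items())
    if len(va) == 0 or len(vb) == 0:
        raise ValueError("both genotype groups must be non-empty")
    if np.ptp(np.concatenate([va, vb])) == 0:
        t, p = 0.0, 1.0          # all observations identical: no evidence
    else:
        t, p = stats.ttest_ind(va, vb, equal_var=True)
    return {
        "groups": (ga, gb),
        "n": (len(va), len(vb)),
        "mean": (float(2.0 ** va.mean()), float(2.0 ** vb.mean())),
        "higher_group": ga if va.mean() > vb.mean() else gb,
        "t": float(t),
        "p": float(p),
        "df": len(va) + len(vb) - 2,
        "low_n": min(len(va), len(vb)) < 3,
    }


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))
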