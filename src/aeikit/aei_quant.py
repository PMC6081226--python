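"""Allelic-ratio quantification from SNaPshot primer-extension peak heights.

The raw allelic ratio at a heterozygous marker SNP is the ratio of the two
allele-specific fluorescent peak heights (reference over alternate).  The
cDNA ratio is then divided by the arithmetic mean of the same sample's
genomic-DNA ratios — a diploid heterozygote's gDNA is 1:1 by construction,
so this normalization cancels allele-specific assay bias.  A normalized
ratio different from 1 in cDNA is allelic expression imbalance (AEI) and
indicates cis-acting regulation.

All downstream statistics operate on log2 ratios; raw ratios are kept for
display.  Orientation (ref/alt vs major/minor) is explicit metadata on
every record and never inferred from the ratio itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import AmpliconDef, GenotypeMatrix

ORIENTATIONS = ("ref_over_alt", "major_over_minor", "minor_over_major")

#: Default heterozygote gDNA ratio window, symmetric on the log scale
#: (2^-0.585 .. 2^0.585).
DEFAULT_HET_WINDOW = (0.67, 1.5)

#: A gDNA record whose minor peak is below this fraction of the total
#: signal is called homozygous.
DEFAULT_HOM_MINOR_FRAC = 0.10


class UndefinedRatioError(ValueError):
    """Raised when a peak pair cannot yield a finite positive ratio."""


@dataclass(frozen=True)
class AEIRecord:
    """A normalized allelic mRNA ratio at one marker for one sample."""

    sample_id: str
    snp_id: str
    amplicon_id: str
    ratio: float
    orientation: str = "ref_over_alt"
    n_gdna: int = 0

    def __post_init__(self):
        if not (self.ratio > 0 and math.isfinite(self.ratio)):
            raise UndefinedRatioError(f"ratio must be finite and > 0, got {self.ratio}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def log2_ratio(self) -> float:
        return math.log2(self.ratio)


def compute_raw_ratio(peak_a1: float, peak_a2: float) -> float:
    """Raw allelic ratio a1/a2 from two peak heights; both must be > 0."""
    if not (peak_a1 > 0 and peak_a2 > 0):
        raise UndefinedRatioError(
            f"both peaks must be > 0 for a defined ratio, got ({peak_a1}, {peak_a2})")
    return float(peak_a1) / float(peak_a2)


def normalize_aei(cdna_raw: float, gdna_raws: Sequence[float]) -> float:
    """cDNA allelic ratio normalized to the mean of the gDNA allelic ratios.

    The arithmetic mean of the raw gDNA ratios is used as the assay-bias
    reference (a geometric-mean variant differs only at second order in
    the noise; see the test suite for the documented comparison).
    """
    if not cdna_raw > 0:
        raise UndefinedRatioError(f"cDNA ratio must be > 0, got {cdna_raw}")
    gdna = [float(g) for g in gdna_raws]
    if len(gdna) == 0:
        raise ValueError("need at least one gDNA ratio for normalization")
    if any(g <= 0 for g in gdna):
        raise UndefinedRatioError("gDNA ratios must all be > 0")
    return cdna_raw / (sum(gdna) / len(gdna))


def orient_ratio(record: AEIRecord, target_orientation: str,
                 ref_is_major: bool) -> AEIRecord:
    """Re-express an AEI record in the requested allele orientation.

    ``ref_is_major`` is the major/minor designation of the marker in the
    analysis population.  Applying the same target twice is a no-op and a
    flip is an involution (the ratio is simply inverted).
    """
    if target_orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {target_orientation!r}")
    if ref_is_major is None:
        raise ValueError(f"{record.snp_id}: major/minor designation unavailable")

    def as_ref_over_alt(orientation: str) -> bool:
        # does this orientation put the ref allele in the numerator?
        if orientation == "ref_over_alt":
            return True
        if orientation == "major_over_minor":
            return ref_is_major
        return not ref_is_major

    if as_ref_over_alt(record.orientation) == as_ref_over_alt(target_orientation):
        new_ratio = record.ratio
    else:
        new_ratio = 1.0 / record.ratio
    return replace(record, ratio=new_ratio, orientation=target_orientation)


def gdna_qc(gdna_peaks: Sequence[tuple[float, float]],
            het_window: tuple[float, float] = DEFAULT_HET_WINDOW,
            hom_minor_frac: float = DEFAULT_HOM_MINOR_FRAC) -> str:
    """Classify a sample/SNP from its gDNA peak replicates.

    Returns ``het`` when both alleles are present and the mean ratio sits
    in the heterozygote window, ``hom`` when the minor peak carries less
    than ``hom_minor_frac`` of the total signal, ``cnv_suspect`` when both
    peaks are clearly present but the ratio falls outside the window
    (e.g. a duplicated allele giving ~2:1), and ``missing`` when no usable
    record exists.
    """
    usable = [(a, b) for a, b in gdna_peaks if (a > 0 or b > 0)]
    if not usable:
        return "missing"
    minor_fracs = [min(a, b) / (a + b) for a, b in usable]
    if float(np.mean(minor_fracs)) < hom_minor_frac:
        return "hom"
    ratios = [a / b for a, b in usable if a > 0 and b > 0]
    if not ratios:
        return "hom"
    lo, hi = het_window
    mean_ratio = float(np.mean(ratios))
    return "het" if lo <= mean_ratio <= hi else "cnv_suspect"


def summarize_timecourse(records: pd.DataFrame,
                         value_col: str = "ratio") -> pd.DataFrame:
    """Per-timepoint n, mean and SEM of allelic ratios (cotransfection kinetics).

    SEM of a single observation is reported as missing (NaN), not 0.
    """
    if "timepoint_hr" not in records.columns:
        raise ValueError("records need a timepoint_hr column")
    df = records.dropna(subset=["timepoint_hr"])
    if df.empty:
        raise ValueError("no records with a timepoint")
    out = (df.groupby("timepoint_hr")[value_col]
             .agg(n="count", mean="mean", sem=lambda v: v.sem(ddof=1))
             .reset_index())
    out.loc[out["n"] == 1, "sem"] = np.nan
    return out


# ---------------------------------------------------------------------------
# cohort-level pipeline
# ---------------------------------------------------------------------------

def quantify(peaks: pd.DataFrame,
             genotypes: GenotypeMatrix | None = None,
             amplicons: Sequence[AmpliconDef] = (),
             target_orientation: str = "ref_over_alt",
             het_window: tuple[float, float] = DEFAULT_HET_WINDOW,
             hom_minor_frac: float = DEFAULT_HOM_MINOR_FRAC) -> pd.DataFrame:
    """Turn a raw peak table into a per-(sample, marker, amplicon) AEI table.

    For every cDNA group the replicate raw ratios are averaged, then
    normalized to the arithmetic mean of the same sample's gDNA raw
    ratios at that marker; when a sample lacks gDNA replicates the
    marker-wide mean across heterozygous samples is used as a batch
    fallback and flagged in ``gdna_source``.  gDNA QC (het / hom /
    cnv_suspect) is attached; records that fail QC or have a non-positive
    peak are retained with a reason, never silently dropped.

    Output columns: sample_id, snp_id, amplicon_id, isoform_class, ratio,
    log2_ratio, orientation, n_gdna, qc_status, gdna_source.
    """
    amp_class = {a.amplicon_id: a.isoform_class for a in amplicons}
    majors = {}
    if genotypes is not None:
        for s in genotypes.snps:
            af = genotypes.alt_frequency(s.snp_id)
            majors[s.snp_id] = (af <= 0.5) if not math.isnan(af) else None

    gdna = peaks[peaks["material"] == "gDNA"]
    cdna = peaks[peaks["material"] == "cDNA"]

    gdna_ratios: dict[tuple[str, str], list[float]] = {}
    gdna_pairs: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (sid, snp), g in gdna.groupby(["sample_id", "snp_id"]):
        pairs = list(zip(g["peak_a1"].astype(float), g["peak_a2"].astype(float)))
        gdna_pairs[(sid, snp)] = pairs
        gdna_ratios[(sid, snp)] = [a / b for a, b in pairs if a > 0 and b > 0]

    qc_status = {key: gdna_qc(pairs, het_window, hom_minor_frac)
                 for key, pairs in gdna_pairs.items()}

    # batch fallback: marker-wide mean of het-sample gDNA ratios
    batch_mean: dict[str, float] = {}
    for (sid, snp), ratios in gdna_ratios.items():
        if ratios and qc_status[(sid, snp)] == "het":
            batch_mean.setdefault(snp, 0.0)
    for snp in batch_mean:
        vals = [r for (s, m), rs in gdna_ratios.items()
                if m == snp and qc_status[(s, m)] == "het" for r in rs]
        batch_mean[snp] = float(np.mean(vals))

    rows = []
    for (sid, snp, amp), g in cdna.groupby(["sample_id", "snp_id", "amplicon_id"]):
        raws = []
        any_bad = False
        for a, b in zip(g["peak_a1"].astype(float), g["peak_a2"].astype(float)):
            if a > 0 and b > 0:
                raws.append(a / b)
            else:
                any_bad = True
        row = {"sample_id": sid, "snp_id": snp, "amplicon_id": amp,
               "isoform_class": amp_class.get(amp, ""),
               "ratio": np.nan, "log2_ratio": np.nan,
               "orientation": target_orientation, "n_gdna": 0,
               "qc_status": qc_status.get((sid, snp), "missing"),
               "gdna_source": ""}
        if not raws:
            row["qc_status"] = "undefined_ratio"
            rows.append(row)
            continue
        cdna_raw = float(np.mean(raws))
        local = gdna_ratios.get((sid, snp), [])
        if local:
            norm = normalize_aei(cdna_raw, local)
            row["n_gdna"] = len(local)
            row["gdna_source"] = "sample"
        elif snp in batch_mean:
            norm = cdna_raw / batch_mean[snp]
            row["gdna_source"] = "batch"
        else:
            row["qc_status"] = "missing"
            rows.append(row)
            continue
        rec = AEIRecord(sid, snp, amp, norm, "ref_over_alt", row["n_gdna"])
        if target_orientation != "ref_over_alt":
            ref_major = majors.get(snp)
            if ref_major is None:
                # fall back to gDNA-implied designation unavailable: keep ref/alt
                row["orientation"] = "ref_over_alt"
            else:
                rec = orient_ratio(rec, target_orientation, ref_major)
        if any_bad and row["qc_status"] == "het":
            row["qc_status"] = "het_partial"
        row["ratio"] = rec.ratio
        row["log2_ratio"] = rec.log2_ratio
        row["orientation"] = rec.orientation
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "amplicon_id",
                                       "isoform_class", "ratio", "log2_ratio",
                                       "orientation", "n_gdna", "qc_status",
                                       "gdna_source"])


def usable_aei(aei: pd.DataFrame) -> pd.DataFrame:
    """AEI records that passed heterozygote QC and have a defined ratio."""
    ok = aei["qc_status"].isin(["het", "het_partial"]) & aei["ratio"].notna()
    return aei[ok]
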