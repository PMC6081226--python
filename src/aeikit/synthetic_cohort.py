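"""Synthetic cohorts with the statistical structure the AEI analysis assumes.

Each subject draws two haplotypes from an explicit pool (pairwise LD is a
*derived* property of the pool, never a target).  Per haplotype and
subject, transcription rate and proximal polyadenylation-site usage follow
the two-site forward model: a transcription variant multiplies T by
``beta_T`` and a usage variant shifts logit(f) by ``beta_f``; small
per-subject biological jitter on log T and logit f reproduces the
between-subject spread of true allelic ratios seen in tissue panels.
Observations are then generated with multiplicative log-normal noise on
SNaPshot peak heights, additive Gaussian noise on qPCR Ct values, and
additive Gaussian noise on haplotype-driven quantitative phenotypes.

A truth table records the realized noiseless haplotype parameters and
expected isoform abundances so recovery tests have an exact oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (AmpliconDef, GenotypeMatrix, SampleRecord, SnpDef,
                         validate_amplicon_markers, write_amplicons,
                         write_ct, write_genotypes, write_manifest, write_peaks,
                         write_phenotypes, write_samples)
from .isoform_model import logit

PRESETS = ("paper_like", "null", "strong_effect", "gwas_like")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort.

    ``haplotypes`` are allele strings over ``snps`` (one letter per SNP);
    ``hap_freqs`` must sum to 1.  ``beta_T`` is the multiplicative
    transcription effect of the alt allele at ``exp_snp`` (1.0 = none);
    ``beta_f`` the additive shift on logit(f) of the alt allele at
    ``apa_snp`` (0.0 = none); ``f0`` the baseline proximal-site usage.
    ``pheno_effects`` maps phenotype name -> {haplotype label at
    ``pheno_loci`` -> additive effect per copy}.
    """

    n_subjects: int
    snps: list[SnpDef]
    haplotypes: list[str]
    hap_freqs: list[float]
    amplicons: list[AmpliconDef]
    apa_snp: str | None = None
    exp_snp: str | None = None
    T_base: float = 1.0
    beta_T: float = 1.0
    f0: float = 0.3
    beta_f: float = 0.0
    sigma_peak: float = 0.15
    sigma_bio_t: float = 0.0
    sigma_bio_f: float = 0.0
    sigma_ct: float = 0.15
    sigma_pheno: float = 1.0
    pheno_loci: tuple[str, str] | None = None
    pheno_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    decay_ratio: float = 1.0      # turnover(long)/turnover(short); model assumes 1
    n_gdna_reps: int = 2
    n_cdna_reps: int = 2
    peak_scale: float = 1000.0
    gdna_background: float = 0.02
    ct_housekeeping: float = 20.0
    ct_anchor: float = 24.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if len(self.haplotypes) != len(self.hap_freqs) or not self.haplotypes:
            raise ConfigError("haplotypes and hap_freqs must align and be non-empty")
        if not math.isclose(sum(self.hap_freqs), 1.0, abs_tol=1e-9):
            raise ConfigError(
                f"haplotype frequencies sum to {sum(self.hap_freqs)}, not 1")
        if any(f < 0 for f in self.hap_freqs):
            raise ConfigError("haplotype frequencies must be >= 0")
        for h in self.haplotypes:
            if len(h) != len(self.snps):
                raise ConfigError(
                    f"haplotype {h!r} length != number of SNPs ({len(self.snps)})")
            for allele, snp in zip(h, self.snps):
                if allele not in (snp.ref_allele, snp.alt_allele):
                    raise ConfigError(
                        f"haplotype allele {allele!r} not among "
                        f"{snp.snp_id} alleles")
        if not 0 < self.f0 < 1:
            raise ConfigError(f"f0 must be in (0,1), got {self.f0}")
        if self.T_base <= 0 or self.beta_T <= 0:
            raise ConfigError("T_base and beta_T must be > 0")
        for name in ("sigma_peak", "sigma_bio_t", "sigma_bio_f",
                     "sigma_ct", "sigma_pheno"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.decay_ratio <= 0:
            raise ConfigError("decay_ratio must be > 0")
        validate_amplicon_markers(self.amplicons, self.snps)


@dataclass
class CohortData:
    """Everything simulate_cohort produces for one cohort."""

    config: SimConfig
    samples: list[SampleRecord]
    genotypes: GenotypeMatrix       # phased (the simulator knows the truth)
    peaks: pd.DataFrame
    ct: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


def simulate_cohort(config: SimConfig) -> CohortData:
    """Draw one cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    snp_ids = [s.snp_id for s in config.snps]
    n_snps = len(snp_ids)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    freqs = np.asarray(config.hap_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    hap_idx = rng.choice(len(config.haplotypes), size=(n, 2), p=freqs)

    # allele codes per haplotype (0 = ref, 1 = alt)
    alt_code = np.array([[1 if h[j] == config.snps[j].alt_allele else 0
                          for j in range(n_snps)]
                         for h in config.haplotypes], dtype=np.int8)
    a1 = alt_code[hap_idx[:, 0]]
    a2 = alt_code[hap_idx[:, 1]]
    genotypes = GenotypeMatrix(sample_ids, list(config.snps), a1.copy(), a2.copy(),
                               np.ones((n, n_snps), dtype=bool))

    # per-subject, per-haplotype biology
    if config.exp_snp is not None:
        j_exp = snp_ids.index(config.exp_snp)
        carries_T = np.stack([a1[:, j_exp], a2[:, j_exp]], axis=1).astype(float)
    else:
        carries_T = np.zeros((n, 2))
    if config.apa_snp is not None:
        j_apa = snp_ids.index(config.apa_snp)
        carries_f = np.stack([a1[:, j_apa], a2[:, j_apa]], axis=1).astype(float)
    else:
        carries_f = np.zeros((n, 2))

    T = (config.T_base * np.power(config.beta_T, carries_T)
         * np.exp(rng.normal(0.0, config.sigma_bio_t, size=(n, 2))))
    f = 1.0 / (1.0 + np.exp(-(logit(config.f0) + config.beta_f * carries_f
                              + rng.normal(0.0, config.sigma_bio_f, size=(n, 2)))))
    long_ab = T * (1.0 - f) / config.decay_ratio
    short_ab = T * f
    total_ab = long_ab + short_ab

    # phenotypes
    pheno = pd.DataFrame({"sample_id": sample_ids})
    pheno_means: dict[str, np.ndarray] = {}
    if config.pheno_effects:
        if config.pheno_loci is None:
            raise ConfigError("pheno_effects given without pheno_loci")
        j1 = snp_ids.index(config.pheno_loci[0])
        j2 = snp_ids.index(config.pheno_loci[1])
        hap_label = [h[j1] + h[j2] for h in config.haplotypes]
        for name, effects in config.pheno_effects.items():
            eff_by_hap = np.array([effects.get(lbl, 0.0) for lbl in hap_label])
            mean = eff_by_hap[hap_idx[:, 0]] + eff_by_hap[hap_idx[:, 1]]
            pheno_means[name] = mean
            pheno[name] = mean + rng.normal(0.0, config.sigma_pheno, size=n)

    # peak tables
    het = (a1 + a2) == 1
    ref_first = a1 == 0     # haplotype 1 carries the ref allele at this SNP
    peak_frames = []
    gdna_done: set[str] = set()
    for amp in config.amplicons:
        for snp_id in amp.markers_covered:
            j = snp_ids.index(snp_id)
            contrib = total_ab if amp.isoform_class == "ALL_ISOFORMS" else long_ab
            # gDNA: every sample, once per marker (assay shared across amplicons)
            if snp_id not in gdna_done:
                gdna_done.add(snp_id)
                ref_copies = 2.0 - (a1[:, j] + a2[:, j])
                alt_copies = (a1[:, j] + a2[:, j]).astype(float)
                for rep in range(config.n_gdna_reps):
                    noise = np.exp(rng.normal(0.0, config.sigma_peak, size=(n, 2)))
                    peak_frames.append(pd.DataFrame({
                        "sample_id": sample_ids,
                        "snp_id": snp_id,
                        "material": "gDNA",
                        "amplicon_id": amp.amplicon_id,
                        "peak_a1": config.peak_scale
                        * (ref_copies + config.gdna_background) * noise[:, 0],
                        "peak_a2": config.peak_scale
                        * (alt_copies + config.gdna_background) * noise[:, 1],
                        "replicate_id": f"g{rep + 1}",
                    }))
            # cDNA: heterozygous samples only
            idx = np.flatnonzero(het[:, j])
            if idx.size == 0:
                continue
            hap_of_ref = np.where(ref_first[idx, j], 0, 1)
            c_ref = contrib[idx, hap_of_ref]
            c_alt = contrib[idx, 1 - hap_of_ref]
            for rep in range(config.n_cdna_reps):
                noise = np.exp(rng.normal(0.0, config.sigma_peak,
                                          size=(idx.size, 2)))
                peak_frames.append(pd.DataFrame({
                    "sample_id": [sample_ids[i] for i in idx],
                    "snp_id": snp_id,
                    "material": "cDNA",
                    "amplicon_id": amp.amplicon_id,
                    "peak_a1": config.peak_scale * c_ref * noise[:, 0],
                    "peak_a2": config.peak_scale * c_alt * noise[:, 1],
                    "replicate_id": f"c{rep + 1}",
                }))
    peaks = pd.concat(peak_frames, ignore_index=True)
    peaks["timepoint_hr"] = np.nan

    # qPCR Ct table (long-3'UTR, total, housekeeping; duplicates)
    total_expr = total_ab.sum(axis=1)
    long_expr = long_ab.sum(axis=1)
    ct_rows = []
    for rep in range(2):
        noise = rng.normal(0.0, config.sigma_ct, size=(n, 3))
        ct_rows.append(pd.DataFrame({
            "sample_id": sample_ids, "assay": "PGK1",
            "ct": config.ct_housekeeping + noise[:, 0],
            "replicate_id": f"q{rep + 1}"}))
        ct_rows.append(pd.DataFrame({
            "sample_id": sample_ids, "assay": "TOTAL_SNCA",
            "ct": config.ct_anchor
            - np.log2(total_expr / (2 * config.T_base)) + noise[:, 1],
            "replicate_id": f"q{rep + 1}"}))
        ct_rows.append(pd.DataFrame({
            "sample_id": sample_ids, "assay": "LONG_3UTR",
            "ct": config.ct_anchor
            - np.log2(long_expr / (2 * config.T_base)) + noise[:, 2],
            "replicate_id": f"q{rep + 1}"}))
    ct = pd.concat(ct_rows, ignore_index=True)

    # sample descriptors (tissue-panel-like demographics)
    sexes = np.where(rng.random(n) < 0.85, "M", "F")
    ages = np.clip(rng.normal(36.1, 10.3, size=n), 18.0, None)
    samples = [SampleRecord(sid, "synthetic", str(sx), float(round(ag, 1)), "")
               for sid, sx, ag in zip(sample_ids, sexes, ages)]

    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "hap1": [config.haplotypes[k] for k in hap_idx[:, 0]],
        "hap2": [config.haplotypes[k] for k in hap_idx[:, 1]],
        "T1": T[:, 0], "T2": T[:, 1],
        "f1": f[:, 0], "f2": f[:, 1],
        "long1": long_ab[:, 0], "long2": long_ab[:, 1],
        "short1": short_ab[:, 0], "short2": short_ab[:, 1],
        "total1": total_ab[:, 0], "total2": total_ab[:, 1],
    })
    for name, mean in pheno_means.items():
        truth[f"pheno_mean_{name}"] = mean

    return CohortData(config, samples, genotypes, peaks, ct, pheno, truth)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_CHROM = "chr4"


def _snca_like_snps() -> list[SnpDef]:
    """Marker and candidate SNPs laid out like the SNCA 3'UTR / gene body.

    The gene sits on the genomic minus strand, so the proximal
    (short-isoform) end of the 3'UTR is at the higher coordinate; a SNP in
    the TOTAL_3UTR region is present in every isoform while one in the
    LONG_ONLY region is transcribed only when the distal polyA site is
    used.  All alleles are plus-strand G>A.
    """
    mk = lambda sid, pos, cls: SnpDef(sid, _CHROM, pos, "G", "A", cls)
    return [
        mk("rsAPA01", 90647418, "TOTAL_3UTR"),      # polyA-usage variant + marker
        mk("rsEXP01", 90646886, "LONG_ONLY_3UTR"),  # transcription variant + marker
        mk("rsTOT01", 90647400, "TOTAL_3UTR"),      # neutral all-isoform marker
        mk("rsN01", 90678000, "INTRONIC"),
        mk("rsN02", 90681000, "INTRONIC"),
        mk("rsN03", 90684000, "INTRONIC"),
        mk("rsN04", 90687000, "INTRONIC"),
        mk("rsN05", 90690000, "INTRONIC"),
    ]


def _snca_like_amplicons() -> list[AmpliconDef]:
    return [
        # short product around the proximal markers: all isoforms
        AmpliconDef("ampTotal", _CHROM, 90647350, 90647550, "ALL_ISOFORMS",
                    ("rsAPA01", "rsTOT01")),
        # 667 bp product spanning both markers: long isoforms only
        AmpliconDef("ampLong", _CHROM, 90646850, 90647517, "LONG_ONLY",
                    ("rsAPA01", "rsEXP01")),
    ]


#: Haplotype pool over [rsAPA01, rsEXP01, rsTOT01, rsN01..rsN05].  The
#: usage-variant minor allele (freq 0.13, its African MAF) always rides
#: with the transcription-variant major allele (D' ~ 1, low r^2, the two
#: minors on opposite haplotypes); decoys rsN01/rsN02 are partial proxies.
_PAPER_POOL = [
    ("AGGAGGGG", 0.065),
    ("AGAGGGGG", 0.065),
    ("GAGGAGGG", 0.10),
    ("GAAGGGGG", 0.10),
    ("GAGGAGGA", 0.10),
    ("GGGGGGGG", 0.20),
    ("GGAGGGGG", 0.17),
    ("GGAAGAGG", 0.03),
    ("GGGGGAAA", 0.17),
]

#: Default candidate list for the genotype-association scan (the two AEI
#: marker SNPs are the response and are not scanned against themselves).
SCAN_CANDIDATES = ["rsAPA01", "rsN01", "rsN02", "rsN03", "rsN04", "rsN05"]

# usage shift: baseline f = 0.3, alt-allele f = 0.6, i.e. a 1.75-fold
# allelic ratio of long isoforms -- the "up to twofold" tissue regime
_BETA_F_PAPER = logit(0.6) - logit(0.3)

_TABLE2_EFFECTS = {
    "immediate_recall": {"AG": -0.21, "GA": -0.09},
    "delayed_recall": {"AG": -0.17, "GA": -0.07},
}


def preset_config(name: str, n_subjects: int | None = None,
                  seed: int = 0) -> SimConfig:
    """Named study-condition presets for the generator."""
    if name in ("paper_like", "null", "strong_effect"):
        cfg = SimConfig(
            n_subjects=n_subjects or 200,
            snps=_snca_like_snps(),
            haplotypes=[h for h, _ in _PAPER_POOL],
            hap_freqs=[f for _, f in _PAPER_POOL],
            amplicons=_snca_like_amplicons(),
            apa_snp="rsAPA01", exp_snp="rsEXP01",
            beta_T=1.25, f0=0.3, beta_f=_BETA_F_PAPER,
            sigma_peak=0.15, sigma_bio_t=0.2, sigma_bio_f=0.3,
            sigma_ct=0.15, sigma_pheno=1.4,
            pheno_loci=("rsEXP01", "rsAPA01"),
            pheno_effects=_TABLE2_EFFECTS,
            seed=seed,
        )
        if name == "null":
            cfg = replace(cfg, beta_T=1.0, beta_f=0.0, pheno_effects={})
        elif name == "strong_effect":
            cfg = replace(cfg, beta_T=1.5, beta_f=logit(0.75) - logit(0.3))
        return cfg
    if name == "gwas_like":
        snps = [s for s in _snca_like_snps() if s.snp_id in ("rsAPA01", "rsEXP01")]
        amps = [AmpliconDef("ampLong", _CHROM, 90646850, 90647517, "LONG_ONLY",
                            ("rsAPA01", "rsEXP01")),
                AmpliconDef("ampTotal", _CHROM, 90647350, 90647550,
                            "ALL_ISOFORMS", ("rsAPA01",))]
        # haplotype strings over [rsAPA01, rsEXP01]; labels at pheno_loci
        # (rsEXP01, rsAPA01) reverse them, matching the frequency table
        # convention AG 0.24 / GA 0.16 / GG 0.60
        return SimConfig(
            n_subjects=n_subjects or 1000,
            snps=snps,
            haplotypes=["GA", "AG", "GG"],
            hap_freqs=[0.24, 0.16, 0.60],
            amplicons=amps,
            apa_snp="rsAPA01", exp_snp="rsEXP01",
            beta_T=1.25, f0=0.3, beta_f=_BETA_F_PAPER,
            sigma_peak=0.15, sigma_bio_t=0.2, sigma_bio_f=0.3,
            sigma_ct=0.15, sigma_pheno=1.4,
            pheno_loci=("rsEXP01", "rsAPA01"),
            pheno_effects=_TABLE2_EFFECTS,
            seed=seed,
        )
    raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")


def emit_fixture(config_name: str, out_dir, seed: int = 0,
                 n_subjects: int | None = None,
                 genotype_dialect: str = "vcf_subset") -> dict:
    """Simulate a named preset and write every on-disk format to ``out_dir``."""
    from pathlib import Path

    cfg = preset_config(config_name, n_subjects=n_subjects, seed=seed)
    cohort = simulate_cohort(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gpath = out / ("genotypes.vcf" if genotype_dialect == "vcf_subset"
                   else "genotypes.tsv")
    write_genotypes(cohort.genotypes, gpath, genotype_dialect)
    write_peaks(cohort.peaks, out / "peaks.tsv")
    write_ct(cohort.ct, out / "ct.tsv")
    write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
    write_amplicons(cfg.amplicons, out / "amplicons.bed")
    write_samples(cohort.samples, out / "samples.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    files = ["genotypes", "peaks.tsv", "ct.tsv", "phenotypes.tsv",
             "amplicons.bed", "samples.tsv", "truth.tsv"]
    write_manifest(out, {"preset": config_name, "n_subjects": cfg.n_subjects},
                   seed, [gpath] + [out / f for f in files[1:]])
    return {"config": cfg, "dir": out}
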