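# Methods

## The measurement and its normalization

SNaPshot primer extension yields two allele-specific fluorescent peak
heights per sample, marker SNP, material (gDNA or cDNA) and amplicon. The
raw allelic ratio is `peak_ref / peak_alt`; ratios with a non-positive
peak are undefined and the record is flagged, never silently dropped. The
cDNA ratio of a heterozygote is divided by the **arithmetic mean** of that
sample's raw gDNA ratios — gDNA is 1:1 by construction, so the quotient
cancels allele-specific assay bias (dye efficiency, extension bias). A
geometric-mean normalizer would differ only at second order in the assay
noise (~0.5% for 10% noise; the test suite documents the comparison), but
the arithmetic mean of measured gDNA ratios is the procedure this package
implements. Downstream statistics use log2 ratios; raw ratios are for
display.

When a sample lacks gDNA replicates, the marker-wide mean across
heterozygous samples is used as a batch fallback and flagged
(`gdna_source=batch`). gDNA QC classifies each sample/marker as `het`
(mean ratio within [0.67, 1.5], symmetric ±0.585 on the log2 scale), `hom`
(minor peak < 10% of total signal) or `cnv_suspect` (clear biallelic peaks
with a ratio outside the window, e.g. an allele duplication near 2:1).
The window and hom threshold are conservative defaults; both are
parameters.

## Two-polyadenylation-site isoform model

Haplotype *h* transcribes at rate `T_h > 0` and routes each transcript to
the proximal polyA site with probability `f_h ∈ (0,1)`. Under equal
turnover of short and long isoforms, allelic ratios by amplicon class are

- `R_total = T1/T2`,
- `R_long = T1(1−f1) / (T2(1−f2))`,
- `R_short = T1 f1 / (T2 f2)` (model-internal: no amplicon can measure
  only short isoforms, since their sequence is contained in the long ones).

`U = R_long / R_total = (1−f1)/(1−f2)` isolates the usage shift;
`solve_f_shift` anchors it to absolute fractions given a baseline `f2`,
feasible only when `U(1−f2) < 1`. The model deliberately collapses all
proximal polyA sites into one short class: real 3′UTRs may use several
proximal sites, but every analysis here dichotomizes short vs long. The
equal-turnover assumption is the model's main biological caveat; the
simulator has a `decay_ratio` knob (turnover long / turnover short,
default 1) to probe sensitivity, and the inference intentionally ignores
it.

ΔΔCt quantification of the relative long-isoform share assumes a
per-cycle amplification factor of 2.0 (100% efficiency) for all assays;
an `efficiency` parameter is exposed because this is the single largest
systematic in ΔΔCt work. The housekeeping terms cancel algebraically in
`2^−(Ct_long − Ct_total)`, but the housekeeping assay is still required
per sample so that incomplete plates are flagged rather than silently
computed.

## Association scan

The response per sample is the mean **magnitude** |log2 AEI| over records
of the requested amplicon class. Magnitude is used because in unphased
tissue data the marker heterozygote's phase relative to a candidate
allele is unknown; a cis variant then manifests as larger AEI in its
heterozygous carriers regardless of sign, and the scan is invariant to a
global orientation flip. The default grouping is het vs hom (phase-free);
a three-genotype ANOVA is available and is usually more powerful for
additive effects. F and p come from one-way ANOVA (with two groups, F is
exactly the squared pooled-variance t). Bonferroni's multiplier is the
number of tests actually performed, not the number requested; p-values
are floored at the smallest positive double and never reported as 0.
Identical values across groups give p = 1; zero within-group variance
with differing means reports the floor.

The paired gDNA-vs-cDNA test (establishing AEI at a marker beyond assay
noise) is a paired t-test of per-sample log2 cDNA vs log2 gDNA ratios,
with an exclusion list so a known large-effect variant's heterozygotes
can be removed when isolating a second, moderate signal.

## Haplotypes and LD

Phased genotypes are counted directly. Unphased two-locus genotypes are
ambiguous only for double heterozygotes; EM iterates posterior phase
weights and frequency updates until the largest frequency change is
below 1e-8 (≤1000 iterations), with the log-likelihood asserted
non-decreasing at every step. A brute-force coarse-to-fine grid search
over the frequency simplex (`grid_ml_frequencies`, final resolution
2e-5) serves as an independent maximum-likelihood reference; EM matches
it to better than 1e-4 on random cohorts.

LD uses the standard definitions: `D = p(AB) − p(A)p(B)`,
`D′ = |D|/Dmax`, `r² = D²/(pA pa pB pb)`. Association regresses the
phenotype on per-subject haplotype dosages (EM posterior expectations for
unphased double heterozygotes — no hard assignment), omitting the most
frequent haplotype as baseline; collinear designs (only two haplotypes
present) are reduced and noted. A consistency check flags subjects whose
joint genotype is impossible without a haplotype rarer than a configurable
floor — with three common haplotypes, a double-minor homozygote is a
genotyping-error candidate.

## Synthetic cohorts: what they emulate, and what they do not

Each subject draws two haplotypes from an explicit pool; LD among
candidate SNPs is whatever the pool implies. The default `paper_like`
conditions: usage-variant allele frequency 0.13 (its frequency in African
populations), transcription-variant allele 0.30, the two minor alleles on
opposite haplotypes (D′ ≈ 1, r² ≈ 0.06), n = 200 subjects, five intronic
decoy candidates in weak-to-moderate LD (the strongest at r² ≈ 0.29,
chosen so the scan's runner-up p lands near the published table's 0.018
vs 3.1e-5 gap), and a neutral all-isoform marker SNP. Effects:
`f` 0.3 → 0.6 for the usage allele (long-isoform allelic ratio 1.75, the
"up to twofold" tissue regime) and `beta_T = 1.25` for the transcription
allele (moderate AEI).

Measurement noise is multiplicative log-normal on peak heights
(`sigma_peak = 0.15` on the natural-log scale — fluorescence areas are
strictly positive and heteroscedastic) and additive Gaussian on Ct values
(`sigma_ct = 0.15`). Two per-subject **biological variability** terms,
`sigma_bio_t = 0.2` on log T and `sigma_bio_f = 0.3` on logit f, give
true allelic ratios the between-subject spread real tissue panels show;
their magnitudes were derived once from the observed dual-marker
concordance (R² ≈ 0.65 across compound heterozygotes) together with the
measurement-noise arithmetic: two markers on one amplicon measure the
same transcript pool, so R² ≈ (σ²_signal/(σ²_signal+σ²_noise))², and with
duplicate averaging σ²_noise ≈ 0.047 (log2), requiring σ_signal ≈ 0.45
log2-units. Without these terms every compound heterozygote would have an
identical expected ratio and cross-marker concordance would be noise
against noise.

Phenotypes are additive per haplotype copy at two designated loci plus
Gaussian noise. The `gwas_like` preset reproduces the published haplotype
frequency setting (AG 0.24 / GA 0.16 / GG 0.60, n = 1000) with effects
−0.21 / −0.09 (immediate recall) and −0.17 / −0.07 (delayed recall) and
`sigma_pheno = 1.4`, which puts ~80% power on the AG effect and leaves
the GA effect usually non-significant — the qualitative pattern the
haplotype table shows. The `null` preset zeroes all three effect types,
and `strong_effect` raises them (f 0.3 → 0.75, beta_T 1.5).

What the generator does **not** emulate: technical replicates are
independent draws (real duplicate extractions share within-sample
variance, so replicate agreement here is slightly optimistic); no
read-level or sequence-level simulation; no population structure beyond
the haplotype pool; phenotype effects are strictly additive. Passing
recovery tests therefore demonstrate correctness of the estimators under
this generative model, not robustness to correlated technical error or
non-additive genetics.

## Numerical choices

- One `numpy` Generator seeded once per cohort drives every draw; no
  per-module reseeding, so outputs are byte-identical across runs.
- The usage effect is parameterized on logit(f), keeping f in (0,1) for
  any effect size. `beta_T` is the multiplicative factor itself (1 = no
  effect).
- SEM of a single observation is reported missing, not 0.
- EM initializes at linkage equilibrium of the observed marginals; the
  two-locus likelihood is unimodal in practice and the grid reference
  guards against boundary pathologies (frequencies clipped at 1e-12 for
  the first iteration only).
- The grid search tolerates 1e-9 of simplex round-off so boundary optima
  (an absent haplotype) are not excluded by floating-point error.
- Scan ties are broken by stable sort on p, so ranks are reproducible.

## Problem sizes

Simulation-based checks use 100 cohorts of n = 200 for scan recovery and
null calibration, 50 random cohorts of n = 80 for EM validation, and
n = 1000 cohorts for haplotype-effect recovery — sizes at which the
binomial uncertainty of the reported rates (±3–5%) is small relative to
the margins being asserted.

## Known limitations

- The magnitude-based scan response loses power relative to a signed,
  phase-aware analysis when phase is actually known; the signed option
  exists but is off by default.
- Bonferroni over correlated tests is conservative; no permutation-based
  FWER control is provided.
- The EM path covers exactly two loci; longer haplotypes are out of scope.
- LD statistics are point estimates without confidence intervals.
- `R_short` is a model output only; nothing in the data directly
  constrains short-isoform allelic ratios.
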