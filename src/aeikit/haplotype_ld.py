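"""Two-locus haplotype frequencies, linkage disequilibrium, and phenotype
association.

Haplotype frequencies come from direct chromosome counting when calls are
phased, and from the classic expectation–maximization over the
double-heterozygote phase ambiguity when they are not.  LD is summarized
as D, D' and r-squared.  Haplotype–phenotype association regresses a
quantitative score on per-subject haplotype dosages (EM posterior
expectations when unphased) with the most frequent haplotype as baseline.

Haplotype labels are written locus-major in the order given in ``loci``,
using each SNP's actual allele letters (e.g. ``"AG"`` = alt of locus 1
with ref of locus 2 when those are the A and G bases).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import GenotypeMatrix, MISSING

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeTable:
    """Two-locus haplotype frequencies.

    ``freqs`` maps a two-letter haplotype label (allele of locus 1 then
    locus 2) to a frequency; the four labels cover ref/alt at both loci.
    """

    loci: tuple[str, str]
    freqs: dict[str, float]
    n_chromosomes: int
    method: str                      # {"counted", "EM"}
    loglik: float | None = None      # EM final log-likelihood
    alleles: tuple[tuple[str, str], tuple[str, str]] = ((".", "."), (".", "."))

    def __post_init__(self):
        total = sum(self.freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        if any(f < -1e-12 for f in self.freqs.values()):
            raise ValueError("negative haplotype frequency")

    def label(self, i: int, j: int) -> str:
        """Label of the haplotype carrying allele-code i at locus 1, j at 2."""
        return self.alleles[0][i] + self.alleles[1][j]

    def freq_array(self) -> np.ndarray:
        """Frequencies as a 2x2 array indexed [allele1][allele2] (0=ref)."""
        return np.array([[self.freqs[self.label(i, j)] for j in (0, 1)]
                         for i in (0, 1)])

    def rare(self, floor: float = 0.01) -> list[str]:
        return [h for h, f in self.freqs.items() if 0 <= f < floor]


@dataclass(frozen=True)
class LDStats:
    """Linkage disequilibrium between two biallelic loci."""

    D: float
    D_prime: float
    r_squared: float
    allele_freqs: dict[str, float]


def _genotype_counts(gm: GenotypeMatrix, loci: tuple[str, str]):
    j1, j2 = gm.snp_index(loci[0]), gm.snp_index(loci[1])
    a = np.stack([gm.a1[:, j1], gm.a2[:, j1]], axis=1)
    b = np.stack([gm.a1[:, j2], gm.a2[:, j2]], axis=1)
    ph = gm.phased[:, j1] & gm.phased[:, j2]
    ok = (a != MISSING).all(axis=1) & (b != MISSING).all(axis=1)
    return a[ok], b[ok], ph[ok], ok


def estimate_haplotypes(gm: GenotypeMatrix, loci: tuple[str, str],
                        rare_floor: float = 0.01) -> HaplotypeTable:
    """Estimate two-locus haplotype frequencies.

    Fully phased input is counted directly; otherwise the EM algorithm
    resolves the double-heterozygote ambiguity to maximum-likelihood
    frequencies (convergence when the largest frequency change is below
    1e-8, at most 1000 iterations).  A monomorphic locus still yields a
    (degenerate) table.  Haplotypes below ``rare_floor`` are reported but
    can be listed via :meth:`HaplotypeTable.rare`.
    """
    s1 = gm.snps[gm.snp_index(loci[0])]
    s2 = gm.snps[gm.snp_index(loci[1])]
    alleles = ((s1.ref_allele, s1.alt_allele), (s2.ref_allele, s2.alt_allele))
    a, b, ph, _ = _genotype_counts(gm, loci)
    if a.shape[0] == 0:
        raise ValueError("no sample genotyped at both loci")
    label = lambda i, j: alleles[0][i] + alleles[1][j]
    if bool(ph.all()):
        counts = np.zeros((2, 2))
        for chrom in (0, 1):
            for i in (0, 1):
                for j in (0, 1):
                    counts[i, j] += int(((a[:, chrom] == i) & (b[:, chrom] == j)).sum())
        n_chrom = int(counts.sum())
        freqs = {label(i, j): float(counts[i, j] / n_chrom)
                 for i in (0, 1) for j in (0, 1)}
        return HaplotypeTable(loci, freqs, n_chrom, "counted", None, alleles)
    d1 = a.sum(axis=1)   # alt dosage locus 1
    d2 = b.sum(axis=1)
    p, loglik = _em_two_locus(d1, d2)
    freqs = {label(i, j): float(p[i, j]) for i in (0, 1) for j in (0, 1)}
    return HaplotypeTable(loci, freqs, 2 * len(d1), "EM", loglik, alleles)


def _loglik(n: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 dosage table under hap freqs p."""
    ll = 0.0
    for d1 in (0, 1, 2):
        for d2 in (0, 1, 2):
            if n[d1, d2] == 0:
                continue
            prob = _genotype_prob(p, d1, d2)
            if prob <= 0:
                return -math.inf
            ll += n[d1, d2] * math.log(prob)
    return ll


def _genotype_prob(p: np.ndarray, d1: int, d2: int) -> float:
    """P(unphased two-locus genotype) as a sum over consistent hap pairs."""
    prob = 0.0
    for i1, i2 in itertools.product((0, 1), repeat=2):
        if i1 + i2 != d1:
            continue
        for j1, j2 in itertools.product((0, 1), repeat=2):
            if j1 + j2 != d2:
                continue
            # ordered pair (h1=(i1,j1), h2=(i2,j2)); ordered sum double-counts
            # unordered heterozygous pairs, which is exactly the multiplicity 2
            prob += p[i1, j1] * p[i2, j2]
    # each unordered pair counted twice except identical haplotypes... the
    # ordered sum IS the correct genotype probability (2pq appears as pq+qp)
    return prob


def _em_two_locus(d1: np.ndarray, d2: np.ndarray):
    """EM for two-locus haplotype frequencies from unphased dosages."""
    n = np.zeros((3, 3))
    for x, y in zip(d1, d2):
        n[int(x), int(y)] += 1
    n_chrom = 2 * n.sum()
    # initialize at linkage equilibrium from the marginals
    p1 = (n[1, :].sum() + 2 * n[2, :].sum()) / n_chrom  # alt freq locus 1
    p2 = (n[:, 1].sum() + 2 * n[:, 2].sum()) / n_chrom
    p = np.array([[(1 - p1) * (1 - p2), (1 - p1) * p2],
                  [p1 * (1 - p2), p1 * p2]])
    p = np.clip(p, 1e-12, None)
    p /= p.sum()
    prev_ll = -math.inf
    for _ in range(EM_MAX_ITER):
        # E-step: expected haplotype counts
        c = np.zeros((2, 2))
        # unambiguous contributions
        for dd1 in (0, 1, 2):
            for dd2 in (0, 1, 2):
                cnt = n[dd1, dd2]
                if cnt == 0 or (dd1 == 1 and dd2 == 1):
                    continue
                i_alleles = [0, 0] if dd1 == 0 else [1, 1] if dd1 == 2 else [0, 1]
                j_alleles = [0, 0] if dd2 == 0 else [1, 1] if dd2 == 2 else [0, 1]
                if dd1 == 1:
                    j = j_alleles[0]
                    c[0, j] += cnt
                    c[1, j] += cnt
                elif dd2 == 1:
                    i = i_alleles[0]
                    c[i, 0] += cnt
                    c[i, 1] += cnt
                else:
                    c[i_alleles[0], j_alleles[0]] += 2 * cnt
        ndh = n[1, 1]
        if ndh > 0:
            w_cis = p[0, 0] * p[1, 1]
            w_trans = p[0, 1] * p[1, 0]
            tot = w_cis + w_trans
            post = 0.5 if tot == 0 else w_cis / tot
            c[0, 0] += ndh * post
            c[1, 1] += ndh * post
            c[0, 1] += ndh * (1 - post)
            c[1, 0] += ndh * (1 - post)
        new_p = c / n_chrom
        ll = _loglik(n, new_p)
        if ll < prev_ll - 1e-9:
            raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
        delta = float(np.abs(new_p - p).max())
        p = new_p
        prev_ll = ll
        if delta < EM_TOL:
            return p, ll
    raise RuntimeError(f"EM did not converge within {EM_MAX_ITER} iterations "
                       f"(last max change {delta:.2e})")


def grid_ml_frequencies(d1, d2, coarse: float = 0.02,
                        refinements: int = 3) -> np.ndarray:
    """Brute-force maximum-likelihood haplotype frequencies on a simplex grid.

    Validation utility, fully independent of the EM path: scans the
    3-simplex of (p00, p01, p10) on a coarse grid and refines around the
    best point.  Final resolution ~ ``coarse / 10**refinements``.
    """
    n = np.zeros((3, 3))
    for x, y in zip(np.asarray(d1, dtype=int), np.asarray(d2, dtype=int)):
        n[x, y] += 1

    def ll_of(p00, p01, p10):
        p11 = 1.0 - p00 - p01 - p10
        ok = p11 >= -1e-9      # tolerate round-off on the simplex boundary
        ll = np.full(p00.shape, -np.inf)
        if not ok.any():
            return ll
        p = [p00[ok], p01[ok], p10[ok], np.clip(p11[ok], 0.0, None)]
        sub = np.zeros(p[0].shape)
        for dd1 in (0, 1, 2):
            for dd2 in (0, 1, 2):
                cnt = n[dd1, dd2]
                if cnt == 0:
                    continue
                prob = np.zeros_like(sub)
                for i1 in (0, 1):
                    i2 = dd1 - i1
                    if i2 not in (0, 1):
                        continue
                    for j1 in (0, 1):
                        j2 = dd2 - j1
                        if j2 not in (0, 1):
                            continue
                        prob = prob + p[2 * i1 + j1] * p[2 * i2 + j2]
                with np.errstate(divide="ignore"):
                    sub = sub + cnt * np.log(prob)
        ll[ok] = sub
        return ll

    lo = np.zeros(3)
    hi = np.ones(3)
    step = coarse
    best = None
    for _ in range(refinements + 1):
        axes = [np.arange(lo[k], hi[k] + step / 2, step) for k in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        flat = [x.ravel() for x in g]
        ll = ll_of(*flat)
        k = int(np.argmax(ll))
        best = np.array([flat[0][k], flat[1][k], flat[2][k]])
        lo = np.clip(best - 2 * step, 0, 1)
        hi = np.clip(best + 2 * step, 0, 1)
        step /= 10.0
    p11 = 1.0 - best.sum()
    return np.array([[best[0], best[1]], [best[2], max(p11, 0.0)]])


def ld_stats(table: HaplotypeTable) -> LDStats:
    """D, D' and r-squared from a two-locus haplotype table.

    With A/a the alt/ref alleles of locus 1 and B/b of locus 2:
    D = p(AB) - p(A) p(B); D' = |D| / Dmax with Dmax = min(pA pb, pa pB)
    for D > 0 and min(pA pB, pa pb) for D < 0; r^2 = D^2 / (pA pa pB pb).
    Both loci must be polymorphic.
    """
    p = table.freq_array()
    pA = p[1, :].sum()   # alt allele, locus 1
    pB = p[:, 1].sum()
    pa, pb = 1 - pA, 1 - pB
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("LD undefined for a monomorphic locus")
    D = p[1, 1] - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        dmax = 1.0
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * pa * pB * pb)
    a1, a2 = table.alleles
    return LDStats(float(D), float(d_prime), float(r2),
                   {f"{table.loci[0]}:{a1[1]}": float(pA),
                    f"{table.loci[0]}:{a1[0]}": float(pa),
                    f"{table.loci[1]}:{a2[1]}": float(pB),
                    f"{table.loci[1]}:{a2[0]}": float(pb)})


def haplotype_dosages(gm: GenotypeMatrix, table: HaplotypeTable) -> pd.DataFrame:
    """Per-subject expected haplotype dosage (0/1/2 copies of each haplotype).

    Phased subjects are counted directly.  For unphased double
    heterozygotes the EM posterior splits one copy of each phase
    configuration according to the estimated frequencies; all other
    genotypes are unambiguous.
    """
    loci = table.loci
    a, b, ph, ok = _genotype_counts(gm, loci)
    samples = [s for s, keep in zip(gm.samples, ok) if keep]
    p = table.freq_array()
    labels = [table.label(i, j) for i in (0, 1) for j in (0, 1)]
    out = np.zeros((len(samples), 4))
    for row in range(len(samples)):
        if ph[row]:
            for chrom in (0, 1):
                idx = 2 * int(a[row, chrom]) + int(b[row, chrom])
                out[row, idx] += 1
            continue
        d1, d2 = int(a[row].sum()), int(b[row].sum())
        if d1 == 1 and d2 == 1:
            w_cis = p[0, 0] * p[1, 1]
            w_trans = p[0, 1] * p[1, 0]
            tot = w_cis + w_trans
            post = 0.5 if tot == 0 else w_cis / tot
            out[row, 0] += post          # ref-ref
            out[row, 3] += post          # alt-alt
            out[row, 1] += 1 - post
            out[row, 2] += 1 - post
        else:
            i_pair = (0, 0) if d1 == 0 else (1, 1) if d1 == 2 else (0, 1)
            j_pair = (0, 0) if d2 == 0 else (1, 1) if d2 == 2 else (0, 1)
            if d1 == 1:
                j = j_pair[0]
                out[row, 0 + j] += 1
                out[row, 2 + j] += 1
            elif d2 == 1:
                i = i_pair[0]
                out[row, 2 * i] += 1
                out[row, 2 * i + 1] += 1
            else:
                out[row, 2 * i_pair[0] + j_pair[0]] += 2
    return pd.DataFrame(out, index=samples, columns=labels)


def haplotype_association(dosages: pd.DataFrame, phenotype: pd.Series,
                          table: HaplotypeTable,
                          baseline: str | None = None) -> pd.DataFrame:
    """Linear regression of a quantitative phenotype on haplotype dosages.

    The baseline haplotype (default: most frequent) is omitted from the
    design; each remaining haplotype present in the cohort gets an
    additive effect per copy relative to baseline, with a Wald p-value.
    Returns one row per haplotype including the baseline (effect 0,
    ``baseline_flag`` set).  Haplotypes absent from every subject are
    reported with missing effects.
    """
    common = [s for s in dosages.index if s in phenotype.index]
    if len(common) < 3:
        raise ValueError("need >= 3 subjects with phenotype")
    X_all = dosages.loc[common]
    y = phenotype.loc[common].astype(float)
    if baseline is None:
        baseline = max(table.freqs, key=table.freqs.get)
    cols = [h for h in X_all.columns
            if h != baseline and X_all[h].to_numpy().std() > 0]
    note = ""
    if not cols:
        raise ValueError("no polymorphic non-baseline haplotype: not testable")
    X = sm.add_constant(X_all[cols].to_numpy())
    # guard against exact collinearity (e.g. only two haplotypes present)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        cols = cols[: rank - 1]
        X = sm.add_constant(X_all[cols].to_numpy())
        note = "reduced model (collinear dosages)"
    fit = sm.OLS(y.to_numpy(), X).fit()
    rows = []
    for h in dosages.columns:
        freq = table.freqs.get(h, 0.0)
        if h == baseline:
            rows.append({"haplotype": h, "frequency": freq, "effect": 0.0,
                         "se": np.nan, "p_value": np.nan,
                         "baseline_flag": True, "note": note})
        elif h in cols:
            k = cols.index(h) + 1
            rows.append({"haplotype": h, "frequency": freq,
                         "effect": float(fit.params[k]),
                         "se": float(fit.bse[k]),
                         "p_value": float(fit.pvalues[k]),
                         "baseline_flag": False, "note": note})
        else:
            rows.append({"haplotype": h, "frequency": freq, "effect": np.nan,
                         "se": np.nan, "p_value": np.nan,
                         "baseline_flag": False,
                         "note": "absent or constant in cohort"})
    return pd.DataFrame(rows)


def haplotype_consistency_check(gm: GenotypeMatrix, table: HaplotypeTable,
                                rare_floor: float = 0.01) -> pd.DataFrame:
    """Flag subjects whose joint genotype requires a rare haplotype.

    With only three common haplotypes, some two-locus genotypes (e.g.
    homozygous for both minor alleles) are impossible without the rare
    fourth haplotype; such subjects are genotyping-error candidates.
    Returns the flagged subjects with the rare haplotype each implies.
    """
    rare = set(table.rare(rare_floor))
    if not rare:
        return pd.DataFrame(columns=["sample_id", "required_haplotype"])
    common = [h for h in table.freqs if h not in rare]
    a, b, ph, ok = _genotype_counts(gm, table.loci)
    samples = [s for s, keep in zip(gm.samples, ok) if keep]
    labels = [[table.label(i, j) for j in (0, 1)] for i in (0, 1)]
    rows = []
    for row, sid in enumerate(samples):
        d1, d2 = int(a[row].sum()), int(b[row].sum())
        feasible = False
        need: set[str] = set()
        for i1 in (0, 1):
            i2 = d1 - i1
            if i2 not in (0, 1):
                continue
            for j1 in (0, 1):
                j2 = d2 - j1
                if j2 not in (0, 1):
                    continue
                pair = {labels[i1][j1], labels[i2][j2]}
                if pair <= set(common):
                    feasible = True
                else:
                    need |= (pair - set(common))
        if not feasible:
            rows.append({"sample_id": sid,
                         "required_haplotype": ",".join(sorted(need))})
    return pd.DataFrame(rows, columns=["sample_id", "required_haplotype"])
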