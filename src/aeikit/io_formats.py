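"""Readers and writers for the on-disk formats used across the package.

All tabular inputs are UTF-8, tab-delimited text with a header row.
Genotypes come either as a wide TSV (with ``##SNP`` header lines carrying
the variant definitions) or as a minimal VCFv4.2 subset restricted to the
eight fixed columns plus ``FORMAT=GT``.  Amplicons are BED intervals
(0-based, half-open) with the isoform class in column 5 and the covered
marker SNPs in column 6.  Readers validate and reject; they never coerce
silently, and round-tripping through a writer and back is the identity.

Coordinate conventions are never mixed: :class:`SnpDef.pos` is 1-based
(VCF convention), :class:`AmpliconDef` intervals are 0-based half-open
(BED convention), and containment tests use ``pos - 1 in [start, end)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

REGION_CLASSES = frozenset({"TOTAL_3UTR", "LONG_ONLY_3UTR", "INTRONIC", "OTHER"})
ISOFORM_CLASSES = frozenset({"ALL_ISOFORMS", "LONG_ONLY"})
MATERIALS = frozenset({"gDNA", "cDNA"})

PEAK_COLUMNS = ["sample_id", "snp_id", "material", "amplicon_id",
                "peak_a1", "peak_a2", "replicate_id", "timepoint_hr"]
CT_COLUMNS = ["sample_id", "assay", "ct", "replicate_id"]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


class FormatValidationError(ValueError):
    """Structurally parseable input that violates a field constraint."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    cohort: str = ""
    sex: str = "unknown"          # {M, F, unknown}
    age: float | None = None      # years, >= 0 or missing
    diagnosis: str = ""

    def __post_init__(self):
        if self.sex not in {"M", "F", "unknown"}:
            raise FormatValidationError(f"sex must be M/F/unknown, got {self.sex!r}")
        if self.age is not None and not (self.age >= 0):
            raise FormatValidationError(f"age must be missing or >= 0, got {self.age}")


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP; alleles are plus-strand bases, pos is 1-based."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    region_class: str = "OTHER"

    def __post_init__(self):
        if self.pos < 1:
            raise FormatValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise FormatValidationError(f"{self.snp_id}: ref and alt alleles identical")
        if self.region_class not in REGION_CLASSES:
            raise FormatValidationError(
                f"{self.snp_id}: unknown region_class {self.region_class!r}")


@dataclass(frozen=True)
class AmpliconDef:
    """A PCR amplicon; BED interval, tagged by the isoform class it captures."""

    amplicon_id: str
    chrom: str
    start: int   # 0-based inclusive
    end: int     # 0-based exclusive
    isoform_class: str
    markers_covered: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.start < self.end:
            raise FormatValidationError(
                f"{self.amplicon_id}: start must be < end ({self.start}, {self.end})")
        if self.isoform_class not in ISOFORM_CLASSES:
            raise FormatValidationError(
                f"{self.amplicon_id}: unknown isoform_class {self.isoform_class!r}")

    def contains(self, snp: SnpDef) -> bool:
        """True if the marker position lies inside the amplicon interval."""
        return self.chrom == snp.chrom and self.start <= snp.pos - 1 < self.end


MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Genotype calls for ``samples`` x ``snps``.

    ``a1``/``a2`` hold allele codes (0 = ref, 1 = alt, -1 = missing) per
    chromosome; for unphased calls the order of a1/a2 is arbitrary and the
    ``phased`` flag is False.  Dosage is the ALT-allele count.
    """

    samples: list[str]
    snps: list[SnpDef]
    a1: np.ndarray
    a2: np.ndarray
    phased: np.ndarray

    def __post_init__(self):
        n, m = len(self.samples), len(self.snps)
        for name in ("a1", "a2", "phased"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise FormatValidationError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}")
        if len(set(self.samples)) != n:
            raise FormatValidationError("duplicate sample_id in GenotypeMatrix")
        if len({s.snp_id for s in self.snps}) != m:
            raise FormatValidationError("duplicate snp_id in GenotypeMatrix")

    # -- access helpers -----------------------------------------------------

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"snp {snp_id!r} not in genotype matrix") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        """ALT-allele count per sample (float, NaN where missing)."""
        j = self.snp_index(snp_id)
        a1, a2 = self.a1[:, j], self.a2[:, j]
        d = (a1 + a2).astype(float)
        d[(a1 == MISSING) | (a2 == MISSING)] = np.nan
        return d

    def is_het(self, snp_id: str) -> np.ndarray:
        j = self.snp_index(snp_id)
        return (self.a1[:, j] + self.a2[:, j]) == 1

    def call_string(self, i: int, j: int) -> str:
        a1, a2 = self.a1[i, j], self.a2[i, j]
        if a1 == MISSING or a2 == MISSING:
            return "./."
        sep = "|" if self.phased[i, j] else "/"
        if not self.phased[i, j]:
            a1, a2 = sorted((int(a1), int(a2)))
        return f"{a1}{sep}{a2}"

    def alt_frequency(self, snp_id: str) -> float:
        d = self.dosage(snp_id)
        d = d[~np.isnan(d)]
        if d.size == 0:
            return float("nan")
        return float(d.sum() / (2 * d.size))

    def unphased(self) -> "GenotypeMatrix":
        """A copy with all phase information discarded."""
        lo = np.minimum(self.a1, self.a2)
        hi = np.maximum(self.a1, self.a2)
        miss = (self.a1 == MISSING) | (self.a2 == MISSING)
        lo = lo.copy()
        hi = hi.copy()
        lo[miss] = MISSING
        hi[miss] = MISSING
        return GenotypeMatrix(list(self.samples), list(self.snps), lo, hi,
                              np.zeros_like(self.phased))


def _parse_call(token: str, where: tuple) -> tuple[int, int, bool]:
    token = token.strip()
    if token in {"./.", ".|.", ".", ""}:
        return (int(MISSING), int(MISSING), False)
    phased = "|" in token
    sep = "|" if phased else "/"
    parts = token.split(sep)
    if len(parts) != 2 or not all(p in {"0", "1"} for p in parts):
        raise ParseError(f"bad genotype call {token!r}", *where)
    return (int(parts[0]), int(parts[1]), phased)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from a wide TSV or a minimal VCFv4.2 subset.

    ``dialect`` is one of ``vcf_subset``, ``tsv`` or ``auto`` (sniffed from
    the first line).  Missing calls are preserved as missing, never imputed.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError("empty genotype file", path, 1)
    first = text.splitlines()[0]
    if dialect == "auto":
        dialect = "vcf_subset" if first.startswith("##fileformat=VCF") else "tsv"
    if dialect == "vcf_subset":
        return _read_genotypes_vcf(path, text)
    if dialect == "tsv":
        return _read_genotypes_tsv(path, text)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path, text: str) -> GenotypeMatrix:
    snps: list[SnpDef] = []
    header: list[str] | None = None
    rows: list[tuple[str, list[str]]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("##SNP\t"):
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise ParseError("##SNP line needs 7 fields "
                                 "(##SNP id chrom pos ref alt region_class)",
                                 path, lineno)
            try:
                snps.append(SnpDef(f[1], f[2], int(f[3]), f[4], f[5], f[6]))
            except (ValueError, FormatValidationError) as e:
                raise ParseError(str(e), path, lineno) from e
            continue
        f = line.rstrip("\n").split("\t")
        if header is None:
            header = f
            if header[0] != "sample_id":
                raise ParseError("first column of genotype TSV must be sample_id",
                                 path, lineno)
            declared = [s.snp_id for s in snps]
            if header[1:] != declared:
                raise ParseError(
                    f"header SNP columns {header[1:]} do not match ##SNP "
                    f"declarations {declared}", path, lineno)
            continue
        if len(f) != len(header):
            raise ParseError(f"expected {len(header)} fields, got {len(f)}",
                             path, lineno)
        rows.append((f[0], f[1:]))
    if header is None or not rows:
        raise ParseError("genotype TSV has no data rows", path, 1)
    sample_ids = [r[0] for r in rows]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"duplicate sample_id {dup[0]!r}", path, 1)
    n, m = len(rows), len(snps)
    a1 = np.full((n, m), MISSING, dtype=np.int8)
    a2 = np.full((n, m), MISSING, dtype=np.int8)
    ph = np.zeros((n, m), dtype=bool)
    for i, (_, calls) in enumerate(rows):
        for j, tok in enumerate(calls):
            a1[i, j], a2[i, j], ph[i, j] = _parse_call(tok, (path, None))
    return GenotypeMatrix(sample_ids, snps, a1, a2, ph)


_VCF_FIXED = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]


def _read_genotypes_vcf(path, text: str) -> GenotypeMatrix:
    region: dict[str, str] = {}
    sample_ids: list[str] | None = None
    snps: list[SnpDef] = []
    calls: list[list[tuple[int, int, bool]]] = []
    saw_fileformat = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("##"):
            if line.startswith("##fileformat=VCFv4"):
                saw_fileformat = True
            elif line.startswith("##region_class="):
                # package extension: ##region_class=<snp_id>:<class>,...
                for item in line.split("=", 1)[1].split(","):
                    if item:
                        sid, cls = item.split(":")
                        region[sid] = cls
            continue
        if line.startswith("#CHROM"):
            f = line.rstrip("\n").split("\t")
            if f[:9] != _VCF_FIXED:
                raise ParseError("malformed VCF column header", path, lineno)
            sample_ids = f[9:]
            if len(set(sample_ids)) != len(sample_ids):
                raise ParseError("duplicate sample_id in VCF header", path, lineno)
            continue
        if sample_ids is None:
            raise ParseError("VCF data line before #CHROM header", path, lineno)
        f = line.rstrip("\n").split("\t")
        if len(f) != 9 + len(sample_ids):
            raise ParseError(f"expected {9 + len(sample_ids)} fields, got {len(f)}",
                             path, lineno)
        chrom, pos, snp_id, ref, alt = f[0], f[1], f[2], f[3], f[4]
        if f[8] != "GT":
            raise ParseError(f"FORMAT must be GT, got {f[8]!r}", path, lineno)
        if len(ref) != 1 or len(alt) != 1 or "," in alt:
            raise ParseError("only biallelic single-base records supported",
                             path, lineno)
        try:
            snps.append(SnpDef(snp_id, chrom, int(pos), ref, alt,
                               region.get(snp_id, "OTHER")))
        except (ValueError, FormatValidationError) as e:
            raise ParseError(str(e), path, lineno) from e
        calls.append([_parse_call(tok, (path, lineno)) for tok in f[9:]])
    if not saw_fileformat:
        raise ParseError("missing ##fileformat=VCFv4.x header", path, 1)
    if sample_ids is None or not snps:
        raise ParseError("VCF subset has no variant records", path, 1)
    n, m = len(sample_ids), len(snps)
    a1 = np.full((n, m), MISSING, dtype=np.int8)
    a2 = np.full((n, m), MISSING, dtype=np.int8)
    ph = np.zeros((n, m), dtype=bool)
    for j, col in enumerate(calls):
        for i, (x, y, p) in enumerate(col):
            a1[i, j], a2[i, j], ph[i, j] = x, y, p
    return GenotypeMatrix(sample_ids, snps, a1, a2, ph)


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        lines = []
        for s in gm.snps:
            lines.append("##SNP\t{}\t{}\t{}\t{}\t{}\t{}".format(
                s.snp_id, s.chrom, s.pos, s.ref_allele, s.alt_allele, s.region_class))
        lines.append("\t".join(["sample_id"] + gm.snp_ids))
        for i, sid in enumerate(gm.samples):
            lines.append("\t".join([sid] + [gm.call_string(i, j)
                                            for j in range(len(gm.snps))]))
    elif dialect == "vcf_subset":
        lines = ["##fileformat=VCFv4.2",
                 "##source=aeikit",
                 "##region_class=" + ",".join(
                     f"{s.snp_id}:{s.region_class}" for s in gm.snps),
                 "\t".join(_VCF_FIXED + gm.samples)]
        for j, s in enumerate(gm.snps):
            row = [s.chrom, str(s.pos), s.snp_id, s.ref_allele, s.alt_allele,
                   ".", "PASS", ".", "GT"]
            row += [gm.call_string(i, j) for i in range(len(gm.samples))]
            lines.append("\t".join(row))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# peak / Ct / phenotype / sample tables
# ---------------------------------------------------------------------------

def read_peaks(path) -> pd.DataFrame:
    """Read a SNaPshot peak-height table.

    Required columns: sample_id, snp_id, material, amplicon_id, peak_a1,
    peak_a2.  Optional: replicate_id, timepoint_hr.  Peaks must be
    nonnegative and material gDNA/cDNA.
    """
    path = Path(path)
    df = _read_tsv(path, required=PEAK_COLUMNS[:6])
    for col in ("peak_a1", "peak_a2"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0][0]
            raise FormatValidationError(
                f"{path}: negative peak height in column {col} (row {bad + 2})")
    bad_mat = ~df["material"].isin(MATERIALS)
    if bad_mat.any():
        val = df.loc[bad_mat, "material"].iloc[0]
        raise FormatValidationError(f"{path}: unknown material {val!r}")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = "r1"
    if "timepoint_hr" not in df.columns:
        df["timepoint_hr"] = np.nan
    else:
        df["timepoint_hr"] = pd.to_numeric(df["timepoint_hr"], errors="coerce")
    return df[PEAK_COLUMNS]


def write_peaks(df: pd.DataFrame, path) -> None:
    cols = [c for c in PEAK_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_ct(path) -> pd.DataFrame:
    """Read a qPCR Ct table (sample_id, assay, ct, optional replicate_id)."""
    path = Path(path)
    df = _read_tsv(path, required=CT_COLUMNS[:3])
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if not np.isfinite(df["ct"]).all():
        raise FormatValidationError(f"{path}: non-finite Ct value")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = "r1"
    return df[CT_COLUMNS]


def write_ct(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CT_COLUMNS)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: sample_id plus one numeric column per score."""
    path = Path(path)
    df = _read_tsv(path, required=["sample_id"])
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatValidationError(f"{path}: duplicate sample_id {dup!r}")
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_samples(path) -> list[SampleRecord]:
    path = Path(path)
    df = _read_tsv(path, required=["sample_id"])
    if df["sample_id"].duplicated().any():
        raise FormatValidationError(f"{path}: duplicate sample_id")
    out = []
    for _, r in df.iterrows():
        age = r.get("age", None)
        age = None if age in (None, "", "NA") or pd.isna(age) else float(age)
        out.append(SampleRecord(str(r["sample_id"]), str(r.get("cohort", "")),
                                str(r.get("sex", "unknown")), age,
                                str(r.get("diagnosis", ""))))
    return out


def write_samples(records: Sequence[SampleRecord], path) -> None:
    rows = [{"sample_id": r.sample_id, "cohort": r.cohort, "sex": r.sex,
             "age": "" if r.age is None else r.age, "diagnosis": r.diagnosis}
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError("empty file", path, 1)
    df = pd.read_csv(path, sep="\t", dtype=str).rename(columns=str.strip)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}", path, 1)
    return df


# ---------------------------------------------------------------------------
# amplicon BED
# ---------------------------------------------------------------------------

def read_amplicons(path) -> list[AmpliconDef]:
    """Read amplicons from BED: chrom start end name isoform_class [markers]."""
    path = Path(path)
    out = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                  start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 5:
            raise ParseError("BED line needs >= 5 columns "
                             "(chrom start end amplicon_id isoform_class)",
                             path, lineno)
        markers = tuple(m for m in f[5].split(",") if m) if len(f) > 5 else ()
        try:
            out.append(AmpliconDef(f[3], f[0], int(f[1]), int(f[2]), f[4], markers))
        except (ValueError, FormatValidationError) as e:
            raise ParseError(str(e), path, lineno) from e
    if not out:
        raise ParseError("no amplicon records", path, 1)
    return out


def write_amplicons(amps: Sequence[AmpliconDef], path) -> None:
    lines = ["\t".join([a.chrom, str(a.start), str(a.end), a.amplicon_id,
                        a.isoform_class, ",".join(a.markers_covered)])
             for a in amps]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_amplicon_markers(amps: Sequence[AmpliconDef],
                              snps: Sequence[SnpDef]) -> None:
    """Check every covered marker's position lies inside its amplicon."""
    by_id = {s.snp_id: s for s in snps}
    for a in amps:
        for sid in a.markers_covered:
            snp = by_id.get(sid)
            if snp is None:
                raise FormatValidationError(
                    f"amplicon {a.amplicon_id} covers undeclared SNP {sid}")
            if not a.contains(snp):
                raise FormatValidationError(
                    f"SNP {sid} at pos {snp.pos} not inside amplicon "
                    f"{a.amplicon_id} [{a.start}, {a.end})")


# ---------------------------------------------------------------------------
# config + run manifest
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML key-value run configuration."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatValidationError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int | None,
                   inputs: Iterable = ()) -> Path:
    """Write a run manifest (config hash, seed, input checksums) as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
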