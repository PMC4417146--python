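"""Genotype matrix container and standard-format I/O.

Coordinates are 1-based and inclusive at both ends throughout the package,
matching the convention of published inversion breakpoint tables.  The
counted allele is always ``alleleB`` (PLINK A1, VCF ALT); dosages count
copies of alleleB.  Strand is taken as given — all analyses happen within a
single dataset, so no allele flipping is performed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
#: minimum number of SNPs for a region to support reliable inversion inference
MIN_REGION_SNPS = 11

_VARIANT_COLS = ["chrom", "pos", "id", "alleleA", "alleleB"]


@dataclass(frozen=True)
class RegionSpec:
    """A genomic interval, 1-based and inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "RegionSpec":
        """Parse a ``chr:start-end`` string."""
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chr:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with variant and sample metadata.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_variants)`` integer array with entries in
        ``{0, 1, 2}`` counting alleleB copies; missing genotypes are ``-1``.
    variant_map
        DataFrame with columns ``chrom, pos, id, alleleA, alleleB``;
        positions strictly increasing within each chromosome.
    samples
        DataFrame with columns ``sample_id, father_id, mother_id`` plus any
        ancestry-label / phenotype columns.  Empty string means no parent.
    """

    dosages: np.ndarray
    variant_map: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        self.dosages = self.dosages.astype(np.int8, copy=False)
        n, m = self.dosages.shape
        if len(self.variant_map) != m:
            raise ValueError(f"variant_map has {len(self.variant_map)} rows for {m} variant columns")
        if len(self.samples) != n:
            raise ValueError(f"samples has {len(self.samples)} rows for {n} dosage rows")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        vm = self.variant_map
        for chrom, grp in vm.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        dup = vm.duplicated(subset=["chrom", "pos", "alleleA", "alleleB"])
        if dup.any():
            raise ValueError("duplicate (chrom,pos,alleleA,alleleB) variants")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        self.variant_map = vm.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing encoded as NaN."""
        x = self.dosages.astype(float)
        x[self.dosages == MISSING] = np.nan
        return x

    def trios(self) -> pd.DataFrame:
        """Complete trios: rows (child, father, mother) of sample ids where
        both parents are present in the sample table."""
        ids = set(self.samples["sample_id"])
        rows = []
        for _, r in self.samples.iterrows():
            f, m = r.get("father_id", ""), r.get("mother_id", "")
            if f and m and f in ids and m in ids:
                rows.append((r["sample_id"], f, m))
        return pd.DataFrame(rows, columns=["child", "father", "mother"])


def _normalize_samples(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in ("father_id", "mother_id"):
        if c not in out:
            out[c] = ""
        out[c] = out[c].astype(str).replace({"0": "", "nan": ""})
    out["sample_id"] = out["sample_id"].astype(str)
    return out


# ---------------------------------------------------------------------------
# PLINK 1.9 binary trio (bed/bim/fam), SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit bed codes -> alleleB (=A1) dosage
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam file set.

    The counted allele (alleleB) is the .bim A1 allele, so bed code ``00``
    (homozygous A1) maps to dosage 2.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing {prefix.with_suffix(ext)}")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "sample_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    payload = prefix.with_suffix(".bed").read_bytes()
    if payload[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file (bad magic)")
    bytes_per_snp = (n + 3) // 4
    if len(payload) - 3 != bytes_per_snp * m:
        raise ValueError(
            f".bed payload is {len(payload) - 3} bytes; expected {bytes_per_snp * m} "
            f"for {n} samples x {m} variants"
        )
    raw = np.frombuffer(payload, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T

    variant_map = pd.DataFrame({
        "chrom": bim["chrom"], "pos": bim["pos"].astype(int), "id": bim["id"].astype(str),
        "alleleA": bim["a2"], "alleleB": bim["a1"],
    })
    samples = _normalize_samples(fam[["sample_id", "father_id", "mother_id"]])
    samples["sex"] = fam["sex"].to_numpy()
    return GenotypeMatrix(dosages, variant_map, samples)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam; alleleB goes to the .bim A1 column."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vm = gm.variant_map
    bim = pd.DataFrame({
        0: vm["chrom"], 1: vm["id"], 2: 0, 3: vm["pos"], 4: vm["alleleB"], 5: vm["alleleA"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    s = gm.samples
    fam = pd.DataFrame({
        0: s["sample_id"], 1: s["sample_id"],
        2: s["father_id"].replace("", "0"), 3: s["mother_id"].replace("", "0"),
        4: s["sex"] if "sex" in s else 0, 5: -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = gm.n_individuals, gm.n_variants
    codes = np.empty((m, n), dtype=np.uint8)
    d = gm.dosages.T
    codes[d == 2] = 0
    codes[d == MISSING] = 1
    codes[d == 1] = 2
    codes[d == 0] = 3
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    parts = codes.reshape(m, -1, 4)
    packed = parts[..., 0] | (parts[..., 1] << 2) | (parts[..., 2] << 4) | (parts[..., 3] << 6)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, region: RegionSpec | None = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (GT field).

    Multiallelic records are skipped (counted in a warning); half-missing
    genotypes (e.g. ``./1``) are treated as missing.  Dosage counts ALT
    alleles.  ``region`` filters by chromosome and 1-based inclusive
    position.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, records, n_multi = [], [], 0
    for v in vcf:
        if region is not None and (
            str(v.CHROM) != region.chrom or not (region.start <= v.POS <= region.end)
        ):
            continue
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        g = np.array([a[:2] for a in v.genotypes], dtype=int)
        dos = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1)).astype(np.int8)
        rows.append(dos)
        records.append((str(v.CHROM), v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic record(s)")
    if not records:
        raise ValueError(f"no biallelic records in {path}" + (f" within {region}" if region else ""))
    variant_map = pd.DataFrame(records, columns=_VARIANT_COLS)
    dosages = np.vstack(rows).T
    samples = _normalize_samples(pd.DataFrame({"sample_id": sample_ids}))
    return GenotypeMatrix(dosages, variant_map, samples)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only); alleleA is REF, alleleB is ALT."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variant_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples["sample_id"]) + "\n")
        for j, v in gm.variant_map.iterrows():
            gts = "\t".join(gt_str[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.alleleA}\t{v.alleleB}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Slicing and QC
# ---------------------------------------------------------------------------

def extract_region(gm: GenotypeMatrix, region: RegionSpec, min_variants: int = 1) -> GenotypeMatrix:
    """Variants with ``region.start <= pos <= region.end`` on ``region.chrom``.

    Raises if fewer than ``min_variants`` remain (regions with very few SNPs
    — fewer than :data:`MIN_REGION_SNPS` — do not support reliable inversion
    inference; pass that constant for analysis-grade extraction).
    """
    vm = gm.variant_map
    if not (vm["chrom"] == region.chrom).any():
        raise ValueError(f"chromosome {region.chrom} not in variant map")
    keep = ((vm["chrom"] == region.chrom)
            & (vm["pos"] >= region.start) & (vm["pos"] <= region.end)).to_numpy()
    n_keep = int(keep.sum())
    if n_keep < max(min_variants, 1):
        raise ValueError(f"region {region} contains {n_keep} variants (< {max(min_variants, 1)})")
    return GenotypeMatrix(gm.dosages[:, keep], vm.loc[keep], gm.samples)


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.0, call_rate_min: float = 0.0,
) -> tuple[GenotypeMatrix, dict]:
    """Remove variants with MAF < ``maf_min`` or call rate < ``call_rate_min``.

    Returns the filtered matrix and a report of removed counts.  Retained
    dosage values are never altered.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= call_rate_min <= 1):
        raise ValueError("call_rate_min must be in [0, 1]")
    x = gm.dosages_float()
    call_rate = 1.0 - np.isnan(x).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(x, axis=0) / 2.0
    p = np.nan_to_num(p, nan=0.0)
    maf = np.minimum(p, 1 - p)
    low_maf = maf < maf_min
    low_call = call_rate < call_rate_min
    keep = ~(low_maf | low_call)
    if not keep.any():
        raise ValueError("all variants removed by QC filters")
    report = {
        "n_removed_maf": int(low_maf.sum()),
        "n_removed_call_rate": int((low_call & ~low_maf).sum()),
        "n_retained": int(keep.sum()),
    }
    return GenotypeMatrix(gm.dosages[:, keep], gm.variant_map.loc[keep], gm.samples), report
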