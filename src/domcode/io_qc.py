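"""PLINK-format genotype I/O, phenotype tables, and marker quality control.

Genotypes are stored as B-allele counts in {0, 1, 2}.  By convention the B
allele is the first allele column of the .bim file (PLINK's A1); pass
``count_allele2=True`` to count the second column instead.  The .bed codec
implements the v1.00 SNP-major layout: a 3-byte magic (0x6c 0x1b 0x01)
followed by ceil(n/4) bytes per marker, two bits per individual from the
low-order end (00 = A1 homozygote, 01 = missing, 10 = heterozygote,
11 = A2 homozygote).

Quality control follows common practice for dense SNP panels: markers are
dropped when the minor allele frequency falls below a cutoff (default 0.01)
or when an exact Hardy-Weinberg test rejects (default p < 1e-6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeData",
    "QCReport",
    "QCError",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "allele_frequency",
    "hwe_exact_pvalue",
    "qc_filter",
    "read_phenotypes",
    "write_phenotypes",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_MISSING = -9  # internal sentinel while decoding


class PlinkFormatError(ValueError):
    """Malformed or mutually inconsistent bed/bim/fam files."""


class QCError(ValueError):
    """Raised when filtering removes every marker; carries the report."""

    def __init__(self, message, report: "QCReport"):
        super().__init__(message)
        self.report = report


@dataclass
class GenotypeData:
    """Individuals x markers B-allele counts with marker metadata.

    ``genotypes`` is integer {0,1,2}; a float matrix is only permitted on the
    mean-imputation path of :func:`read_plink` (values then lie in [0, 2]).
    """

    genotypes: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x markers) array")
        n, m = self.genotypes.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one individual and one marker")
        for name in ("marker_ids", "chrom", "bp", "allele_a", "allele_b"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length {m}")
            setattr(self, name, arr)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape != (n,):
            raise ValueError(f"sample_ids must have length {n}")
        if len(set(self.marker_ids.tolist())) != m:
            raise ValueError("marker_ids must be unique")
        g = self.genotypes
        if np.issubdtype(g.dtype, np.integer):
            if g.min() < 0 or g.max() > 2:
                raise ValueError("genotypes must lie in {0, 1, 2}")
        else:
            if np.any(np.isnan(g)) or g.min() < 0 or g.max() > 2:
                raise ValueError("float genotypes must be finite and in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def select_markers(self, index) -> "GenotypeData":
        """New GenotypeData restricted to the given marker index/mask."""
        return GenotypeData(
            self.genotypes[:, index],
            self.marker_ids[index],
            self.chrom[index],
            self.bp[index],
            self.allele_a[index],
            self.allele_b[index],
            self.sample_ids,
        )


# ---------------------------------------------------------------------------
# bed codec

# per-byte lookup: 4 two-bit fields -> A1-allele count (or missing sentinel)
_BITS_TO_COUNT = np.array([2, _MISSING, 1, 0], dtype=np.int64)
_DECODE_TABLE = np.empty((256, 4), dtype=np.int64)
for _b in range(256):
    for _i in range(4):
        _DECODE_TABLE[_b, _i] = _BITS_TO_COUNT[(_b >> (2 * _i)) & 3]
_COUNT_TO_BITS = {2: 0b00, 1: 0b10, 0: 0b11}


def read_plink(prefix, mean_impute: bool = False, count_allele2: bool = False) -> GenotypeData:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeData`.

    Missing genotypes raise unless ``mean_impute`` is set, in which case each
    missing value is replaced by the column mean of the observed genotypes
    and the matrix becomes real-valued.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    if n == 0 or m == 0:
        raise PlinkFormatError("empty fam or bim file")
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed does not start with the v1.00 SNP-major magic bytes"
        )
    bpf = math.ceil(n / 4)  # bytes per marker
    if len(raw) - 3 != bpf * m:
        raise PlinkFormatError(
            f"{prefix}.bed payload has {len(raw) - 3} bytes, expected {bpf * m} "
            f"for {n} individuals x {m} markers"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpf)
    geno = _DECODE_TABLE[data].reshape(m, bpf * 4)[:, :n].T.copy()  # (n, m)
    if count_allele2:
        miss = geno == _MISSING
        geno = 2 - geno
        geno[miss] = _MISSING
        allele_b, allele_a = bim["a2"].to_numpy(), bim["a1"].to_numpy()
    else:
        allele_b, allele_a = bim["a1"].to_numpy(), bim["a2"].to_numpy()
    missing = geno == _MISSING
    if missing.any():
        if not mean_impute:
            k = int(missing.sum())
            raise ValueError(
                f"{k} missing genotype(s) present; re-read with mean_impute=True "
                "or impute externally"
            )
        g = geno.astype(float)
        g[missing] = np.nan
        col_mean = np.nanmean(g, axis=0)
        if np.any(np.isnan(col_mean)):
            raise ValueError("some markers have no observed genotypes to impute from")
        g[missing] = np.broadcast_to(col_mean, g.shape)[missing]
        geno = g
    return GenotypeData(
        geno,
        bim["snp"].to_numpy(),
        bim["chrom"].to_numpy(),
        bim["bp"].to_numpy(dtype=np.int64),
        allele_a,
        allele_b,
        fam.iloc[:, 1].to_numpy(),
    )


def write_plink(data: GenotypeData, prefix) -> None:
    """Write bed (v1.00 SNP-major) / bim / fam; round-trips through read_plink."""
    prefix = Path(prefix)
    g = data.genotypes
    if not np.issubdtype(g.dtype, np.integer):
        if np.any(g != np.rint(g)):
            raise ValueError("cannot write imputed (non-integer) genotypes to bed")
        g = np.rint(g).astype(np.int64)
    n, m = g.shape
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bim = pd.DataFrame(
        {
            "chrom": data.chrom,
            "snp": data.marker_ids,
            "cm": 0,
            "bp": data.bp,
            "a1": data.allele_b,  # B allele stored as A1 (the counted allele)
            "a2": data.allele_a,
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": data.sample_ids,
            "iid": data.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "phe": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bits = np.empty((m, n), dtype=np.uint8)
    for count, code in _COUNT_TO_BITS.items():
        bits[g.T == count] = code
    pad = (-n) % 4
    if pad:
        bits = np.concatenate([bits, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    bits = bits.reshape(m, -1, 4)
    packed = (
        bits[:, :, 0]
        | (bits[:, :, 1] << 2)
        | (bits[:, :, 2] << 4)
        | (bits[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# summaries and QC


def allele_frequency(data) -> np.ndarray:
    """Per-marker B-allele frequency p = (column sum) / 2n."""
    g = data.genotypes if isinstance(data, GenotypeData) else np.asarray(data, float)
    return g.mean(axis=0) / 2.0


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton-style enumeration).

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed one.
    Symmetric in swapping the homozygote classes; returns 1.0 for a
    monomorphic marker (single point of support).
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_b = 2 * counts[2] + counts[1]
    rare = min(n_b, 2 * n - n_b)
    if rare == 0:
        return 1.0
    # conditional distribution of the het count given allele counts:
    # P(het+2) / P(het) = rare_rem * common_rem / ((het+2)(het+1)) pattern,
    # generated by the standard recurrence from the mode.
    mode = rare * (2 * n - rare) // (2 * n)
    if mode % 2 != rare % 2:
        mode += 1
    probs = np.zeros(rare + 1)
    probs[mode] = 1.0
    h = mode
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mode
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    probs /= probs.sum()
    obs = probs[counts[1]]
    pval = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, pval))


@dataclass
class QCReport:
    """Which markers a qc_filter pass removed, and why."""

    n_before: int
    n_after: int
    removed: list = field(default_factory=list)  # (marker_id, reason)

    def removed_ids(self) -> list:
        return [mid for mid, _ in self.removed]


def qc_filter(
    data: GenotypeData,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-6,
    exclude_low_hwe_p: bool = True,
):
    """Drop markers failing MAF or exact-HWE filters.

    ``exclude_low_hwe_p=True`` (default) removes markers whose HWE exact
    p-value is below ``hwe_alpha``; the opposite direction is available for
    completeness but discards almost every marker on real panels.

    Returns ``(filtered GenotypeData, QCReport)``; raises :class:`QCError`
    (with the report attached) if nothing survives.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    g = data.genotypes
    if not np.issubdtype(g.dtype, np.integer):
        if np.any(g != np.rint(g)):
            raise ValueError("qc_filter needs unimputed integer genotypes")
        g = np.rint(g).astype(np.int64)
    p = allele_frequency(data)
    maf = np.minimum(p, 1.0 - p)
    n_bb = (g == 2).sum(axis=0)
    n_ab = (g == 1).sum(axis=0)
    n_aa = (g == 0).sum(axis=0)
    keep = np.ones(data.n_markers, dtype=bool)
    removed = []
    for j in range(data.n_markers):
        reasons = []
        if maf[j] < maf_min:
            reasons.append(f"maf {maf[j]:.4g} < {maf_min}")
        hwe_p = hwe_exact_pvalue(n_aa[j], n_ab[j], n_bb[j])
        if exclude_low_hwe_p:
            if hwe_p < hwe_alpha:
                reasons.append(f"hwe p {hwe_p:.3g} < {hwe_alpha}")
        elif hwe_p > hwe_alpha:
            reasons.append(f"hwe p {hwe_p:.3g} > {hwe_alpha}")
        if reasons:
            keep[j] = False
            removed.append((data.marker_ids[j], "; ".join(reasons)))
    report = QCReport(data.n_markers, int(keep.sum()), removed)
    if not keep.any():
        raise QCError("quality control removed every marker", report)
    return data.select_markers(keep), report


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype table (header: IID then trait names)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs an IID column plus >= 1 trait")
    df = df.set_index(df.columns[0])
    df.index.name = "IID"
    return df.astype(float)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "IID"
    out.to_csv(path, sep="\t")
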