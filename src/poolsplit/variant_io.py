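"""Input/output for the standard formats the pipeline touches.

Reads SNV call sets (VCF 4.x via cyvcf2), donor genotype VCFs with GL/GP
FORMAT fields, plain-text barcode whitelists, and the two allele count
matrices as CSV (SNVs in rows, barcodes in columns).  Also implements the
read-level quality filter applied when counting alleles from a BAM.

Only biallelic SNVs are modelled: indels, MNPs and complex events are
dropped on read.  Multi-allelic records are split into one biallelic
record per single-base ALT before any filtering, so downstream code only
ever sees a single ref base and a single alt base.  VCF positions stay
1-based everywhere; the SNV identifier used throughout is ``chrom:pos``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from cyvcf2 import VCF

from .errors import NoInformativeVariantsError, PoolsplitError, VCFParseError

#: SAM flag mask excluding unmapped, secondary, QC-fail, duplicate and
#: supplementary reads (``samtools view -F 3844``).
QC_FLAG_MASK = 3844

#: Minimum mapping quality for a read to be counted (``samtools view -q 10``).
MIN_MAPQ = 10

#: Default barcode tag (10x convention); overridable wherever it is used.
DEFAULT_BARCODE_TAG = "CB"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SNVRecord:
    """A biallelic single-nucleotide variant.

    ``gp`` optionally carries per-sample genotype probability triplets
    (RR, RA, AA), one row per sample, when the record came from a donor
    genotype VCF.  Probabilities sum to 1 per sample.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    qual: float
    gp: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"negative QUAL at {self.chrom}:{self.pos}")
        if self.gp is not None:
            gp = np.asarray(self.gp, dtype=float)
            if gp.ndim != 2 or gp.shape[1] != 3:
                raise ValueError("GP must be an (n_samples, 3) array")
            if not np.allclose(gp.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(
                    f"GP triplets at {self.chrom}:{self.pos} do not sum to 1"
                )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def _split_biallelic(variant) -> list[tuple[str, str]]:
    """Yield (ref, alt) pairs of single-base alleles for a cyvcf2 record."""
    ref = variant.REF
    if len(ref) != 1 or ref not in _BASES:
        return []
    out = []
    for alt in variant.ALT:
        if len(alt) == 1 and alt in _BASES:
            out.append((ref, alt))
    return out


def read_snv_vcf(
    path: str,
    min_qual: float = 30.0,
    common_snp_path: str | None = None,
) -> list[SNVRecord]:
    """Read a VCF of SNVs called on the pooled BAM and apply quality filters.

    Keeps biallelic SNVs with ``QUAL > min_qual`` (strict, per the upstream
    convention of retaining quality scores greater than 30).  Multi-allelic
    records are split into biallelic records first.  When
    ``common_snp_path`` is given, records are intersected with that VCF on
    ``(chrom, pos, ref, alt)`` so mismatched alleles at shared positions do
    not slip through.  Input order is preserved.

    Raises
    ------
    NoInformativeVariantsError
        If no SNV survives filtering.
    VCFParseError
        If the file cannot be opened/parsed.
    """
    common: set[tuple[str, int, str, str]] | None = None
    if common_snp_path is not None:
        common = set()
        for rec in _iter_vcf(common_snp_path):
            for ref, alt in _split_biallelic(rec):
                common.add((rec.CHROM, rec.POS, ref, alt))

    records: list[SNVRecord] = []
    for rec in _iter_vcf(path):
        qual = rec.QUAL
        if qual is None or not qual > min_qual:
            continue
        for ref, alt in _split_biallelic(rec):
            if common is not None and (rec.CHROM, rec.POS, ref, alt) not in common:
                continue
            records.append(SNVRecord(rec.CHROM, rec.POS, ref, alt, float(qual)))
    if not records:
        raise NoInformativeVariantsError(
            f"no informative variants survive filtering of {path} "
            f"(min_qual={min_qual}, common_snps={common_snp_path})"
        )
    return records


def _iter_vcf(path: str):
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    line_no = 0
    try:
        for rec in vcf:
            line_no += 1
            yield rec
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF record (data line {line_no + 1}) in {path}: {exc}"
        ) from exc
    finally:
        vcf.close()


def read_donor_vcf(path: str) -> tuple[list[str], list[SNVRecord]]:
    """Read a multi-sample donor genotype VCF with GP (or GL) FORMAT fields.

    Returns the sample names and one :class:`SNVRecord` per biallelic SNV,
    each carrying an ``(n_samples, 3)`` GP array.  GL (log10-likelihood)
    triplets are converted to probabilities when GP is absent.  No quality
    filter is applied: donor genotype VCFs are reference panels, not calls
    on the pooled BAM.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[SNVRecord] = []
    try:
        for rec in vcf:
            pairs = _split_biallelic(rec)
            if len(pairs) != 1:
                continue  # donor panels: keep strictly biallelic records
            ref, alt = pairs[0]
            gp = _genotype_probabilities(rec, path)
            if gp is None:
                continue
            records.append(
                SNVRecord(rec.CHROM, rec.POS, ref, alt,
                          float(rec.QUAL or 0.0), gp=gp)
            )
    finally:
        vcf.close()
    if not records:
        raise NoInformativeVariantsError(f"no usable genotype records in {path}")
    return samples, records


def _genotype_probabilities(rec, path: str) -> np.ndarray | None:
    gp = None
    try:
        gp = rec.format("GP")
    except KeyError:
        gp = None
    if gp is not None:
        gp = np.asarray(gp, dtype=float)
        return gp / gp.sum(axis=1, keepdims=True)
    try:
        gl = rec.format("GL")
    except KeyError:
        return None
    if gl is None:
        return None
    gl = np.asarray(gl, dtype=float)
    if np.any(gl > 1e-9):
        raise VCFParseError(f"GL values > 0 at {rec.CHROM}:{rec.POS} in {path}")
    lik = np.power(10.0, gl - gl.max(axis=1, keepdims=True))
    return lik / lik.sum(axis=1, keepdims=True)


def read_barcodes(path: str) -> list[str]:
    """Read a barcode whitelist, one barcode per line.

    Duplicates are removed with a warning (first occurrence kept); blank
    lines are ignored.  An empty file is an error.
    """
    seen: dict[str, None] = {}
    duplicates = 0
    with open(path) as fh:
        for line in fh:
            bc = line.strip()
            if not bc:
                continue
            if bc in seen:
                duplicates += 1
            else:
                seen[bc] = None
    if duplicates:
        warnings.warn(f"{duplicates} duplicate barcode(s) removed from {path}")
    if not seen:
        raise PoolsplitError(f"barcode whitelist {path} is empty")
    return list(seen)


def qc_read_passes(read, whitelist, barcode_tag: str = DEFAULT_BARCODE_TAG) -> bool:
    """Decide whether an aligned read is counted.

    True iff mapping quality >= 10, none of the flag-mask-3844 bits
    (unmapped / secondary / QC-fail / duplicate / supplementary) is set,
    and the read's barcode tag is present in the whitelist.  Reads without
    the tag are rejected rather than raising.
    """
    if read.mapping_quality < MIN_MAPQ:
        return False
    if read.flag & QC_FLAG_MASK:
        return False
    try:
        barcode = read.get_tag(barcode_tag)
    except KeyError:
        return False
    return barcode in whitelist


def write_matrix_csv(matrix, row_ids, col_ids, path: str) -> None:
    """Write an SNV x barcode integer count matrix as CSV.

    Layout: rows labelled ``chrom:pos``, columns by barcode, first header
    cell empty — i.e. the standard labelled-matrix CSV the rest of the
    pipeline exchanges (``ref_filtered.csv`` / ``alt_filtered.csv``).
    """
    if sp.issparse(matrix):
        matrix = np.asarray(matrix.todense())
    else:
        matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise PoolsplitError("refusing to write an empty matrix")
    if matrix.shape != (len(row_ids), len(col_ids)):
        raise PoolsplitError(
            f"matrix shape {matrix.shape} does not match labels "
            f"({len(row_ids)} rows, {len(col_ids)} cols)"
        )
    df = pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, index_label="")


def read_matrix_csv(path: str) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a matrix written by :func:`write_matrix_csv`.

    Returns ``(counts, row_ids, col_ids)`` with counts as CSR int32;
    ``read(write(M)) == M`` exactly for integer matrices.
    """
    df = pd.read_csv(path, index_col=0)
    if df.size == 0:
        raise PoolsplitError(f"matrix CSV {path} is empty")
    counts = sp.csr_matrix(df.to_numpy(dtype=np.int32))
    return counts, [str(i) for i in df.index], [str(c) for c in df.columns]
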