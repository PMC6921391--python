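"""Build the paired reference/alternative allele count matrices.

The central data structure of the whole method: two sparse matrices of
identical shape and labelling, ``N_R[v, c]`` and ``N_A[v, c]``, holding
the number of QC-passing reads in cell barcode ``c`` whose aligned base
at SNV ``v`` equals the reference or the alternative allele.  Bases
matching neither allele, and reads with no aligned base at the position
(deletion/refskip), contribute to neither matrix.

After counting, SNVs that look homozygous in aggregate are removed: the
pooled counts are scored under a three-genotype binomial error model and
only sites whose normalized heterozygous likelihood GL(RA) is at least
``log10(1 - error)`` are retained — homozygous sites carry no signal for
telling donors apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pysam
import scipy.sparse as sp
from scipy.special import logsumexp

from . import variant_io
from .errors import NoInformativeVariantsError
from .variant_io import SNVRecord, qc_read_passes

#: Aggregate per-SNV depth is capped at this value before computing the
#: three-genotype likelihoods; very deep sites otherwise make all three
#: log-likelihoods degenerate.  Configurable via ``het_likelihood_filter``.
DEFAULT_DEPTH_CAP = 10_000


@dataclass
class AlleleCountMatrices:
    """Paired sparse SNV x cell matrices of ref and alt allele counts."""

    ref: sp.csr_matrix
    alt: sp.csr_matrix
    snv_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.ref = sp.csr_matrix(self.ref)
        self.alt = sp.csr_matrix(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError(
                f"ref {self.ref.shape} and alt {self.alt.shape} shapes differ"
            )
        if self.ref.shape != (len(self.snv_ids), len(self.barcodes)):
            raise ValueError("matrix shape does not match labels")
        if self.ref.nnz and self.ref.data.min() < 0:
            raise ValueError("negative reference counts")
        if self.alt.nnz and self.alt.data.min() < 0:
            raise ValueError("negative alternative counts")

    @property
    def n_snvs(self) -> int:
        return self.ref.shape[0]

    @property
    def n_cells(self) -> int:
        return self.ref.shape[1]

    def total(self) -> sp.csr_matrix:
        """Total allele counts N_T = N_A + N_R."""
        return (self.ref + self.alt).tocsr()

    def subset(self, snv_idx=None, cell_idx=None) -> "AlleleCountMatrices":
        """Row/column subset preserving label alignment."""
        ref, alt = self.ref, self.alt
        snv_ids, barcodes = self.snv_ids, self.barcodes
        if snv_idx is not None:
            snv_idx = np.asarray(snv_idx)
            ref, alt = ref[snv_idx], alt[snv_idx]
            snv_ids = [snv_ids[i] for i in snv_idx]
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            ref, alt = ref[:, cell_idx], alt[:, cell_idx]
            barcodes = [barcodes[i] for i in cell_idx]
        return AlleleCountMatrices(ref.tocsr(), alt.tocsr(), snv_ids, barcodes)


def build_count_matrices(
    bam_path: str,
    snvs: list[SNVRecord],
    whitelist: list[str],
    barcode_tag: str = variant_io.DEFAULT_BARCODE_TAG,
) -> AlleleCountMatrices:
    """Count ref/alt alleles per (SNV, barcode) from an indexed BAM.

    For every SNV the overlapping reads are fetched; each QC-passing read
    (see :func:`poolsplit.variant_io.qc_read_passes`) contributes one count
    to N_R or N_A according to its aligned base at the SNV position.
    Contigs named in the VCF but absent from the BAM header produce a
    warning and all-zero rows.
    """
    barcodes = list(dict.fromkeys(whitelist))
    bc_index = {bc: j for j, bc in enumerate(barcodes)}
    wl = set(barcodes)

    rows_r, cols_r, rows_a, cols_a = [], [], [], []
    missing_contigs: set[str] = set()
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        contigs = set(bam.references)
        for i, snv in enumerate(snvs):
            if snv.chrom not in contigs:
                missing_contigs.add(snv.chrom)
                continue
            pos0 = snv.pos - 1  # pysam is 0-based
            for read in bam.fetch(snv.chrom, pos0, pos0 + 1):
                if not qc_read_passes(read, wl, barcode_tag):
                    continue
                base = _base_at(read, pos0)
                if base is None:
                    continue
                j = bc_index[read.get_tag(barcode_tag)]
                if base == snv.ref:
                    rows_r.append(i)
                    cols_r.append(j)
                elif base == snv.alt:
                    rows_a.append(i)
                    cols_a.append(j)
    if missing_contigs:
        warnings.warn(
            "contig(s) absent from BAM header, SNVs skipped with zero counts: "
            + ", ".join(sorted(missing_contigs))
        )
    shape = (len(snvs), len(barcodes))
    ref = sp.coo_matrix(
        (np.ones(len(rows_r), dtype=np.int32), (rows_r, cols_r)), shape=shape
    ).tocsr()
    alt = sp.coo_matrix(
        (np.ones(len(rows_a), dtype=np.int32), (rows_a, cols_a)), shape=shape
    ).tocsr()
    return AlleleCountMatrices(ref, alt, [s.id for s in snvs], barcodes)


def _base_at(read, pos0: int) -> str | None:
    """Aligned query base at reference position ``pos0``, or None."""
    seq = read.query_sequence
    if seq is None:
        return None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            return seq[qpos].upper()
    return None


def aggregate_het_log10_gp(
    alt_sum: np.ndarray,
    ref_sum: np.ndarray,
    error_rate: float = 0.01,
    depth_cap: int = DEFAULT_DEPTH_CAP,
) -> np.ndarray:
    """Normalized log10 probability of genotype RA from pooled counts.

    Per SNV the pooled alt/ref counts are scored under a binomial error
    model with per-read alt probability ``error`` (RR), ``0.5`` (RA) and
    ``1 - error`` (AA); the three log10-likelihoods are normalized to sum
    to one under a uniform genotype prior.  Counts are rescaled so total
    depth never exceeds ``depth_cap``.
    """
    a = np.asarray(alt_sum, dtype=float)
    r = np.asarray(ref_sum, dtype=float)
    depth = a + r
    scale = np.where(depth > depth_cap, depth_cap / np.maximum(depth, 1), 1.0)
    a, r = a * scale, r * scale
    p = np.array([error_rate, 0.5, 1.0 - error_rate])
    # (n_snvs, 3) log10-likelihood; the binomial coefficient cancels in the
    # normalization so it is omitted.
    log10_l = a[:, None] * np.log10(p)[None, :] + r[:, None] * np.log10(1 - p)[None, :]
    ln = log10_l * np.log(10.0)
    norm = logsumexp(ln, axis=1, keepdims=True)
    return (ln[:, 1] - norm[:, 0]) / np.log(10.0)


def het_likelihood_filter(
    matrices: AlleleCountMatrices,
    error_rate: float = 0.01,
    depth_cap: int = DEFAULT_DEPTH_CAP,
) -> AlleleCountMatrices:
    """Drop SNVs whose pooled counts do not look heterozygous.

    An SNV is retained iff its normalized log10 GL(RA) is at least
    ``log10(1 - error_rate)``.  Raises
    :class:`~poolsplit.errors.NoInformativeVariantsError` when nothing
    survives.
    """
    if matrices.n_snvs == 0:
        raise NoInformativeVariantsError("no SNVs to filter")
    alt_sum = np.asarray(matrices.alt.sum(axis=1)).ravel()
    ref_sum = np.asarray(matrices.ref.sum(axis=1)).ravel()
    log10_p_ra = aggregate_het_log10_gp(alt_sum, ref_sum, error_rate, depth_cap)
    keep = np.flatnonzero(log10_p_ra >= np.log10(1.0 - error_rate))
    if keep.size == 0:
        raise NoInformativeVariantsError(
            "all SNVs removed by the heterozygous-likelihood filter; "
            "consider intersecting the call set with a common-SNP list"
        )
    return matrices.subset(snv_idx=keep)
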