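"""Synthetic pooled scRNA-seq allele-count data with known truth.

Generates multi-donor diploid genotypes (Hardy-Weinberg draws at
Beta-distributed alt-allele frequencies, or full-sibling pairs by
Mendelian transmission from simulated parents), then simulates the
ref/alt count matrices a pooled experiment would yield: each cell is
assigned to a donor, a per-cell read budget is drawn from a lognormal
depth profile and spread over SNVs in proportion to expression-like
coverage weights, and each read at SNV v carries the alternative allele
with probability

    P(A) = 1/2 * L(RA) + L(AA)

computed from the donor's (normalized) genotype likelihoods — so a
heterozygous donor emits alt reads at ~0.5 and homozygous donors at the
genotyping error rate.  Doublets are created afterwards by merging a
randomly chosen fraction of barcodes with a second, disjoint set
column-wise, exactly as droplets sharing a barcode would add their reads.

A template-BAM mode is also provided: instead of the parametric depth
profile, the read coverage is taken from a real barcode-tagged BAM by
walking its reads, which preserves the empirical expression profile.

Defaults mirror a typical large 10x run (12,383 cells at ~4,973 reads
per cell, 3% + 3% barcode merging); tests and the bundled analyses use
explicit scaled-down sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
import scipy.sparse as sp

from .allele_counter import AlleleCountMatrices, _base_at
from .errors import PoolsplitError
from .variant_io import SNVRecord, qc_read_passes

DEFAULT_DOUBLET_FRACTION = 0.03
DEFAULT_GP_ERROR = 0.01

_GT_RR, _GT_RA, _GT_AA = 0, 1, 2
_ACGT = "ACGT"


@dataclass
class DonorGenotypes:
    """Diploid genotypes plus GP triplets for the pooled donors.

    ``genotypes[d, v]`` is the alt-allele dosage (0, 1 or 2);
    ``gp[d, v]`` the (RR, RA, AA) probability triplet.
    """

    donors: list[str]
    snv_ids: list[str]
    genotypes: np.ndarray  # (n_donors, n_snvs) int8
    gp: np.ndarray  # (n_donors, n_snvs, 3)
    alt_freqs: np.ndarray  # (n_snvs,)
    ref_alleles: list[str] = field(default_factory=list)
    alt_alleles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d, v = self.genotypes.shape
        if self.gp.shape != (d, v, 3):
            raise ValueError("gp shape must be (n_donors, n_snvs, 3)")
        if not np.allclose(self.gp.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("GP triplets must sum to 1")
        if not self.ref_alleles:
            self.ref_alleles = ["A"] * v
            self.alt_alleles = ["C"] * v

    @property
    def n_donors(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class DepthProfile:
    """Parametric per-cell/per-SNV read-depth model.

    Total reads per cell are lognormal with mean ``mean_reads_per_cell``
    (sigma on the log scale ``cell_sigma``); reads land on SNVs
    multinomially with lognormal weights (``snv_weight_sigma``), giving
    the heavy-tailed, sparse coverage characteristic of scRNA-seq.
    """

    mean_reads_per_cell: float = 4973.0
    cell_sigma: float = 0.5
    snv_weight_sigma: float = 1.5
    snv_weights: np.ndarray | None = None

    def cell_depths(self, n_cells: int, rng: np.random.Generator) -> np.ndarray:
        mu = np.log(self.mean_reads_per_cell) - self.cell_sigma**2 / 2
        depths = rng.lognormal(mu, self.cell_sigma, size=n_cells)
        return np.maximum(depths.round().astype(int), 1)

    def weights(self, n_snvs: int, rng: np.random.Generator) -> np.ndarray:
        if self.snv_weights is not None:
            w = np.asarray(self.snv_weights, dtype=float)
            if w.shape != (n_snvs,):
                raise PoolsplitError("snv_weights length must equal n_snvs")
        else:
            w = rng.lognormal(0.0, self.snv_weight_sigma, size=n_snvs)
        return w / w.sum()


@dataclass
class SimulationTruth:
    """Gold-standard barcode-to-donor assignment, the evaluation reference."""

    barcode_to_donor: dict[str, str]  # singlets only
    doublets: list[tuple[str, str, tuple[str, str]]]  # (kept, merged, (d1, d2))
    params: dict = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        """Per-barcode truth label: donor name or "DBL"."""
        out = dict(self.barcode_to_donor)
        for kept, _merged, _pair in self.doublets:
            out[kept] = "DBL"
        return out

    def doublet_pairs(self) -> dict[str, tuple[str, str]]:
        return {kept: pair for kept, _m, pair in self.doublets}


def _gp_from_genotypes(genotypes: np.ndarray, error: float) -> np.ndarray:
    gp = np.full(genotypes.shape + (3,), error)
    for g in (_GT_RR, _GT_RA, _GT_AA):
        gp[..., g][genotypes == g] = 1.0 - 2 * error
    return gp


def synth_donor_genotypes(
    n_donors: int,
    n_snvs: int,
    rng: np.random.Generator,
    allele_freq_sampler=None,
    gp_error: float = DEFAULT_GP_ERROR,
) -> DonorGenotypes:
    """Unrelated diploid donors under Hardy-Weinberg equilibrium.

    Alt-allele frequencies default to Beta(2, 2) rescaled to
    [0.05, 0.95] — common, segregating variants, as a population SNP
    panel would supply.  GP triplets put ``1 - 2*gp_error`` on the true
    genotype.
    """
    if n_donors < 1:
        raise PoolsplitError("need at least one donor")
    if allele_freq_sampler is None:
        freqs = 0.05 + 0.90 * rng.beta(2.0, 2.0, size=n_snvs)
    else:
        freqs = np.asarray(allele_freq_sampler(n_snvs, rng), dtype=float)
    # genotype = number of alt alleles in two HW draws
    genotypes = (
        rng.random((n_donors, n_snvs)) < freqs
    ).astype(np.int8) + (rng.random((n_donors, n_snvs)) < freqs).astype(np.int8)
    gp = _gp_from_genotypes(genotypes, gp_error)
    return DonorGenotypes(
        donors=[f"donor{d}" for d in range(n_donors)],
        snv_ids=[f"1:{100 * (v + 1)}" for v in range(n_snvs)],
        genotypes=genotypes,
        gp=gp,
        alt_freqs=freqs,
        ref_alleles=[_ACGT[i] for i in rng.integers(0, 2, size=n_snvs) * 2],
        alt_alleles=[_ACGT[i] for i in rng.integers(0, 2, size=n_snvs) * 2 + 1],
    )


def synth_sibling_pair(
    n_snvs: int,
    rng: np.random.Generator,
    parent_freqs: np.ndarray | None = None,
    gp_error: float = DEFAULT_GP_ERROR,
) -> DonorGenotypes:
    """Two full siblings by Mendelian transmission from simulated parents.

    Each parent is a Hardy-Weinberg draw; each sibling independently
    receives one uniformly chosen allele from each parent per SNV, so the
    pair shares 0/1/2 alleles identical-by-descent with the usual
    1/4 : 1/2 : 1/4 weights.
    """
    if parent_freqs is None:
        parent_freqs = 0.05 + 0.90 * rng.beta(2.0, 2.0, size=n_snvs)
    else:
        parent_freqs = np.asarray(parent_freqs, dtype=float)
        n_snvs = parent_freqs.shape[0]
    # parental haplotypes: (2 parents, 2 haplotypes, n_snvs)
    hap = (rng.random((2, 2, n_snvs)) < parent_freqs).astype(np.int8)
    sibs = np.empty((2, n_snvs), dtype=np.int8)
    for s in range(2):
        from_p0 = hap[0, rng.integers(0, 2, size=n_snvs), np.arange(n_snvs)]
        from_p1 = hap[1, rng.integers(0, 2, size=n_snvs), np.arange(n_snvs)]
        sibs[s] = from_p0 + from_p1
    gp = _gp_from_genotypes(sibs, gp_error)
    return DonorGenotypes(
        donors=["sib0", "sib1"],
        snv_ids=[f"1:{100 * (v + 1)}" for v in range(n_snvs)],
        genotypes=sibs,
        gp=gp,
        alt_freqs=parent_freqs,
    )


def alt_read_probability(gp: np.ndarray) -> np.ndarray:
    """Per-read alternative-allele probability from (RR, RA, AA) likelihoods.

    P(A) = 1/2 * L(RA) + L(AA), with the likelihood triplet renormalized
    to sum to 1 first (genotype likelihood files are not always
    normalized).
    """
    gp = np.asarray(gp, dtype=float)
    norm = gp / gp.sum(axis=-1, keepdims=True)
    return 0.5 * norm[..., 1] + norm[..., 2]


def _barcode(i: int, length: int = 12) -> str:
    return "".join(_ACGT[(i >> (2 * j)) & 3] for j in range(length)) + f"-{i}"


def simulate_counts(
    genotypes: DonorGenotypes,
    n_cells: int,
    profile: DepthProfile | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AlleleCountMatrices, SimulationTruth]:
    """Draw the ref/alt count matrices for a pooled run of singlet cells.

    Barcodes are assigned to donors uniformly at random; per cell, the
    read budget from the depth profile is spread multinomially over SNVs
    and each read is alt with the donor's Eq.-style allele probability.
    """
    rng = np.random.default_rng() if rng is None else rng
    profile = DepthProfile() if profile is None else profile
    n_snvs = genotypes.n_snvs
    barcodes = [_barcode(i) for i in range(n_cells)]
    donor_of = rng.integers(0, genotypes.n_donors, size=n_cells)
    depths = profile.cell_depths(n_cells, rng)
    weights = profile.weights(n_snvs, rng)
    p_alt = alt_read_probability(genotypes.gp)  # (n_donors, n_snvs)

    rows, cols, alt_data, ref_data = [], [], [], []
    for c in range(n_cells):
        counts = rng.multinomial(depths[c], weights)
        covered = np.flatnonzero(counts)
        n_alt = rng.binomial(counts[covered], p_alt[donor_of[c], covered])
        n_ref = counts[covered] - n_alt
        rows.extend(covered.tolist())
        cols.extend([c] * len(covered))
        alt_data.extend(n_alt.tolist())
        ref_data.extend(n_ref.tolist())

    shape = (n_snvs, n_cells)
    alt = sp.coo_matrix((alt_data, (rows, cols)), shape=shape, dtype=np.int32)
    ref = sp.coo_matrix((ref_data, (rows, cols)), shape=shape, dtype=np.int32)
    matrices = AlleleCountMatrices(
        ref.tocsr(), alt.tocsr(), list(genotypes.snv_ids), barcodes
    )
    truth = SimulationTruth(
        barcode_to_donor={
            bc: genotypes.donors[d] for bc, d in zip(barcodes, donor_of)
        },
        doublets=[],
        params={
            "n_donors": genotypes.n_donors,
            "n_cells": n_cells,
            "n_snvs": n_snvs,
            "mean_reads_per_cell": profile.mean_reads_per_cell,
            "doublet_fraction": 0.0,
        },
    )
    return matrices, truth


def simulate_counts_from_bam(
    bam_path: str,
    snvs: list[SNVRecord],
    whitelist: list[str],
    genotypes: DonorGenotypes,
    rng: np.random.Generator | None = None,
    barcode_tag: str = "CB",
) -> tuple[AlleleCountMatrices, SimulationTruth]:
    """Template-BAM simulation: real coverage, simulated alleles.

    Walks the template BAM's QC-passing reads at the given SNVs; each
    read keeps its barcode and position but its allele is re-drawn from
    the genotype likelihoods of the donor its barcode was (randomly)
    assigned to.  Preserves the empirical depth/expression profile.
    """
    rng = np.random.default_rng() if rng is None else rng
    barcodes = list(dict.fromkeys(whitelist))
    bc_index = {bc: j for j, bc in enumerate(barcodes)}
    wl = set(barcodes)
    donor_of = rng.integers(0, genotypes.n_donors, size=len(barcodes))
    snv_index = {s.id: i for i, s in enumerate(snvs)}
    p_alt = alt_read_probability(genotypes.gp)
    geno_index = {s: v for v, s in enumerate(genotypes.snv_ids)}

    rows, cols, alt_data, ref_data = [], [], [], []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        contigs = set(bam.references)
        for snv in snvs:
            if snv.chrom not in contigs or snv.id not in geno_index:
                continue
            i = snv_index[snv.id]
            v = geno_index[snv.id]
            pos0 = snv.pos - 1
            for read in bam.fetch(snv.chrom, pos0, pos0 + 1):
                if not qc_read_passes(read, wl, barcode_tag):
                    continue
                if _base_at(read, pos0) is None:
                    continue
                j = bc_index[read.get_tag(barcode_tag)]
                is_alt = rng.random() < p_alt[donor_of[j], v]
                rows.append(i)
                cols.append(j)
                alt_data.append(int(is_alt))
                ref_data.append(int(not is_alt))

    shape = (len(snvs), len(barcodes))
    alt = sp.coo_matrix((alt_data, (rows, cols)), shape=shape, dtype=np.int32)
    ref = sp.coo_matrix((ref_data, (rows, cols)), shape=shape, dtype=np.int32)
    matrices = AlleleCountMatrices(
        ref.tocsr(), alt.tocsr(), [s.id for s in snvs], barcodes
    )
    truth = SimulationTruth(
        barcode_to_donor={
            bc: genotypes.donors[d] for bc, d in zip(barcodes, donor_of)
        },
        doublets=[],
        params={
            "n_donors": genotypes.n_donors,
            "n_cells": len(barcodes),
            "n_snvs": len(snvs),
            "template_bam": bam_path,
            "doublet_fraction": 0.0,
        },
    )
    return matrices, truth


def inject_doublets(
    matrices: AlleleCountMatrices,
    truth: SimulationTruth,
    doublet_fraction: float = DEFAULT_DOUBLET_FRACTION,
    rng: np.random.Generator | None = None,
) -> tuple[AlleleCountMatrices, SimulationTruth]:
    """Merge disjoint barcode pairs to create doublets.

    ``round(fraction * n_cells)`` barcodes are chosen as keepers and an
    equally sized disjoint set is merged into them column-wise (then
    dropped), so total counts are conserved.  The truth marks keepers as
    DBL and records the donor pair; same-donor merges can occur and are
    recorded like any other (they are undetectable in principle and the
    evaluation reports them separately).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_cells = matrices.n_cells
    n_dbl = int(round(doublet_fraction * n_cells))
    if 2 * n_dbl > n_cells:
        raise PoolsplitError(
            f"doublet fraction {doublet_fraction} needs {2 * n_dbl} distinct "
            f"barcodes but only {n_cells} exist"
        )
    if n_dbl == 0:
        return matrices, truth
    chosen = rng.choice(n_cells, size=2 * n_dbl, replace=False)
    keepers, merged = chosen[:n_dbl], chosen[n_dbl:]

    # column-merge operator: kept columns map to themselves, merged-in
    # columns fold into their keeper, so new = old @ T conserves counts
    keep_cols = np.setdiff1d(np.arange(n_cells), merged)
    out_index = {int(j): p for p, j in enumerate(keep_cols)}
    src = np.concatenate([keep_cols, merged])
    dst = np.concatenate(
        [np.arange(len(keep_cols)), [out_index[int(k)] for k in keepers]]
    )
    t = sp.coo_matrix(
        (np.ones(len(src), dtype=np.int32), (src, dst)),
        shape=(n_cells, len(keep_cols)),
    ).tocsc()
    new = AlleleCountMatrices(
        (matrices.ref @ t).tocsr(),
        (matrices.alt @ t).tocsr(),
        list(matrices.snv_ids),
        [matrices.barcodes[i] for i in keep_cols],
    )

    singlets = dict(truth.barcode_to_donor)
    doublets = list(truth.doublets)
    for k, m in zip(keepers, merged):
        bk, bm = matrices.barcodes[k], matrices.barcodes[m]
        pair = (singlets.pop(bk), singlets.pop(bm))
        doublets.append((bk, bm, pair))
    params = dict(truth.params)
    params["doublet_fraction"] = doublet_fraction
    return new, SimulationTruth(singlets, doublets, params)


def write_truth_tsv(truth: SimulationTruth, path: str, header: str = "") -> None:
    """Write the truth table: barcode, label, merged barcode, donor pair."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("barcode\tlabel\tmerged_barcode\tdonor_pair\n")
        for bc, donor in truth.barcode_to_donor.items():
            fh.write(f"{bc}\t{donor}\t.\t.\n")
        for kept, merged, (d1, d2) in truth.doublets:
            fh.write(f"{kept}\tDBL\t{merged}\t{d1},{d2}\n")


def read_truth_tsv(path: str) -> SimulationTruth:
    singlets: dict[str, str] = {}
    doublets = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("barcode\t"):
                continue
            bc, label, merged, pair = line.rstrip("\n").split("\t")
            if label == "DBL":
                d1, d2 = pair.split(",")
                doublets.append((bc, merged, (d1, d2)))
            else:
                singlets[bc] = label
    return SimulationTruth(singlets, doublets)


def write_donor_vcf(genotypes: DonorGenotypes, path: str) -> None:
    """Write donor genotypes as a minimal VCF with GT, GP and GL fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description='
            '"Genotype probability (RR,RA,AA)">\n'
        )
        fh.write(
            '##FORMAT=<ID=GL,Number=G,Type=Float,Description='
            '"Genotype log10-likelihood (RR,RA,AA)">\n'
        )
        chroms = {s.split(":")[0] for s in genotypes.snv_ids}
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.donors)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for v, snv_id in enumerate(genotypes.snv_ids):
            chrom, pos = snv_id.split(":")
            fields = [
                chrom, pos, ".", genotypes.ref_alleles[v],
                genotypes.alt_alleles[v], "100", "PASS", ".", "GT:GP:GL",
            ]
            for d in range(genotypes.n_donors):
                gp = genotypes.gp[d, v]
                gl = np.log10(np.maximum(gp, 1e-300))
                fields.append(
                    gt_str[int(genotypes.genotypes[d, v])]
                    + ":" + ",".join(f"{x:.6f}" for x in gp)
                    + ":" + ",".join(f"{x:.4f}" for x in gl)
                )
            fh.write("\t".join(fields) + "\n")
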