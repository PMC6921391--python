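"""Shared fixtures: synthetic BAM/VCF builders and small simulated pools."""

import numpy as np
import pysam
import pytest

import poolsplit as ps


def write_bam(path, reads, contigs=(("chr1", 10000),)):
    """Write a sorted, indexed BAM from (chrom, pos0, seq, cigar, barcode,
    mapq, flag) tuples; barcode=None omits the CB tag."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in contigs],
    }
    contig_ids = {c: i for i, (c, _) in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (contig_ids[r[0]], r[1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i, (chrom, pos0, seq, cigar, barcode, mapq, flag) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.query_sequence = seq
            a.cigarstring = cigar
            a.reference_id = contig_ids[chrom]
            a.reference_start = pos0
            a.mapping_quality = mapq
            a.flag = flag
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if barcode is not None:
                a.set_tag("CB", barcode)
            out.write(a)
    pysam.index(str(path))
    return str(path)


def write_vcf(path, rows, contigs=("chr1",)):
    """Write a minimal VCF; rows are (chrom, pos, ref, alt, qual) tuples
    where alt may be comma-separated for multi-allelic records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=100000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, qual in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\n")
    return str(path)


@pytest.fixture(scope="session")
def small_pool():
    """A small 2-donor pooled simulation with doublets, filtered, plus truth."""
    rng = np.random.default_rng(42)
    geno = ps.synth_donor_genotypes(2, 800, rng)
    profile = ps.DepthProfile(mean_reads_per_cell=400)
    matrices, truth = ps.simulate_counts(geno, 300, profile, rng)
    matrices, truth = ps.inject_doublets(matrices, truth, 0.03, rng)
    filtered = ps.het_likelihood_filter(matrices)
    return geno, filtered, truth
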