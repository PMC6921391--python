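# poolsplit

Genotype-free demultiplexing of pooled single-cell RNA-seq.

Pooling samples before droplet barcoding is the cheapest way to scale
scRNA-seq, but every downstream analysis then needs each cell barcode
assigned back to its donor — and droplets holding two cells (doublets)
flagged. poolsplit does both using only the genetic signal already in
the reads: no donor genotypes, no cell hashing. It is aimed at labs
pooling human or non-model-organism samples where reference genotypes
are unavailable, expensive, or (as with tumor subclones) do not exist.

## Method

From a barcode-tagged BAM and a VCF of SNVs called on it, poolsplit
builds two sparse SNV × barcode matrices of reference and alternative
allele counts, N_R and N_A, then fits a mixture model over cells: each
cluster S_n (one per donor, plus one free cluster that captures
doublets) has allele fractions P(A_v|S_n), and

    log P(C_i|S_n) = Σ_v [ N_A(i,v)·log P(A_v|S_n) + N_R(i,v)·log(1 − P(A_v|S_n)) ]

Fitting is by expectation–maximization with pseudo-counted updates

    P(A_v|S_n) = [Σ_i N_A(i,v)·P(S_n|C_i) + pseudo_A] / [Σ_i N_T(i,v)·P(S_n|C_i) + pseudo_AR]

seeded from PCA + K-means on a dense sub-matrix of well-covered cells
and SNVs, with 30 re-randomized restarts keeping the best model
log-likelihood. Cells are assigned where the posterior P(S_n|C_i)
exceeds 0.99; the doublet cluster is identified by its cross-assignment
likelihood, and doublet calls are topped up to an expected proportion
by read depth. Finally each cluster is genotyped as presence/absence of
the alternative allele per SNV, a minimal set of *distinguishing
variants* separating every cluster pair is selected (Gram-Schmidt plus
exact minimization), and clusters are mapped to named donors by
comparing P/A patterns — so a handful of targeted genotyping assays
suffices to put donor names on clusters.

A first-class simulator generates pooled pools with known truth
(Hardy-Weinberg donors or full-sibling pairs, genotype-likelihood-driven
allele sampling, merged-barcode doublets), and an evaluation module
scores predictions (TPR/FDR per class, Cohen's kappa).

## Worked example (synthetic pool)

```
$ poolsplit simulate --donors 2 --cells 500 --snvs 1500 \
    --reads-per-cell 600 --seed 7 --out-dir sim
simulated 1500 SNVs x 485 barcodes (15 doublets)

$ poolsplit run --ref sim/ref_filtered.csv --alt sim/alt_filtered.csv \
    --num-samples 2 --restarts 10 --doublet-fraction 0.031 --seed 7 --out-dir out
log-likelihood -102828.32; doublet cluster 0

$ poolsplit genotype-map --cluster-pa out/cluster_pa.tsv --geno-vcf sim/donors.vcf \
    --variants out/distinguishing_variants.txt --out out/mapping.tsv
total match score 2.000 over 1 variants

$ poolsplit evaluate --predictions out/result.tsv --truth sim/truth.tsv \
    --mapping out/mapping.tsv
cells evaluated:              485
unassigned:                   0
singlet TPR (avg over donors): 0.9787
singlet FDR:                  2.19e-03
doublet TPR (cross-donor):    0.8333
Cohen's kappa:                0.9221
...
```

Reading the output: 500 simulated cells became 485 barcodes after 15
barcode pairs were merged into doublets. A single distinguishing SNV
sufficed to map both clusters to their donors (match score 1.0 each).
97.9% of each donor's cells were correctly recovered; 5 of the 6
detectable (cross-donor) doublets were flagged. The nine same-donor
doublets carry no genetic signal and are reported separately. The
`count` subcommand produces the same ref/alt matrices from a real
BAM + VCF + barcode whitelist instead of the simulator.

The same pipeline is available as a library:

```python
import numpy as np, poolsplit as ps

rng = np.random.default_rng(1)
geno = ps.synth_donor_genotypes(2, 3000, rng)
m, truth = ps.simulate_counts(geno, 1500, ps.DepthProfile(mean_reads_per_cell=750), rng)
m, truth = ps.inject_doublets(m, truth, 0.03, rng)
m = ps.het_likelihood_filter(m)
a = ps.demultiplex(m, n_samples=2, rng=rng, expected_doublet_fraction=0.031)
```

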