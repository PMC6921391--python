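# Methods

## Problem and model

A pooled scRNA-seq run mixes cells from `N` donors before droplet
barcoding. Each droplet's reads carry the donor's alleles at whatever
SNVs its transcripts happen to cover, so the per-barcode pattern of
reference/alternative allele counts is a (sparse, noisy) fingerprint of
the donor genotype. poolsplit models these fingerprints with a finite
mixture:

- Hidden state: which cluster `S_n` (donor, or the extra doublet
  cluster) a cell `C_i` belongs to.
- Emission: given a cluster, the alternative read count at SNV `v` is
  binomial in the total count with cluster allele fraction
  `P(A_v|S_n)`, so

  `log P(C_i|S_n) = Σ_v [ N_A(i,v)·log P(A_v|S_n) + N_R(i,v)·log(1−P(A_v|S_n)) ]`,

  summed over the non-zero entries only. All likelihoods are carried in
  log space; raw products underflow at realistic depths.

The model is deliberately genotype-free: allele fractions are estimated
from the pooled data itself, and donor genotypes (when available at all)
enter only at the very end, to name the clusters.

### Doublets

Droplets containing two cells are modelled by one extra mixture
component (`N+1` clusters are fitted for `N` donors). Its allele
fractions are free parameters; in practice EM drives them toward the
average of the donor fractions, which is what a cross-donor doublet
looks like. After convergence the doublet component is identified by
the cross-assignment score: for each cluster `c`,

`score(c) = mean over cells homed elsewhere of [ log P(C_i|S_c) + log P(S_c) ]`

and the argmax is declared the doublet cluster — the component that
best explains *other* clusters' cells is the averaged one. The mean
(rather than a raw sum) makes the comparison independent of cluster
sizes: the doublet cluster is small, so a raw sum over its many foreign
cells would be penalized for its size rather than scored on fit — on
sibling pools, where per-cell likelihood gaps are modest, a raw sum
demonstrably designates a whole donor cluster as doublet.

Because genetics cannot flag doublets whose two cells share a genotype,
the user may supply an expected doublet proportion; if fewer cells sit
in the doublet cluster, the deepest singlets (largest total counts) are
relabelled `DBL` until the expectation is met — doublets carry roughly
twice the reads of a singlet.

## Fitting

1. **Seeding.** The count matrix is far too sparse for direct
   clustering, so a dense core is extracted: cells and SNVs are ranked
   by their number of zero totals and 10% of the worst of each are
   removed per iteration — drawn at random from the worst-ranked 20%,
   so each restart sees a different but always-valid seed — until every
   remaining cell is non-zero at >90% of remaining SNVs and vice versa.
   Seed-cell alt fractions (`N_A/(N_A+N_R)`, zero-total entries imputed
   at the prior mean 0.5) are reduced by PCA (≤20 components) and split
   into `N+1` clusters by K-means (k-means++, 10 internal restarts).
   On very sparse inputs an unlucky trim draw can dip below the seed
   floor of 10 cells per cluster; the restart then retries with the
   density target relaxed in steps of 0.05 before giving up.
2. **Initialization.** Per cluster, `P(A_v|S_n) = (ΣN_A + pseudo_A) /
   (ΣN_A + ΣN_R + pseudo_AR)` over its seed cells; cluster weights
   start uniform. Pseudo-counts default to `pseudo_A = 1`,
   `pseudo_AR = 2` — a symmetric Beta-style prior with mean 0.5 that
   keeps every fraction strictly inside (0, 1).
3. **EM.** E-step: responsibilities by Bayes' theorem; M-step:
   allele fractions from responsibility-weighted counts plus the
   pseudo-counts, weights from responsibility masses. Iterate until the
   model log-likelihood `L = Σ_i log Σ_n P(C_i|S_n)·P(S_n)` changes by
   less than `tol = 1e-4` (absolute), cap 1000 iterations.
4. **Restarts.** The whole of 1–3 is repeated 30 times (trimming draw
   and K-means both re-randomized from independent substreams) and the
   restart with the largest `L` wins — the likelihood surface is
   multimodal and a single run can park the extra cluster on noise.
5. **Assignment.** Cells are assigned to their argmax cluster only when
   the *equal-prior* posterior `P(S_n|C_i) = P(C_i|S_n)/Σ_x P(C_i|S_x)`
   strictly exceeds 0.99; otherwise `unassigned`.

Two posterior conventions coexist by design. The EM loop weighs
responsibilities by the current cluster weights — that, and only that,
makes the update ascend the objective that contains the weights. The
*assignment* posterior assumes equal priors: the doublet component's
small weight (~3%) should not handicap a borderline doublet at the hard
0.99 threshold, and donor sizes should not bias cell calls. The two
coincide at initialization, where weights start uniform.

**Monotonicity.** Because the M-step adds pseudo-counts it is a MAP
update, so the EM ascent guarantee applies to the penalized objective
`L + Σ_{v,n}[pseudo_A·log p + (pseudo_AR−pseudo_A)·log(1−p)]` (exposed
as `map_history`), not to the raw likelihood, which can dip by the
prior pull (observed ≲ 1e-5 relative). Tests assert strict 1e-8
monotonicity on the penalized objective.

## Variant and read filters

- Reads: mapping quality ≥ 10 and none of the SAM flag bits in mask
  3844 (unmapped / secondary / QC-fail / duplicate / supplementary),
  plus a whitelisted barcode tag (default `CB`). Upstream duplicate
  *removal* is treated as preprocessing; the duplicate flag bit is
  honoured regardless.
- Variants: biallelic SNVs only (multi-allelic records split first),
  `QUAL > 30` strict, optional intersection with a common-SNP VCF on
  `(chrom, pos, ref, alt)`.
- Heterozygosity: per SNV the pooled counts are scored under a
  three-genotype binomial model (per-read alt probability `error`,
  0.5, `1−error` for RR/RA/AA; `error = 0.01`), normalized with a
  uniform genotype prior; SNVs with normalized
  `log10 P(RA) < log10(1−error)` are dropped. In practice this removes
  sites whose pooled alt fraction lies outside roughly (0.15, 0.85) —
  sites homozygous across the whole pool, which carry no
  donor-separating signal. Aggregate depth is rescaled to a cap of
  10,000 before scoring so that very deep sites do not degenerate the
  comparison; the cap is configurable.

## Naming clusters: P/A genotyping and distinguishing variants

Each singlet cluster is summarized per SNV as `P` (pooled alt count
> 10), `A` (pooled ref count > 10 and *zero* alt reads) or `NA`. The
same matrix is derived from donor genotypes where available (`P` when
GP(RA) or GP(AA) > 0.9; `A` when GP(RR) > 0.9).

A minimal distinguishing set — SNVs whose P/A patterns jointly separate
every cluster pair — is selected from NA-free rows showing both tokens:
unique patterns are kept, greedy Gram-Schmidt retains rows linearly
independent of the span already kept (residual tolerance 1e-6,
stopping once all pairs separate), any still-identical pair is repaired
with a row on which it differs, and the resulting set is shrunk to
minimum cardinality by exhaustive search over unique patterns (smallest
size first, bounded at 200k combinations; beyond the budget a greedy
removal prune is used instead). Gram-Schmidt alone is not minimal — two
well-chosen variants can separate four clusters where the basis keeps
four — and a genotyping assay on these loci is priced per locus, so
minimality is the point. Clusters are then matched to donors by the
assignment (enumerated for ≤8 donors, Hungarian beyond) maximizing the
per-pair token match fraction over the distinguishing SNVs, `NA`
excluded from scoring.

## Synthetic data

The simulator generates the study conditions end to end:

- **Genotypes.** Unrelated donors: per-SNV alt frequency
  `f ~ Beta(2,2)` rescaled to `[0.05, 0.95]` (common, segregating
  panel SNPs), genotypes Hardy-Weinberg. Sibling pairs: two parents
  drawn the same way, two offspring by independent Mendelian
  transmission. GP triplets put `1 − 2e` on the true genotype
  (`e = 0.01`).
- **Counts.** Cells are assigned to donors uniformly at random. Per
  cell, total reads are lognormal around the target reads-per-cell
  (log-scale sigma 0.5 — the depth spread of a filtered 10x barcode
  list) and land on SNVs multinomially with lognormal weights (sigma
  1.5 — the heavy-tailed expression profile that concentrates coverage
  on few transcripts). Each read is alternative with probability
  `P(A) = ½·L(RA) + L(AA)` from the donor's normalized genotype
  likelihoods, so hets emit alt reads at ~0.5 and homozygotes at the
  error rate. A template-BAM mode replaces the parametric profile with
  a real BAM's reads (barcodes and coverage kept, alleles re-drawn).
- **Doublets.** `round(0.03·n)` barcodes are merged column-wise with a
  disjoint equal-sized set, which is then dropped — counts are
  conserved exactly, and the truth table records keeper, merged-in
  barcode and donor pair. Same-donor merges are allowed and recorded;
  they are undetectable in principle (their reads are one genotype) and
  the evaluation reports them separately.

Defaults mirror a large 10x run (12,383 cells, ~4,973 reads/cell); the
bundled analyses use 1,500 cells, 3,000 SNVs (5,000 for siblings, which
need more sites to find discordant ones) and ~750 reads/cell so a full
30-restart run takes seconds on one CPU.

What the simulator does *not* emulate: ambient RNA, UMI duplication
structure, allele-specific expression, sequencing-error base calls at
non-SNV positions, batch effects, or empirical barcode-depth/expression
correlation beyond the lognormal shapes. Passing tests therefore
demonstrate correctness of the method under its own generative
assumptions, not performance on any particular real dataset.

## Evaluation conventions

Per truth class: TPR = correct / class size (unassigned cells count
against the denominator); FDR = wrong / assigned (unassigned excluded).
"Average" metrics are unweighted means over classes. Cohen's kappa is
computed over assigned cells (flag-switchable). Two deliberate
refinements, both surfaced in the report rather than hidden:

- `singlet_fdr` excludes same-donor doublets that were called as their
  constituent donor (no genotype error was made); `singlet_fdr_strict`
  counts them as errors.
- `doublet_tpr_cross_donor` restricts doublet recall to cross-donor
  merges, the genetically detectable kind.

## Known limitations

- A cross-donor doublet whose minor component contributes less than
  about one-sixth of the reads is indistinguishable from its dominant
  donor under this model: per read at a discordant site the doublet
  model gains `log(0.5/0.015) ≈ 3.5` nats from minor-donor reads but
  loses `log(0.985/0.5) ≈ 0.68` per major-donor read, a scale-free
  ratio bound that deeper sequencing does not move. With the lognormal
  depth spread above, ~2% of simulated doublets sit beyond it.
- The number of donors must be known; model selection over `N` is out
  of scope.
- Two clusters sharing P/A genotypes at every confidently-called SNV
  cannot be mapped to donors (reported as an error naming the pair);
  expected for monozygotic twins or tumor subclones without private
  SNVs in covered transcripts.
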