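"""Presence/absence genotyping of clusters and cluster-to-donor mapping.

Each converged cluster is summarized as a presence/absence call of the
alternative allele per SNV ("P" when the cluster's pooled alt count
exceeds 10, "A" when the pooled ref count exceeds 10 with no alt reads at
all, "NA" otherwise).  The same kind of matrix is derived from donor
genotype probabilities (GP > 0.9).  A minimal set of distinguishing
variants — SNVs whose P/A patterns jointly separate every pair of
clusters — is then selected via Gram-Schmidt orthogonalization with an
exact minimization pass, and the two matrices are matched to map clusters
back to the donors they came from.

P/A matrices are plain pandas DataFrames (SNV id index, cluster or donor
columns, object dtype with tokens "P"/"A"/"NA").
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .allele_counter import AlleleCountMatrices
from .errors import IndistinguishableClustersError, PoolsplitError
from .variant_io import SNVRecord, read_donor_vcf

DEFAULT_MIN_COUNT = 10
DEFAULT_GP_THRESHOLD = 0.9
DEFAULT_GS_TOL = 1e-6

PRESENT, ABSENT, MISSING = "P", "A", "NA"
_TOKENS = {PRESENT, ABSENT, MISSING}

#: Combination budget for the exact minimal-subset search; beyond it the
#: greedy result is only pruned, not exhaustively minimized.
_EXACT_SEARCH_BUDGET = 200_000


def validate_pa_matrix(pa: pd.DataFrame) -> None:
    """Check P/A matrix invariants: tokens only, unique row labels."""
    if not pa.index.is_unique:
        raise PoolsplitError("P/A matrix row labels must be unique")
    bad = set(np.unique(pa.to_numpy())) - _TOKENS
    if bad:
        raise PoolsplitError(f"invalid P/A tokens: {sorted(bad)}")


def cluster_pa_matrix(
    matrices: AlleleCountMatrices,
    labels: list,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """P/A genotypes per cluster from pooled per-cluster allele counts.

    ``labels`` holds, per cell, an integer singlet cluster id or the
    strings "DBL"/"unassigned"; only singlet clusters are genotyped.  Per
    (SNV, cluster): "P" iff the summed alt count exceeds ``min_count``;
    "A" iff the summed ref count exceeds ``min_count`` with zero alt
    count; else "NA".
    """
    if len(labels) != matrices.n_cells:
        raise PoolsplitError("labels must cover every cell")
    clusters = sorted({lab for lab in labels if isinstance(lab, (int, np.integer))})
    if not clusters:
        raise PoolsplitError("no singlet clusters in labels")
    data = {}
    for cl in clusters:
        members = np.flatnonzero(
            np.fromiter(
                (isinstance(lab, (int, np.integer)) and lab == cl for lab in labels),
                dtype=bool,
                count=len(labels),
            )
        )
        col = np.full(matrices.n_snvs, MISSING, dtype=object)
        if members.size == 0:
            warnings.warn(f"cluster {cl} has no assigned cells; all-NA column")
        else:
            alt = np.asarray(matrices.alt[:, members].sum(axis=1)).ravel()
            ref = np.asarray(matrices.ref[:, members].sum(axis=1)).ravel()
            col[alt > min_count] = PRESENT
            col[(ref > min_count) & (alt == 0)] = ABSENT
        data[cl] = col
    pa = pd.DataFrame(data, index=list(matrices.snv_ids))
    validate_pa_matrix(pa)
    return pa


def sample_pa_from_gp(
    gp: np.ndarray,
    donor_names: list[str],
    snv_ids: list[str],
    snv_subset: list[str] | None = None,
    gp_threshold: float = DEFAULT_GP_THRESHOLD,
) -> pd.DataFrame:
    """Donor-side P/A matrix from genotype probability triplets.

    ``gp`` has shape (n_donors, n_snvs, 3) ordered (RR, RA, AA).  "P" is
    set when GP(RA) or GP(AA) exceeds the threshold, "A" when GP(RR)
    does; SNVs requested but absent get an all-NA row with a warning.
    """
    gp = np.asarray(gp, dtype=float)
    index = {s: i for i, s in enumerate(snv_ids)}
    wanted = list(snv_ids) if snv_subset is None else list(snv_subset)
    rows = []
    missing = []
    for s in wanted:
        i = index.get(s)
        if i is None:
            missing.append(s)
            rows.append([MISSING] * len(donor_names))
            continue
        row = []
        for d in range(len(donor_names)):
            rr, ra, aa = gp[d, i]
            if ra > gp_threshold or aa > gp_threshold:
                row.append(PRESENT)
            elif rr > gp_threshold:
                row.append(ABSENT)
            else:
                row.append(MISSING)
        rows.append(row)
    if missing:
        warnings.warn(
            f"{len(missing)} SNV(s) absent from donor genotypes; set to NA"
        )
    pa = pd.DataFrame(rows, index=wanted, columns=list(donor_names), dtype=object)
    validate_pa_matrix(pa)
    return pa


def sample_pa_matrix(
    donor_vcf: str,
    snv_subset: list[str] | None = None,
    gp_threshold: float = DEFAULT_GP_THRESHOLD,
    r2_threshold: float | None = None,
) -> pd.DataFrame:
    """Donor-side P/A matrix read from a genotype VCF with GP/GL fields.

    With ``r2_threshold`` set, variants lacking ``R2 > threshold`` in the
    VCF INFO field (imputation quality) are dropped before the matrix is
    built; the filter is skipped silently when no record carries R2.
    """
    samples, records = read_donor_vcf(donor_vcf)
    if r2_threshold is not None:
        filtered = _r2_filter(donor_vcf, records, r2_threshold)
        if filtered is not None:
            records = filtered
    gp = np.stack([r.gp for r in records], axis=1)  # donors x snvs x 3
    return sample_pa_from_gp(
        gp, samples, [r.id for r in records], snv_subset, gp_threshold
    )


def _r2_filter(path: str, records: list[SNVRecord], threshold: float):
    from cyvcf2 import VCF

    r2_by_site: dict[str, float] = {}
    vcf = VCF(path)
    try:
        for rec in vcf:
            r2 = rec.INFO.get("R2")
            if r2 is not None:
                r2_by_site[f"{rec.CHROM}:{rec.POS}"] = float(r2)
    finally:
        vcf.close()
    if not r2_by_site:
        return None
    return [r for r in records if r2_by_site.get(r.id, 0.0) > threshold]


def _informative_rows(pa: pd.DataFrame) -> pd.DataFrame:
    """NA-free rows showing both P and A across clusters."""
    arr = pa.to_numpy()
    na_free = ~(arr == MISSING).any(axis=1)
    has_both = (arr == PRESENT).any(axis=1) & (arr == ABSENT).any(axis=1)
    return pa.loc[na_free & has_both]


def _separates_all(mat: np.ndarray) -> bool:
    """True iff all columns of the selected 0/1 matrix are pairwise distinct."""
    k = mat.shape[1]
    for a, b in itertools.combinations(range(k), 2):
        if np.array_equal(mat[:, a], mat[:, b]):
            return False
    return True


def distinguishing_variants(
    pa: pd.DataFrame, gs_tol: float = DEFAULT_GS_TOL
) -> list[str]:
    """Select a minimal SNV set whose P/A patterns separate all clusters.

    Procedure: (1) restrict to NA-free rows with both P and A present;
    (2) deduplicate rows by pattern, keeping the first representative;
    (3) encode P=1/A=0 and greedily keep rows whose Gram-Schmidt residual
    against the span of the rows already kept exceeds ``gs_tol``, stopping
    as soon as the kept rows separate every pair of cluster columns;
    (4) repair any still-identical pair with an NA-free row on which the
    pair differs; (5) shrink the separating set to minimum cardinality by
    exhaustive search over unique patterns (bounded; large instances fall
    back to greedy removal pruning).

    Raises
    ------
    IndistinguishableClustersError
        Naming a cluster pair identical on every NA-free row.
    """
    if pa.shape[1] < 2:
        raise PoolsplitError("need at least 2 clusters")
    validate_pa_matrix(pa)
    info = _informative_rows(pa)

    # deduplicate by pattern, first representative wins
    patterns: dict[tuple, str] = {}
    for snv, row in zip(info.index, info.to_numpy()):
        key = tuple(row)
        patterns.setdefault(key, snv)
    uniq_ids = list(patterns.values())
    uniq = (info.loc[uniq_ids].to_numpy() == PRESENT).astype(float)

    selected: list[int] = []
    basis: list[np.ndarray] = []
    for i, vec in enumerate(uniq):
        if selected and _separates_all(uniq[selected]):
            break
        res = vec.copy()
        for b in basis:
            res -= (res @ b) * b
        norm = np.linalg.norm(res)
        if norm > gs_tol:
            basis.append(res / norm)
            selected.append(i)

    sel_ids = [uniq_ids[i] for i in selected]
    if not (selected and _separates_all(uniq[selected])):
        sel_ids = _pair_repair(pa, info, sel_ids)

    sel_ids = _minimize(pa, uniq_ids, uniq, sel_ids)
    assert _pairs_separated_tokens(pa.loc[sel_ids])
    return sel_ids


def _pairs_separated_tokens(sub: pd.DataFrame) -> bool:
    arr = sub.to_numpy()
    return _separates_all(arr) if arr.size else False


def _pair_repair(pa: pd.DataFrame, info: pd.DataFrame, sel_ids: list[str]):
    """Add rows until every cluster pair differs somewhere in the set."""
    sel_ids = list(sel_ids)
    cols = list(pa.columns)
    arr_info = info.to_numpy()
    for a, b in itertools.combinations(range(len(cols)), 2):
        if sel_ids and not np.array_equal(
            pa.loc[sel_ids, cols[a]].to_numpy(), pa.loc[sel_ids, cols[b]].to_numpy()
        ):
            continue
        diff = np.flatnonzero(arr_info[:, a] != arr_info[:, b])
        if diff.size == 0:
            raise IndistinguishableClustersError(
                f"clusters {cols[a]} and {cols[b]} are identical on every "
                "NA-free P/A row"
            )
        candidate = info.index[diff[0]]
        if candidate not in sel_ids:
            sel_ids.append(candidate)
    return sel_ids


def _minimize(pa, uniq_ids, uniq, sel_ids):
    """Shrink a separating set to minimum cardinality (bounded search)."""
    k = pa.shape[1]
    lower = max(1, int(np.ceil(np.log2(k))))
    size = len(sel_ids)
    if size <= lower:
        return sel_ids
    n = len(uniq_ids)
    budget = _EXACT_SEARCH_BUDGET
    for s in range(lower, size):
        n_combos = _ncr(n, s)
        if n_combos > budget:
            return _prune(pa, sel_ids)
        budget -= n_combos
        for combo in itertools.combinations(range(n), s):
            if _separates_all(uniq[list(combo)]):
                return [uniq_ids[i] for i in combo]
    return sel_ids


def _ncr(n: int, r: int) -> int:
    from math import comb

    return comb(n, r)


def _prune(pa: pd.DataFrame, sel_ids: list[str]) -> list[str]:
    """Greedy removal: drop any variant whose removal keeps separation."""
    sel = list(sel_ids)
    changed = True
    while changed and len(sel) > 1:
        changed = False
        for s in list(sel):
            trial = [x for x in sel if x != s]
            if _pairs_separated_tokens(pa.loc[trial]):
                sel = trial
                changed = True
                break
    return sel


def map_clusters_to_samples(
    cluster_pa: pd.DataFrame,
    sample_pa: pd.DataFrame,
    variants: list[str],
) -> tuple[dict, dict, float]:
    """Match clusters to donors by P/A agreement at the distinguishing SNVs.

    Both matrices are restricted to ``variants``; for every
    (cluster, donor) pair the match fraction over rows where neither side
    is NA is computed, and the one-to-one assignment maximizing the total
    score is returned as ``(mapping, per-pair score, total score)``.  Ties
    between optimal assignments produce a warning (first optimum kept).
    """
    c = cluster_pa.loc[variants]
    s = sample_pa.loc[variants]
    clusters, donors = list(c.columns), list(s.columns)
    if len(clusters) > len(donors):
        raise PoolsplitError("more clusters than donors to map onto")
    score = np.zeros((len(clusters), len(donors)))
    for i, cl in enumerate(clusters):
        cv = c[cl].to_numpy()
        for j, dn in enumerate(donors):
            sv = s[dn].to_numpy()
            usable = (cv != MISSING) & (sv != MISSING)
            score[i, j] = (
                float((cv[usable] == sv[usable]).mean()) if usable.any() else 0.0
            )

    if len(donors) > 8:
        # too many donors to enumerate; Hungarian assignment, no tie check
        from scipy.optimize import linear_sum_assignment

        ri, cj = linear_sum_assignment(-score)
        mapping = {clusters[i]: donors[j] for i, j in zip(ri, cj)}
        pair_scores = {clusters[i]: float(score[i, j]) for i, j in zip(ri, cj)}
        return mapping, pair_scores, float(score[ri, cj].sum())

    best_perm, best_total, tie = None, -np.inf, False
    for perm in itertools.permutations(range(len(donors)), len(clusters)):
        total = sum(score[i, j] for i, j in enumerate(perm))
        if total > best_total + 1e-12:
            best_perm, best_total, tie = perm, total, False
        elif abs(total - best_total) <= 1e-12 and perm != best_perm:
            tie = True
    if tie:
        warnings.warn("multiple optimal cluster-to-donor mappings; keeping first")
    mapping = {clusters[i]: donors[j] for i, j in enumerate(best_perm)}
    pair_scores = {
        clusters[i]: float(score[i, j]) for i, j in enumerate(best_perm)
    }
    return mapping, pair_scores, float(best_total)
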