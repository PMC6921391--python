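"""Model initialization: dense seed submatrix, PCA + K-means, Eq.-style init.

The full allele count matrix is very sparse, so the model is seeded from a
dense core: cells and SNVs with the most zero total counts are iteratively
trimmed (10% per iteration, drawn at random from the worst-ranked 20% so
that every restart sees a different but always-valid seed) until every
remaining cell is non-zero at more than 90% of the remaining SNVs and vice
versa.  The seed cells' alternative-allele fractions are then reduced by
PCA and split into the expected number of clusters by K-means, and the
per-cluster alternative-allele probabilities are initialized from the seed
cells' pooled counts plus pseudo-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .allele_counter import AlleleCountMatrices
from .errors import DenseSubmatrixError, EmptyClusterError

DEFAULT_PSEUDO_ALT = 1.0
DEFAULT_PSEUDO_TOTAL = 2.0


@dataclass
class AlleleFractionModel:
    """Per-cluster alternative-allele probabilities and cluster weights.

    ``p_alt[v, n]`` is P(A_v | S_n), open in (0, 1) thanks to the
    pseudo-counts; ``weights[n]`` is P(S_n), summing to 1.
    """

    p_alt: np.ndarray  # (n_snvs, n_clusters)
    weights: np.ndarray  # (n_clusters,)
    pseudo_alt: float = DEFAULT_PSEUDO_ALT
    pseudo_total: float = DEFAULT_PSEUDO_TOTAL

    def __post_init__(self) -> None:
        self.p_alt = np.asarray(self.p_alt, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.p_alt.ndim != 2:
            raise ValueError("p_alt must be 2-D (SNVs x clusters)")
        if np.any(self.p_alt <= 0) or np.any(self.p_alt >= 1):
            raise ValueError("p_alt entries must lie strictly in (0, 1)")
        if self.weights.shape != (self.p_alt.shape[1],):
            raise ValueError("weights length must equal the number of clusters")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.p_alt.shape[1]


def select_dense_submatrix(
    matrices: AlleleCountMatrices,
    trim_fraction: float = 0.10,
    target_density: float = 0.90,
    rng: np.random.Generator | None = None,
    candidate_window: float = 0.20,
    min_cells: int = 10,
    min_snvs: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively trim sparse cells/SNVs down to a dense seed core.

    Per iteration, cells are ranked by their number of zero-total SNVs and
    SNVs by their number of zero-total cells; ``trim_fraction`` of each is
    removed, drawn uniformly (without replacement) from the worst-ranked
    ``candidate_window`` so repeated restarts explore different seeds.
    Ranking ties are broken by original index.  Stops when every remaining
    cell exceeds ``target_density`` non-zero SNVs and every remaining SNV
    exceeds ``target_density`` non-zero cells.

    Returns ``(snv_indices, cell_indices)`` into the input matrices.

    Raises
    ------
    DenseSubmatrixError
        If the selection collapses below ``min_cells`` cells (callers pass
        ``10 * n_clusters``) or ``min_snvs`` SNVs; a lower density target
        usually fixes this.
    """
    rng = np.random.default_rng() if rng is None else rng
    nz = matrices.total()
    nz.data = np.ones_like(nz.data)  # 0/1 indicator of observed counts
    nz = nz.tocsr()

    snv_idx = np.arange(matrices.n_snvs)
    cell_idx = np.arange(matrices.n_cells)
    while True:
        sub = nz[snv_idx][:, cell_idx]
        row_nnz = sub.getnnz(axis=1)  # non-zero cells per SNV
        col_nnz = sub.getnnz(axis=0)  # non-zero SNVs per cell
        cells_ok = np.all(col_nnz > target_density * len(snv_idx))
        snvs_ok = np.all(row_nnz > target_density * len(cell_idx))
        if cells_ok and snvs_ok:
            return snv_idx, cell_idx
        cell_keep = _trim(cell_idx, len(snv_idx) - col_nnz, trim_fraction,
                          candidate_window, rng)
        snv_keep = _trim(snv_idx, len(cell_idx) - row_nnz, trim_fraction,
                         candidate_window, rng)
        if len(cell_keep) < min_cells or len(snv_keep) < min_snvs:
            raise DenseSubmatrixError(
                f"dense-submatrix selection collapsed to {len(snv_keep)} SNVs x "
                f"{len(cell_keep)} cells (minimum {min_snvs} x {min_cells}); "
                "consider lowering target_density"
            )
        cell_idx, snv_idx = cell_keep, snv_keep


def _trim(idx, zero_counts, trim_fraction, candidate_window, rng):
    """Remove a random trim_fraction of `idx` from the worst candidate_window."""
    n = len(idx)
    n_remove = max(1, int(trim_fraction * n))
    n_window = max(n_remove, int(candidate_window * n))
    # sort by zero count desc, ties by original index asc
    order = np.lexsort((idx, -zero_counts))
    candidates = order[:n_window]
    removed = rng.choice(candidates, size=n_remove, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    return idx[keep]


def seed_clusters(
    matrices: AlleleCountMatrices,
    snv_idx: np.ndarray,
    cell_idx: np.ndarray,
    n_clusters: int,
    rng: np.random.Generator | None = None,
    n_pca_components: int | None = None,
    max_attempts: int = 10,
) -> np.ndarray:
    """PCA + K-means on seed-cell allele fractions.

    Features are the per-(cell, SNV) alternative-allele fractions
    ``N_A / (N_A + N_R)`` over the seed submatrix; entries with zero total
    count (at most 10% per cell by construction) are imputed with the
    uninformative prior mean 0.5.  Returns one label per seed cell with
    exactly ``n_clusters`` non-empty clusters; K-means is re-run with a
    fresh rng substream (up to ``max_attempts``) should a cluster come
    back empty.
    """
    rng = np.random.default_rng() if rng is None else rng
    sub = matrices.subset(snv_idx, cell_idx)
    alt = np.asarray(sub.alt.todense(), dtype=float)
    tot = alt + np.asarray(sub.ref.todense(), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, alt / np.maximum(tot, 1e-300), 0.5)
    x = frac.T  # cells x SNVs

    if n_clusters == 1:
        return np.zeros(x.shape[0], dtype=int)
    if n_clusters > x.shape[0]:
        raise EmptyClusterError(
            f"{n_clusters} clusters requested for {x.shape[0]} seed cells"
        )
    if n_pca_components is None:
        n_pca_components = min(20, x.shape[1], x.shape[0] - 1)
    n_pca_components = max(1, min(n_pca_components, x.shape[1], x.shape[0] - 1))

    for _ in range(max_attempts):
        seed = int(rng.integers(2**31 - 1))
        reduced = PCA(
            n_components=n_pca_components, random_state=seed
        ).fit_transform(x)
        labels = KMeans(
            n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed
        ).fit_predict(reduced)
        if len(np.unique(labels)) == n_clusters:
            return labels
    raise EmptyClusterError(
        f"K-means produced an empty cluster in {max_attempts} attempts"
    )


def init_model(
    matrices: AlleleCountMatrices,
    cell_idx: np.ndarray,
    labels: np.ndarray,
    pseudo_alt: float = DEFAULT_PSEUDO_ALT,
    pseudo_total: float = DEFAULT_PSEUDO_TOTAL,
) -> AlleleFractionModel:
    """Initialize the allele-fraction model from seeded clusters.

    For cluster n, P(A_v | S_n) = (sum_c N_A + pseudo_alt) /
    (sum_c N_A + sum_c N_R + pseudo_total), summing over the seed cells of
    that cluster; cluster weights start uniform.
    """
    labels = np.asarray(labels)
    cell_idx = np.asarray(cell_idx)
    if labels.shape != cell_idx.shape:
        raise ValueError("labels and cell_idx must align")
    clusters = np.unique(labels)
    n_clusters = len(clusters)
    p_alt = np.empty((matrices.n_snvs, n_clusters))
    for k, cl in enumerate(clusters):
        members = cell_idx[labels == cl]
        if members.size == 0:
            raise EmptyClusterError(f"cluster {cl} has no seed cells")
        a = np.asarray(matrices.alt[:, members].sum(axis=1)).ravel()
        r = np.asarray(matrices.ref[:, members].sum(axis=1)).ravel()
        p_alt[:, k] = (a + pseudo_alt) / (a + r + pseudo_total)
    weights = np.full(n_clusters, 1.0 / n_clusters)
    return AlleleFractionModel(p_alt, weights, pseudo_alt, pseudo_total)
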