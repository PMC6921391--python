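"""Expectation-maximization fit of the allele-fraction mixture model.

Each cell is modelled as a draw from one of K clusters (the K expected
donors plus one extra cluster that is free to soak up doublets).  Given a
cluster, the cell's alternative-allele count at SNV v is binomial with the
cluster's allele fraction P(A_v|S_n), so the cell log-likelihood is

    log P(C_i|S_n) = sum_v [ N_A(i,v) log P(A_v|S_n)
                             + N_R(i,v) log(1 - P(A_v|S_n)) ]

summed only over the non-zero entries.  The E-step turns these into
posteriors P(S_n|C_i) by Bayes' theorem with the current cluster weights
(which start uniform); the M-step recomputes allele fractions as
posterior-weighted counts plus pseudo-counts and updates the weights.
Everything is carried in log space; raw products of per-read
probabilities underflow at realistic depths.

The fit is restarted many times (30 by default) from re-randomized
initializations and the restart with the highest model log-likelihood is
kept.  After convergence the doublet cluster is identified as the one
with the largest summed cross-assignment log-likelihood — the cluster
that best explains everybody else's cells is the "average" one, which is
what a doublet cluster looks like — and cells are assigned wherever their
posterior exceeds a hard threshold (0.99), otherwise left unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .allele_counter import AlleleCountMatrices
from .errors import DenseSubmatrixError, PoolsplitError
from .model_init import (
    DEFAULT_PSEUDO_ALT,
    DEFAULT_PSEUDO_TOTAL,
    AlleleFractionModel,
    init_model,
    seed_clusters,
    select_dense_submatrix,
)

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 1000
DEFAULT_N_RESTARTS = 30
DEFAULT_POSTERIOR_THRESHOLD = 0.99

#: Sentinel labels used alongside integer cluster ids.
DOUBLET = "DBL"
UNASSIGNED = "unassigned"


@dataclass
class CellAssignment:
    """Converged model state plus per-cell posteriors and labels.

    ``posterior[i, n]`` is P(S_n | C_i); rows sum to 1.  ``labels`` (set by
    the pipeline after doublet identification) holds, per cell, either an
    integer cluster id, ``"DBL"`` or ``"unassigned"``.
    """

    barcodes: list[str]
    posterior: np.ndarray  # (n_cells, n_clusters)
    model: AlleleFractionModel
    log_likelihood: float
    converged: bool
    n_iter: int
    ll_history: list[float] = field(default_factory=list)
    map_history: list[float] = field(default_factory=list)
    doublet_cluster: int | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        rows = self.posterior.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    def label_strings(self) -> list[str]:
        """Human-readable labels: SNG-<k>, DBL or unassigned."""
        if self.labels is None:
            raise PoolsplitError("labels not set; run the full pipeline")
        return [
            lab if isinstance(lab, str) else f"SNG-{lab}" for lab in self.labels
        ]


def _cell_loglik(model: AlleleFractionModel, matrices: AlleleCountMatrices):
    """log P(C_i|S_n) for all cells/clusters, shape (n_cells, n_clusters)."""
    logp = matrices.alt.T @ np.log(model.p_alt)
    logp += matrices.ref.T @ np.log1p(-model.p_alt)
    return np.asarray(logp)


def e_step(
    model: AlleleFractionModel, matrices: AlleleCountMatrices
) -> tuple[np.ndarray, np.ndarray]:
    """Compute cell log-likelihoods and posterior cluster memberships.

    Returns ``(log P(C_i|S_n), P(S_n|C_i))``.  The posterior applies
    Bayes' theorem with equal sample priors, normalized per cell via
    log-sum-exp; it is the quantity cells are assigned on.  (The EM loop
    itself weighs responsibilities by the current cluster weights — see
    :func:`run_em` — which coincides with this at initialization where
    the weights start uniform.)
    """
    loglik = _cell_loglik(model, matrices)
    if not np.all(np.isfinite(loglik)):
        i, n = np.argwhere(~np.isfinite(loglik))[0]
        raise PoolsplitError(
            f"non-finite log-likelihood for cell {matrices.barcodes[i]} "
            f"in cluster {n}"
        )
    posterior = np.exp(loglik - logsumexp(loglik, axis=1, keepdims=True))
    return loglik, posterior


def _responsibilities(loglik: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Posterior with the current cluster weights as priors (EM-internal).

    Using the weights here (rather than equal priors) is what makes the
    M-step monotone in the Eq.-7-style model log-likelihood, which also
    contains the weights.
    """
    joint = loglik + np.log(weights)[None, :]
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


def m_step(
    matrices: AlleleCountMatrices,
    posterior: np.ndarray,
    pseudo_alt: float = DEFAULT_PSEUDO_ALT,
    pseudo_total: float = DEFAULT_PSEUDO_TOTAL,
) -> AlleleFractionModel:
    """Update allele fractions and cluster weights from the posterior.

    P(A_v|S_n) = (sum_i N_A(i,v) P(S_n|C_i) + pseudo_alt)
               / (sum_i N_T(i,v) P(S_n|C_i) + pseudo_total),
    with N_T = N_A + N_R; weights are the normalized posterior masses.
    """
    alt_w = np.asarray(matrices.alt @ posterior)
    tot_w = alt_w + np.asarray(matrices.ref @ posterior)
    p_alt = (alt_w + pseudo_alt) / (tot_w + pseudo_total)
    col = posterior.sum(axis=0)
    weights = col / col.sum()
    return AlleleFractionModel(p_alt, weights, pseudo_alt, pseudo_total)


def model_log_likelihood(
    model: AlleleFractionModel, matrices: AlleleCountMatrices
) -> float:
    """Overall model log-likelihood, L = sum_i log sum_n P(C_i|S_n) P(S_n)."""
    loglik = _cell_loglik(model, matrices)
    return float(logsumexp(loglik + np.log(model.weights)[None, :], axis=1).sum())


def _log_prior(model: AlleleFractionModel) -> float:
    """Log Beta-style prior implied by the pseudo-counts.

    The allele-fraction update adds ``pseudo_alt`` to the weighted alt
    counts and ``pseudo_total`` to the totals, i.e. it is the MAP update
    under an (unnormalized) prior pseudo_alt*log p + (pseudo_total -
    pseudo_alt)*log(1-p) per (SNV, cluster).  The EM ascent guarantee
    holds for the penalized objective L + log-prior, tracked in
    ``map_history``; the raw likelihood itself can dip by the prior pull.
    """
    a = model.pseudo_alt
    b = model.pseudo_total - model.pseudo_alt
    return float(a * np.log(model.p_alt).sum()
                 + b * np.log1p(-model.p_alt).sum())


def run_em(
    matrices: AlleleCountMatrices,
    model: AlleleFractionModel,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CellAssignment:
    """Alternate E and M steps until |delta L| < tol or max_iter.

    The penalized objective (``map_history``; model log-likelihood plus
    the pseudo-count prior) is non-decreasing across iterations up to
    floating slack — the EM ascent guarantee.  Non-convergence within
    ``max_iter`` returns the last state with ``converged=False`` and a
    warning.  The returned posterior is the equal-prior assignment
    posterior of :func:`e_step`.
    """
    history: list[float] = []
    map_history: list[float] = []
    posterior = None
    ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(max_iter + 1):
        loglik, posterior = e_step(model, matrices)
        joint = loglik + np.log(model.weights)[None, :]
        ll_new = float(logsumexp(joint, axis=1).sum())
        history.append(ll_new)
        map_history.append(ll_new + _log_prior(model))
        if np.isfinite(ll) and abs(ll_new - ll) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
        resp = _responsibilities(loglik, model.weights)
        model = m_step(matrices, resp, model.pseudo_alt, model.pseudo_total)
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations")
    return CellAssignment(
        barcodes=list(matrices.barcodes),
        posterior=posterior,
        model=model,
        log_likelihood=ll,
        converged=converged,
        n_iter=n_iter,
        ll_history=history,
        map_history=map_history,
    )


def run_restarts(
    matrices: AlleleCountMatrices,
    n_samples: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    rng: np.random.Generator | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    pseudo_alt: float = DEFAULT_PSEUDO_ALT,
    pseudo_total: float = DEFAULT_PSEUDO_TOTAL,
    trim_fraction: float = 0.10,
    target_density: float = 0.90,
    candidate_window: float = 0.20,
    extra_doublet_cluster: bool = True,
) -> CellAssignment:
    """Best-of-``n_restarts`` EM fit.

    Each restart re-randomizes both the dense-submatrix trimming and the
    K-means seeding from an independent rng substream, then fits
    ``n_samples + 1`` clusters (the extra one is there to capture
    doublets).  The restart with the largest model log-likelihood wins.
    """
    if n_restarts < 1:
        raise PoolsplitError("n_restarts must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_clusters = n_samples + 1 if extra_doublet_cluster else n_samples
    best: CellAssignment | None = None
    for sub_rng in rng.spawn(n_restarts):
        snv_idx = cell_idx = None
        # on very sparse inputs the dense core can dip below the seed
        # floor for an unlucky trim draw; relax the density target for
        # this restart rather than aborting the whole fit
        last_exc: Exception | None = None
        for target in (target_density, target_density - 0.05,
                       target_density - 0.10, target_density - 0.20):
            try:
                snv_idx, cell_idx = select_dense_submatrix(
                    matrices,
                    trim_fraction=trim_fraction,
                    target_density=target,
                    rng=sub_rng,
                    candidate_window=candidate_window,
                    min_cells=10 * n_clusters,
                )
                break
            except DenseSubmatrixError as exc:
                last_exc = exc
        if snv_idx is None:
            raise last_exc
        labels = seed_clusters(matrices, snv_idx, cell_idx, n_clusters, sub_rng)
        model0 = init_model(matrices, cell_idx, labels, pseudo_alt, pseudo_total)
        result = run_em(matrices, model0, tol=tol, max_iter=max_iter)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    return best


def assign_cells(
    posterior: np.ndarray, threshold: float = DEFAULT_POSTERIOR_THRESHOLD
) -> np.ndarray:
    """Hard labels from the posterior: argmax cluster if its probability
    strictly exceeds ``threshold``, else -1 (unassigned)."""
    hard = posterior.argmax(axis=1)
    confident = posterior.max(axis=1) > threshold
    return np.where(confident, hard, -1)


def identify_doublet_cluster(
    assignment: CellAssignment, matrices: AlleleCountMatrices
) -> int:
    """Pick the doublet cluster by the cross-assignment log-likelihood.

    For each cluster c, every cell whose (argmax) home is some other
    cluster contributes its log-likelihood under cluster c's model plus
    the cluster weight term; the cluster that best explains everyone
    else's cells is the "average" one, i.e. the doublet cluster.  The
    contributions are averaged per foreign cell — clusters of different
    sizes see different numbers of foreign cells, and a raw sum would
    hand the comparison to whichever cluster has the fewest of them
    rather than to the best cross-fit.  Ties break toward the lowest
    index with a warning.
    """
    if assignment.model.n_clusters < 2:
        raise PoolsplitError("need at least 2 clusters to identify doublets")
    loglik = _cell_loglik(assignment.model, matrices)
    home = assignment.posterior.argmax(axis=1)
    logw = np.log(assignment.model.weights)
    k = assignment.model.n_clusters
    scores = np.empty(k)
    for c in range(k):
        others = home != c
        n_others = int(others.sum())
        if n_others == 0:
            scores[c] = -np.inf
            continue
        scores[c] = loglik[others, c].mean() + logw[c]
    top = np.flatnonzero(np.isclose(scores, scores.max(), rtol=0, atol=1e-9))
    if len(top) > 1:
        warnings.warn(
            f"doublet-cluster score tie between clusters {top.tolist()}; "
            "choosing the lowest index"
        )
    return int(top[0])


def label_cells(
    assignment: CellAssignment,
    threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
) -> CellAssignment:
    """Fill in per-cell labels given the identified doublet cluster."""
    if assignment.doublet_cluster is None:
        raise PoolsplitError("identify the doublet cluster first")
    hard = assign_cells(assignment.posterior, threshold)
    labels: list = []
    for h in hard:
        if h == -1:
            labels.append(UNASSIGNED)
        elif h == assignment.doublet_cluster:
            labels.append(DOUBLET)
        else:
            labels.append(int(h))
    assignment.labels = labels
    return assignment


def apply_doublet_expectation(
    assignment: CellAssignment,
    matrices: AlleleCountMatrices,
    expected_doublet_fraction: float,
) -> CellAssignment:
    """Top up doublet calls to the expected count by read depth.

    If fewer cells sit in the doublet cluster than
    ``round(fraction * n_cells)``, the singlet cells with the largest
    total read count are relabelled DBL until the expectation is met.
    Existing doublet calls are never demoted.
    """
    if not (0.0 <= expected_doublet_fraction < 1.0):
        raise PoolsplitError("expected doublet fraction must be in [0, 1)")
    if assignment.labels is None:
        raise PoolsplitError("label cells before applying the doublet expectation")
    labels = list(assignment.labels)
    expected = int(round(expected_doublet_fraction * len(labels)))
    current = sum(1 for lab in labels if lab == DOUBLET)
    deficit = expected - current
    if deficit > 0:
        depth = np.asarray(matrices.total().sum(axis=0)).ravel()
        singlet_idx = [i for i, lab in enumerate(labels) if isinstance(lab, int)]
        singlet_idx.sort(key=lambda i: (-depth[i], i))
        for i in singlet_idx[:deficit]:
            labels[i] = DOUBLET
    assignment.labels = labels
    return assignment
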