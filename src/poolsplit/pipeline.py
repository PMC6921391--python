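"""High-level orchestration: matrices in, labelled cells and mapping out."""

from __future__ import annotations

import numpy as np

from . import em as em_mod
from .allele_counter import AlleleCountMatrices
from .em import (
    DEFAULT_N_RESTARTS,
    DEFAULT_POSTERIOR_THRESHOLD,
    CellAssignment,
    apply_doublet_expectation,
    identify_doublet_cluster,
    label_cells,
    run_restarts,
)


def demultiplex(
    matrices: AlleleCountMatrices,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    posterior_threshold: float = DEFAULT_POSTERIOR_THRESHOLD,
    expected_doublet_fraction: float = 0.0,
    **em_kwargs,
) -> CellAssignment:
    """Full demultiplexing pass on pre-built count matrices.

    Runs best-of-``n_restarts`` EM with ``n_samples + 1`` clusters,
    designates the doublet cluster by cross-assignment likelihood,
    thresholds posteriors into hard labels and, when an expected doublet
    fraction is given, tops doublet calls up by read depth.  Returns a
    :class:`~poolsplit.em.CellAssignment` with ``labels`` populated
    (integer singlet cluster ids, ``"DBL"`` or ``"unassigned"``).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    assignment = run_restarts(
        matrices, n_samples, n_restarts=n_restarts, rng=rng, **em_kwargs
    )
    assignment.doublet_cluster = identify_doublet_cluster(assignment, matrices)
    assignment = label_cells(assignment, threshold=posterior_threshold)
    if expected_doublet_fraction > 0:
        assignment = apply_doublet_expectation(
            assignment, matrices, expected_doublet_fraction
        )
    return assignment


def singlet_clusters(assignment: CellAssignment) -> list[int]:
    """Cluster indices excluding the doublet cluster."""
    k = assignment.model.n_clusters
    return [c for c in range(k) if c != assignment.doublet_cluster]
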