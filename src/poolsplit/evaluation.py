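"""Score demultiplexing output against a known truth table.

Definitions follow the standard demultiplexing conventions: per truth
class, TPR is the fraction of that class's cells that were called
correctly (unassigned cells count against the denominator), FDR is the
fraction of cells *assigned* to the class that actually belong elsewhere
(unassigned cells do not enter FDR at all), and Cohen's kappa measures
overall agreement beyond chance over the assigned cells.

Same-donor doublets — merged barcode pairs whose two cells came from the
same donor — carry no genotypic signal whatsoever, so a caller that
labels one with its constituent donor has made no genotype error.  The
report therefore exposes both conventions: ``singlet_fdr`` excludes
those calls from the singlet FDR (they are counted separately), and
``singlet_fdr_strict`` counts them as errors.  Doublet TPR is likewise
reported overall and restricted to cross-donor merges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import PoolsplitError
from .simulator import SimulationTruth

DBL = "DBL"
UNASSIGNED = "unassigned"


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame  # truth classes x predicted classes
    per_class: pd.DataFrame  # index: class; columns: tpr, fdr, n_truth, n_assigned
    singlet_tpr: float
    singlet_fdr: float
    singlet_fdr_strict: float
    doublet_tpr: float
    doublet_fdr: float
    doublet_tpr_cross_donor: float
    average_tpr: float
    average_fdr: float
    kappa: float
    n_cells: int
    n_unassigned: int
    n_same_donor_doublets: int
    n_same_donor_doublets_called_singlet: int
    extras: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"cells evaluated:              {self.n_cells}",
            f"unassigned:                   {self.n_unassigned}",
            f"singlet TPR (avg over donors): {self.singlet_tpr:.4f}",
            f"singlet FDR:                  {self.singlet_fdr:.2e}",
            f"singlet FDR (strict):         {self.singlet_fdr_strict:.2e}",
            f"doublet TPR:                  {self.doublet_tpr:.4f}",
            f"doublet TPR (cross-donor):    {self.doublet_tpr_cross_donor:.4f}",
            f"doublet FDR:                  {self.doublet_fdr:.4f}",
            f"average TPR:                  {self.average_tpr:.4f}",
            f"average FDR:                  {self.average_fdr:.2e}",
            f"Cohen's kappa:                {self.kappa:.4f}",
            f"same-donor doublets:          {self.n_same_donor_doublets} "
            f"({self.n_same_donor_doublets_called_singlet} called singlet)",
            "",
            "confusion matrix (rows: truth, cols: predicted):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


def evaluate(
    predicted: dict[str, object],
    truth: SimulationTruth,
    mapping: dict | None = None,
    kappa_on_assigned: bool = True,
) -> EvaluationReport:
    """Compare per-barcode predictions with the simulation truth.

    ``predicted`` maps barcode to an integer cluster id (resolved to a
    donor through ``mapping``), or to the strings "DBL"/"unassigned", or
    directly to donor names (then ``mapping`` may be omitted).

    Raises when the barcodes differ from the truth's or when a predicted
    cluster id is missing from the mapping.
    """
    truth_labels = truth.labels()
    if set(predicted) != set(truth_labels):
        raise PoolsplitError("predicted and truth barcode sets differ")

    donors = sorted(set(truth.barcode_to_donor.values()))
    resolved: dict[str, str] = {}
    for bc, lab in predicted.items():
        if isinstance(lab, (int, np.integer)):
            if mapping is None or lab not in mapping:
                raise PoolsplitError(f"cluster {lab} missing from mapping")
            resolved[bc] = mapping[lab]
        else:
            resolved[bc] = str(lab)

    barcodes = list(truth_labels)
    t = pd.Series([truth_labels[bc] for bc in barcodes], index=barcodes)
    p = pd.Series([resolved[bc] for bc in barcodes], index=barcodes)
    pair_of = truth.doublet_pairs()
    same_donor = pd.Series(
        [
            t[bc] == DBL and pair_of[bc][0] == pair_of[bc][1]
            for bc in barcodes
        ],
        index=barcodes,
    )
    same_donor_as_own = same_donor & pd.Series(
        [
            t[bc] == DBL and same_donor[bc] and p[bc] == pair_of[bc][0]
            for bc in barcodes
        ],
        index=barcodes,
    )

    classes = donors + [DBL]
    pred_classes = classes + [UNASSIGNED]
    confusion = pd.crosstab(t, p).reindex(
        index=classes, columns=pred_classes, fill_value=0
    )

    rows = {}
    for cls in classes:
        in_class = t == cls
        called = p == cls
        n_truth = int(in_class.sum())
        n_assigned = int(called.sum())
        correct = int((in_class & called).sum())
        tpr = correct / n_truth if n_truth else np.nan
        if cls == DBL:
            incorrect = int((called & ~in_class).sum())
            denom = n_assigned
        else:
            # comparable FDR: same-donor doublets called as their own donor
            # are not genotype errors; excluded from numerator and denominator
            excused = called & same_donor_as_own
            incorrect = int((called & ~in_class & ~excused).sum())
            denom = n_assigned - int(excused.sum())
        fdr = incorrect / denom if denom else 0.0
        rows[cls] = {
            "tpr": tpr,
            "fdr": fdr,
            "n_truth": n_truth,
            "n_assigned": n_assigned,
        }
    per_class = pd.DataFrame(rows).T

    singlet_tpr = float(per_class.loc[donors, "tpr"].mean())
    singlet_fdr = float(per_class.loc[donors, "fdr"].mean())
    # strict convention: every assigned cell whose truth label differs is wrong
    strict = []
    for cls in donors:
        called = p == cls
        n_assigned = int(called.sum())
        incorrect = int((called & (t != cls)).sum())
        strict.append(incorrect / n_assigned if n_assigned else 0.0)
    singlet_fdr_strict = float(np.mean(strict)) if strict else 0.0

    is_dbl = t == DBL
    cross = is_dbl & ~same_donor
    doublet_tpr = float(per_class.loc[DBL, "tpr"])
    doublet_fdr = float(per_class.loc[DBL, "fdr"])
    doublet_tpr_cross = (
        float(((p == DBL) & cross).sum() / cross.sum()) if cross.sum() else np.nan
    )

    assigned = p != UNASSIGNED
    if kappa_on_assigned:
        kappa = (
            float(cohen_kappa_score(t[assigned], p[assigned]))
            if assigned.sum()
            else np.nan
        )
    else:
        kappa = float(cohen_kappa_score(t, p))

    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        singlet_tpr=singlet_tpr,
        singlet_fdr=singlet_fdr,
        singlet_fdr_strict=singlet_fdr_strict,
        doublet_tpr=doublet_tpr,
        doublet_fdr=doublet_fdr,
        doublet_tpr_cross_donor=doublet_tpr_cross,
        average_tpr=float(per_class["tpr"].mean()),
        average_fdr=float(per_class["fdr"].mean()),
        kappa=kappa,
        n_cells=len(barcodes),
        n_unassigned=int((~assigned).sum()),
        n_same_donor_doublets=int(same_donor.sum()),
        n_same_donor_doublets_called_singlet=int(same_donor_as_own.sum()),
    )
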