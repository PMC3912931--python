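"""Differential-expression acceptance filtering.

The upstream DE test (e.g. a Cuffdiff-style model) is consumed, not
reimplemented: this module takes per-gene p-values together with the
two compared FPKM values, applies Benjamini-Hochberg multiple-testing
correction across all candidates, and retains genes that pass both the
expression gate (FPKM strictly greater than a threshold in at least one
of the two samples, default 1.0) and the significance gate (adjusted
p strictly below a threshold, default 0.05). Retained genes are split
into up- and down-regulated lists by the sign of the B-minus-A change.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import TrioValidationError


class DEDirection(str, Enum):
    UP_IN_B = "up_in_b"
    DOWN_IN_B = "down_in_b"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class DECandidate:
    gene_id: str
    fpkm_a: float
    fpkm_b: float
    p_value: float


@dataclass
class DEFilterResult:
    table: pd.DataFrame  # gene_id, fpkm_a, fpkm_b, p_value, q_value, direction, retained, reason
    up: list[str]
    down: list[str]
    n_ambiguous: int


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Output order matches input order; q_i = min over j with
    p_(j) >= p_(i) of m*p_(j)/rank(j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise TrioValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(
    candidates: Sequence[DECandidate],
    fpkm_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> DEFilterResult:
    """Apply the expression and FDR gates; split retained genes by direction.

    BH adjustment runs over every candidate's p-value (the full tested
    universe), not only over genes passing the expression gate. A gene
    passing both gates with exactly tied FPKM values cannot be assigned
    a direction; it is flagged ambiguous and excluded from both lists,
    with the count reported.
    """
    for cand in candidates:
        if cand.fpkm_a < 0 or cand.fpkm_b < 0:
            raise TrioValidationError(f"negative FPKM for gene {cand.gene_id!r}")
    q = bh_adjust([c.p_value for c in candidates])
    rows = []
    up: list[str] = []
    down: list[str] = []
    n_ambiguous = 0
    for cand, q_value in zip(candidates, q):
        passes_fpkm = max(cand.fpkm_a, cand.fpkm_b) > fpkm_threshold
        passes_q = q_value < q_threshold
        if cand.fpkm_b > cand.fpkm_a:
            direction = DEDirection.UP_IN_B
        elif cand.fpkm_b < cand.fpkm_a:
            direction = DEDirection.DOWN_IN_B
        else:
            direction = DEDirection.AMBIGUOUS
        retained = passes_fpkm and passes_q and direction != DEDirection.AMBIGUOUS
        if passes_fpkm and passes_q and direction == DEDirection.AMBIGUOUS:
            reason = "ambiguous_direction"
            n_ambiguous += 1
        elif not passes_fpkm:
            reason = "below_fpkm_threshold"
        elif not passes_q:
            reason = "not_significant"
        else:
            reason = ""
        if retained:
            (up if direction == DEDirection.UP_IN_B else down).append(cand.gene_id)
        rows.append(
            {
                "gene_id": cand.gene_id,
                "fpkm_a": cand.fpkm_a,
                "fpkm_b": cand.fpkm_b,
                "p_value": cand.p_value,
                "q_value": q_value,
                "direction": direction.value,
                "retained": retained,
                "reason": reason,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "fpkm_a", "fpkm_b", "p_value", "q_value",
            "direction", "retained", "reason",
        ],
    )
    return DEFilterResult(table=table, up=up, down=down, n_ambiguous=n_ambiguous)
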