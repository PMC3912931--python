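"""Dominance-to-additive (d/a) inheritance analysis for an F1 hybrid.

For a gene with hybrid expression ``F1`` and inbred-parent expressions
``P_high`` (the designated reference parent, the denominator of the
ratio) and ``P_low``, with midparent value ``mu = (P_high + P_low)/2``:

    d/a = (F1 - mu) / (P_high - mu)

The ratio is 0 for purely additive inheritance (hybrid at midparent),
+1 for complete dominance of the high parent, -1 for complete dominance
of the low parent, and falls outside [-1, 1] when hybrid expression is
outside the parental range. It is undefined when the two parents are
indistinguishable (denominator within ``epsilon`` of zero).

A one-sample Wilcoxon signed-rank test on the collection of d/a values
asks whether hybrid expression genome-wide deviates from additivity and
in which parental direction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    Condition,
    ExpressionTable,
    GeneSet,
    Genotype,
    Tissue,
    TrioValidationError,
)


class DABin(str, Enum):
    """Inheritance-mode bin for a d/a value.

    The four open intervals mirror the conventional gene lists
    (below -1, between -1 and 0, between 0 and 1, above 1); exact
    boundary values get their own bins rather than being folded into a
    neighbouring interval, and an undefined ratio (equal parents) is
    reported as such.
    """

    OUTSIDE_LOW = "outside_low"      # d/a < -1: outside the low parent's range
    DOMINANT_LOW = "dominant_low"    # d/a = -1: low-parent dominance
    SKEWED_LOW = "skewed_low"        # -1 < d/a < 0: skewed toward the low parent
    ADDITIVE = "additive"            # d/a = 0: additive (midparent)
    SKEWED_HIGH = "skewed_high"      # 0 < d/a < 1: skewed toward the high parent
    DOMINANT_HIGH = "dominant_high"  # d/a = 1: high-parent dominance
    OUTSIDE_HIGH = "outside_high"    # d/a > 1: outside the high parent's range
    UNDEFINED = "undefined"


OPEN_BINS = (DABin.OUTSIDE_LOW, DABin.SKEWED_LOW, DABin.SKEWED_HIGH, DABin.OUTSIDE_HIGH)
BOUNDARY_BINS = (DABin.DOMINANT_LOW, DABin.ADDITIVE, DABin.DOMINANT_HIGH)


class BiasDirection(str, Enum):
    TOWARD_LOW = "toward_low"
    TOWARD_HIGH = "toward_high"
    NONE = "none"


@dataclass(frozen=True)
class DAResult:
    gene_id: str
    tissue: Tissue
    condition: Condition
    f1: float
    p_high: float
    p_low: float
    midparent: float
    da: float | None
    bin: DABin


@dataclass(frozen=True)
class BiasTestResult:
    n_genes: int
    statistic: float  # signed-rank statistic W+ (sum of positive ranks)
    p_value: float
    direction: BiasDirection


def da_ratio(
    f1: float, p_high: float, p_low: float, epsilon: float = 1e-9
) -> float | None:
    """The d/a ratio, or None when the parents are indistinguishable.

    ``p_high`` is the reference (denominator) parent. Returns None when
    |p_high - midparent| <= epsilon, i.e. the parents differ by at most
    2*epsilon.

    Numerics: the denominator p_high - mu is computed as the
    algebraically equal (p_high - p_low)/2, which swapping the parents
    negates exactly in floating point, so the antisymmetry
    da(f1, a, b) = -da(f1, b, a) holds bit-for-bit. Complete-dominance
    inputs (f1 equal to one parent) short-circuit to exactly +/-1.
    """
    for name, value in (("f1", f1), ("p_high", p_high), ("p_low", p_low)):
        if not math.isfinite(value):
            raise TrioValidationError(f"{name} must be finite, got {value}")
    half_diff = (p_high - p_low) / 2.0
    if abs(half_diff) <= epsilon:
        return None
    if f1 == p_high:
        return 1.0
    if f1 == p_low:
        return -1.0
    mu = (p_high + p_low) / 2.0
    return (f1 - mu) / half_diff


def classify_da(da: float | None, boundary_tol: float = 1e-9) -> DABin:
    """Map a d/a value to its inheritance bin.

    Values within ``boundary_tol`` of -1, 0 or 1 are assigned the exact
    boundary bins (dominant_low, additive, dominant_high); measured
    expression makes exact boundaries measure-zero, but simulated
    noise-free data lands on them and tests need determinism.
    """
    if da is None or (isinstance(da, float) and math.isnan(da)):
        return DABin.UNDEFINED
    if abs(da - 1.0) <= boundary_tol:
        return DABin.DOMINANT_HIGH
    if abs(da + 1.0) <= boundary_tol:
        return DABin.DOMINANT_LOW
    if abs(da) <= boundary_tol:
        return DABin.ADDITIVE
    if da < -1.0:
        return DABin.OUTSIDE_LOW
    if da < 0.0:
        return DABin.SKEWED_LOW
    if da < 1.0:
        return DABin.SKEWED_HIGH
    return DABin.OUTSIDE_HIGH


def da_table(
    expr: ExpressionTable,
    gene_set: GeneSet | None = None,
    fpkm_threshold: float = 1.0,
    epsilon: float = 1e-9,
    boundary_tol: float = 1e-9,
) -> tuple[list[DAResult], Counter]:
    """Per-gene d/a results for every (tissue, condition) cell.

    A gene enters a cell's analysis when it belongs to ``gene_set`` (if
    supplied) and at least one of the three genotypes exceeds
    ``fpkm_threshold`` in that cell — mirroring the inclusion rule
    "FPKM > 1 in either parent or the hybrid". Excluded gene-cells are
    tallied by reason in the returned counter
    (``not_in_gene_set``/``below_threshold``); gene-cells with
    indistinguishable parents are kept with bin ``undefined`` and
    counted under ``undefined_da``.
    """
    expr.validate()
    results: list[DAResult] = []
    exclusions: Counter = Counter()
    for tissue in Tissue:
        for condition in Condition:
            s_low = expr.sample_for(Genotype.PARENT_LOW, tissue, condition)
            s_high = expr.sample_for(Genotype.PARENT_HIGH, tissue, condition)
            s_hyb = expr.sample_for(Genotype.HYBRID, tissue, condition)
            for gene in expr.gene_ids:
                if gene_set is not None and gene not in gene_set:
                    exclusions["not_in_gene_set"] += 1
                    continue
                p_low = expr.fpkm(gene, s_low)
                p_high = expr.fpkm(gene, s_high)
                f1 = expr.fpkm(gene, s_hyb)
                if max(f1, p_high, p_low) <= fpkm_threshold:
                    exclusions["below_threshold"] += 1
                    continue
                da = da_ratio(f1, p_high, p_low, epsilon=epsilon)
                if da is None:
                    exclusions["undefined_da"] += 1
                results.append(
                    DAResult(
                        gene_id=gene,
                        tissue=tissue,
                        condition=condition,
                        f1=f1,
                        p_high=p_high,
                        p_low=p_low,
                        midparent=(p_high + p_low) / 2.0,
                        da=da,
                        bin=classify_da(da, boundary_tol=boundary_tol),
                    )
                )
    return results, exclusions


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p-value for the signed-rank statistic.

    Enumerates the null distribution of W+ (all 2^n sign assignments
    equally likely) by dynamic programming over doubled ranks, which are
    integers even with average-rank ties. Two-sided p is
    2*min(P(W+ <= w), P(W+ >= w)) capped at 1, the usual doubling rule.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_bias_test(
    da_values: Sequence[float],
    mu0: float = 0.0,
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> BiasTestResult:
    """One-sample two-sided Wilcoxon signed-rank test of median = ``mu0``.

    Zero differences are dropped; ties receive average ranks. The exact
    null distribution is enumerated for n <= ``exact_max_n``; larger
    samples use the normal approximation with tie correction and
    continuity correction. The reported direction is read from the
    median of the inputs, and is ``none`` unless the test is significant
    at ``alpha``.
    """
    values = np.asarray(list(da_values), dtype=float)
    if values.size == 0:
        raise TrioValidationError("wilcoxon_bias_test requires at least one value")
    if not np.isfinite(values).all():
        raise TrioValidationError("wilcoxon_bias_test requires finite values")
    diffs = values - mu0
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return BiasTestResult(
            n_genes=0, statistic=0.0, p_value=1.0, direction=BiasDirection.NONE
        )
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # variance with average-rank tie correction
        _, tie_counts = np.unique(np.abs(diffs), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if var <= 0:
            p = 1.0
        else:
            delta = w_plus - mean
            cc = 0.5 * np.sign(delta)
            z = (delta - cc) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    direction = BiasDirection.NONE
    if p < alpha:
        median = float(np.median(values))
        if median > mu0:
            direction = BiasDirection.TOWARD_HIGH
        elif median < mu0:
            direction = BiasDirection.TOWARD_LOW
    return BiasTestResult(n_genes=n, statistic=w_plus, p_value=p, direction=direction)


def summarize_bins(results: Iterable[DAResult]) -> pd.DataFrame:
    """Contingency table of bin counts per (tissue, condition).

    Rows are the four (tissue, condition) cells; columns the four open
    d/a bins first, then the exact-boundary bins and ``undefined``,
    reported separately rather than folded into the open intervals.
    """
    bin_order = [b.value for b in OPEN_BINS] + [b.value for b in BOUNDARY_BINS] + [
        DABin.UNDEFINED.value
    ]
    index = pd.MultiIndex.from_product(
        [[t.value for t in Tissue], [c.value for c in Condition]],
        names=["tissue", "condition"],
    )
    table = pd.DataFrame(0, index=index, columns=bin_order, dtype=int)
    for res in results:
        table.loc[(res.tissue.value, res.condition.value), res.bin.value] += 1
    return table


def results_to_frame(results: Iterable[DAResult]) -> pd.DataFrame:
    """Flatten DAResults to a DataFrame for TSV output."""
    rows = [
        {
            "gene_id": r.gene_id,
            "tissue": r.tissue.value,
            "condition": r.condition.value,
            "f1": r.f1,
            "p_high": r.p_high,
            "p_low": r.p_low,
            "midparent": r.midparent,
            "da": r.da if r.da is not None else float("nan"),
            "bin": r.bin.value,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue", "condition", "f1", "p_high", "p_low",
            "midparent", "da", "bin",
        ],
    )
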