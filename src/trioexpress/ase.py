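"""Allele-specific expression in the hybrid at SNPs between the parents.

The workflow mirrors how ASE is measured from a pair of parental
transcriptomes: call SNPs between the paired parental transcripts,
count hybrid reads supporting each parental base at every SNP (reads
aligned against the parent-low transcriptome are scored for the
parent-low base, reads against the parent-high transcriptome for the
parent-high base), aggregate depths per gene, keep genes whose mean
informative depth per SNP strictly exceeds a cutoff (default 10), and
test each gene's allele totals against a balanced 50:50 null with a
two-sided binomial exact test (default alpha 0.05).

Per-gene aggregation treats each read-SNP observation as an
independent draw; a read overlapping several SNPs contributes once per
SNP. Reads covering a SNP but matching neither parental base are
tallied separately (``depth_other``) and excluded from the test.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .core_io import NUCLEOTIDES, AlignedRead, SnpRecord, TrioValidationError
from .defilter import bh_adjust


class AseDirection(str, Enum):
    LOW_HIGHER = "low_higher"
    HIGH_HIGHER = "high_higher"
    BALANCED = "balanced"


@dataclass(frozen=True)
class AlleleDepth:
    snp: SnpRecord
    depth_low: int
    depth_high: int
    depth_other: int


@dataclass(frozen=True)
class GeneAseResult:
    gene_id: str
    n_snps: int
    total_low: int
    total_high: int
    mean_depth_per_snp: float
    p_value: float | None = None
    q_value: float | None = None
    significant: bool = False
    direction: AseDirection = AseDirection.BALANCED


def call_snps(
    low_transcripts: Mapping[str, str],
    high_transcripts: Mapping[str, str],
    pairing: Mapping[str, str] | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> tuple[list[SnpRecord], int]:
    """Call SNPs between paired, length-matched parental transcripts.

    ``pairing`` maps parent-low transcript id to parent-high transcript
    id (identity by default); ``gene_map`` maps the low transcript id to
    its gene id (default: the transcript id itself). Positions where
    either base is not an unambiguous A/C/G/T are skipped; the skip
    count is returned alongside the records. Length mismatches are an
    error, since the comparison assumes a common coordinate frame.
    """
    if pairing is None:
        pairing = {tid: tid for tid in low_transcripts}
    snps: list[SnpRecord] = []
    n_skipped = 0
    for low_id in sorted(pairing):
        high_id = pairing[low_id]
        seq_low = low_transcripts[low_id].upper()
        seq_high = high_transcripts[high_id].upper()
        if len(seq_low) != len(seq_high):
            raise TrioValidationError(
                f"transcript pair {low_id}/{high_id} lengths differ: "
                f"{len(seq_low)} vs {len(seq_high)}"
            )
        gene = gene_map[low_id] if gene_map is not None else low_id
        for i, (base_low, base_high) in enumerate(zip(seq_low, seq_high)):
            if base_low == base_high:
                continue
            if base_low not in NUCLEOTIDES or base_high not in NUCLEOTIDES:
                n_skipped += 1
                continue
            snps.append(
                SnpRecord(
                    transcript_id=low_id,
                    gene_id=gene,
                    position=i + 1,
                    allele_low=base_low,
                    allele_high=base_high,
                )
            )
    return snps, n_skipped


def count_allele_depths(
    reads_vs_low: Sequence[AlignedRead],
    reads_vs_high: Sequence[AlignedRead],
    snps: Sequence[SnpRecord],
) -> list[AlleleDepth]:
    """Count reads supporting each parental base at every SNP.

    ``depth_low`` counts reads from the parent-low alignment whose base
    at the SNP equals the parent-low allele; ``depth_high`` likewise
    from the parent-high alignment; ``depth_other`` counts covering
    reads (in either file) matching neither parental base. A read
    contributes at most once per SNP per file, keyed by read id.
    """
    by_tx_low: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads_vs_low:
        by_tx_low[read.transcript_id].append(read)
    by_tx_high: dict[str, list[AlignedRead]] = defaultdict(list)
    for read in reads_vs_high:
        by_tx_high[read.transcript_id].append(read)

    depths: list[AlleleDepth] = []
    for snp in snps:
        d_low = d_high = d_other = 0
        seen: set[str] = set()
        for read in by_tx_low.get(snp.transcript_id, ()):
            if read.read_id in seen:
                continue
            base = read.base_at(snp.position)
            if base is None:
                continue
            seen.add(read.read_id)
            if base == snp.allele_low:
                d_low += 1
            elif base != snp.allele_high:
                d_other += 1
        seen = set()
        for read in by_tx_high.get(snp.transcript_id, ()):
            if read.read_id in seen:
                continue
            base = read.base_at(snp.position)
            if base is None:
                continue
            seen.add(read.read_id)
            if base == snp.allele_high:
                d_high += 1
            elif base != snp.allele_low:
                d_other += 1
        depths.append(
            AlleleDepth(snp=snp, depth_low=d_low, depth_high=d_high, depth_other=d_other)
        )
    return depths


def aggregate_and_filter(
    depths: Iterable[AlleleDepth],
    min_mean_depth: float = 10.0,
) -> tuple[list[GeneAseResult], Counter]:
    """Sum allele depths per gene and apply the mean-depth filter.

    Mean depth per SNP uses informative reads only, i.e.
    (total_low + total_high)/n_snps; ``depth_other`` does not count.
    Genes are retained when the mean strictly exceeds
    ``min_mean_depth``. Returns pre-test results (no p-values yet) and
    a counter of exclusions by reason.
    """
    per_gene: dict[str, list[AlleleDepth]] = defaultdict(list)
    for depth in depths:
        per_gene[depth.snp.gene_id].append(depth)
    results: list[GeneAseResult] = []
    exclusions: Counter = Counter()
    for gene in sorted(per_gene):
        gene_depths = per_gene[gene]
        total_low = sum(d.depth_low for d in gene_depths)
        total_high = sum(d.depth_high for d in gene_depths)
        n_snps = len(gene_depths)
        mean_depth = (total_low + total_high) / n_snps
        if not mean_depth > min_mean_depth:
            exclusions["below_min_mean_depth"] += 1
            continue
        results.append(
            GeneAseResult(
                gene_id=gene,
                n_snps=n_snps,
                total_low=total_low,
                total_high=total_high,
                mean_depth_per_snp=mean_depth,
            )
        )
    return results, exclusions


def binomial_exact_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided binomial exact p-value by the minimum-likelihood method.

    Sums Binomial(n, p0) probabilities over all outcomes no more likely
    than the observed ``k``.
    """
    if n < 1:
        raise TrioValidationError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise TrioValidationError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise TrioValidationError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def test_allelic_imbalance(
    gene_counts: Sequence[GeneAseResult],
    alpha: float = 0.05,
    bh: bool = False,
) -> tuple[list[GeneAseResult], Counter]:
    """Binomial exact test of each gene's allele totals against 50:50.

    ``significant`` means p (or, with ``bh=True``, the BH-adjusted q)
    below ``alpha``; direction follows the larger total when
    significant, ``balanced`` otherwise. Genes with zero informative
    reads are excluded and counted.
    """
    testable: list[GeneAseResult] = []
    exclusions: Counter = Counter()
    for res in gene_counts:
        if res.total_low + res.total_high < 1:
            exclusions["zero_informative_reads"] += 1
            continue
        testable.append(res)
    p_values = [
        binomial_exact_test(res.total_high, res.total_low + res.total_high)
        for res in testable
    ]
    q_values = list(bh_adjust(p_values)) if (bh and p_values) else [None] * len(p_values)
    out: list[GeneAseResult] = []
    for res, p, q in zip(testable, p_values, q_values):
        crit = q if bh else p
        significant = crit < alpha
        if significant and res.total_high > res.total_low:
            direction = AseDirection.HIGH_HIGHER
        elif significant and res.total_low > res.total_high:
            direction = AseDirection.LOW_HIGHER
        else:
            direction = AseDirection.BALANCED
        out.append(
            replace(res, p_value=p, q_value=q, significant=significant, direction=direction)
        )
    return out, exclusions


# the name follows the "test the imbalance" operation; keep pytest from
# collecting it as a test when the module is imported in a test session
test_allelic_imbalance.__test__ = False  # type: ignore[attr-defined]


def compare_conditions(
    results_a: Sequence[GeneAseResult],
    results_b: Sequence[GeneAseResult],
) -> dict:
    """Overlap of significant allelic imbalance between two conditions.

    Restricted to genes testable in both; counts genes significant in A
    only, B only, both, or neither, and splits the shared significant
    set by whether the imbalance direction agrees.
    """
    by_id_a = {r.gene_id: r for r in results_a}
    by_id_b = {r.gene_id: r for r in results_b}
    shared = sorted(set(by_id_a) & set(by_id_b))
    sig_a = {g for g in shared if by_id_a[g].significant}
    sig_b = {g for g in shared if by_id_b[g].significant}
    both = sig_a & sig_b
    return {
        "n_testable_both": len(shared),
        "a_only": len(sig_a - sig_b),
        "b_only": len(sig_b - sig_a),
        "both": len(both),
        "neither": len(shared) - len(sig_a | sig_b),
        "both_same_direction": sum(
            1 for g in both if by_id_a[g].direction == by_id_b[g].direction
        ),
        "both_opposite_direction": sum(
            1 for g in both if by_id_a[g].direction != by_id_b[g].direction
        ),
    }


def depths_to_frame(depths: Iterable[AlleleDepth]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": d.snp.transcript_id,
            "gene_id": d.snp.gene_id,
            "position": d.snp.position,
            "allele_low": d.snp.allele_low,
            "allele_high": d.snp.allele_high,
            "depth_low": d.depth_low,
            "depth_high": d.depth_high,
            "depth_other": d.depth_other,
        }
        for d in depths
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "position", "allele_low", "allele_high",
            "depth_low", "depth_high", "depth_other",
        ],
    )


def ase_results_to_frame(results: Iterable[GeneAseResult]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "n_snps": r.n_snps,
            "total_low": r.total_low,
            "total_high": r.total_high,
            "mean_depth_per_snp": r.mean_depth_per_snp,
            "p_value": r.p_value if r.p_value is not None else float("nan"),
            "q_value": r.q_value if r.q_value is not None else float("nan"),
            "significant": r.significant,
            "direction": r.direction.value,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_snps", "total_low", "total_high", "mean_depth_per_snp",
            "p_value", "q_value", "significant", "direction",
        ],
    )
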