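"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are used to check: the binomial oracle works in exact
rational arithmetic, the signed-rank oracle enumerates all sign
assignments, and the BH oracle is a literal step-up transcription.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def binomial_two_sided_half(k: int, n: int) -> Fraction:
    """Exact two-sided minimum-likelihood p-value at p0 = 1/2.

    With a symmetric null the pmf is proportional to C(n, j), so the
    sum over outcomes no more likely than k is exact integer
    arithmetic.
    """
    weights = [math.comb(n, j) for j in range(n + 1)]
    observed = weights[k]
    total = sum(w for w in weights if w <= observed)
    return min(Fraction(1), Fraction(total, 2**n))


def signed_rank_two_sided(values, mu0: float = 0.0) -> float:
    """Exact two-sided one-sample signed-rank p-value by enumeration.

    Drops zero differences, assigns average ranks to tied absolute
    differences, enumerates all 2^n sign vectors, and doubles the
    smaller tail of W+ (capped at 1). Only feasible for small n.
    """
    diffs = [v - mu0 for v in values if v != mu0]
    n = len(diffs)
    if n == 0:
        return 1.0
    abs_sorted = sorted((abs(d), i) for i, d in enumerate(diffs))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs_sorted[j + 1][0] == abs_sorted[i][0]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for _, orig in abs_sorted[i : j + 1]:
            ranks[orig] = avg
        i = j + 1
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            n_le += 1
        if w >= w_obs - 1e-12:
            n_ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def bh_step_up(p_values):
    """Literal BH step-up: q_i = min_{p_(j) >= p_(i)} m * p_(j) / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, m * p_values[i] / (rank_idx + 1))
        q_sorted[rank_idx] = running
    q = [0.0] * m
    for rank_idx, i in enumerate(order):
        q[i] = q_sorted[rank_idx]
    return q


def naive_allele_totals(reads_low, reads_high, snps):
    """Brute-force per-gene allele totals by scanning every read at every SNP.

    Mirrors the counting contract (dedup by read id per SNP per file)
    without any indexing by transcript.
    """
    lows_by_tx: dict[str, list] = {}
    for read in reads_low:
        lows_by_tx.setdefault(read.transcript_id, []).append(read)
    highs_by_tx: dict[str, list] = {}
    for read in reads_high:
        highs_by_tx.setdefault(read.transcript_id, []).append(read)
    totals: dict[str, list[int]] = {}
    for snp in snps:
        low = high = 0
        seen = set()
        for read in lows_by_tx.get(snp.transcript_id, []):
            if read.read_id in seen:
                continue
            if read.start <= snp.position <= read.start + len(read.sequence) - 1:
                seen.add(read.read_id)
                if read.sequence[snp.position - read.start] == snp.allele_low:
                    low += 1
        seen = set()
        for read in highs_by_tx.get(snp.transcript_id, []):
            if read.read_id in seen:
                continue
            if read.start <= snp.position <= read.start + len(read.sequence) - 1:
                seen.add(read.read_id)
                if read.sequence[snp.position - read.start] == snp.allele_high:
                    high += 1
        acc = totals.setdefault(snp.gene_id, [0, 0, 0])
        acc[0] += low
        acc[1] += high
        acc[2] += 1
    return {g: {"low": v[0], "high": v[1], "n_snps": v[2]} for g, v in totals.items()}
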