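"""Synthetic trio data with known ground truth.

Emulates the design of a maize inbred x inbred x F1 hybrid expression
study: two parental genotypes and their hybrid, profiled in two tissues
(leaf, root) under two nitrogen regimes (sufficient, limiting) — twelve
samples in all. Every simulated gene carries a known inheritance mode
and a known allelic-imbalance ratio, recorded in a truth table so that
downstream estimates can be scored against the generating values.

Expression model, per gene and per (tissue, condition) cell: the two
parental means are drawn independently from a log-normal; the hybrid
mean is placed along the parental axis at

    hybrid = midparent + t * (parent_high - midparent)

where ``t`` is the gene's true d/a value — exactly 0 for additive
genes, exactly 1 for high-parent dominant genes, and uniform on
(-2,-1), (-1,0), (0,1) or (1,2) for the four open inheritance bins
(the outside bins are truncated at +/-2; any bounded support serves
recovery tests). Multiplicative log-normal noise with a configurable
coefficient of variation is applied to all three observed values.

Read model: each planted SNP receives Poisson-distributed coverage;
each read covers its SNP, is drawn from one parental haplotype
(parent-high with the gene's imbalance probability), and is reported at
its true position against both parental transcriptomes. Read ids
encode the true allele for auditing. No sequencing errors, quality
scores or fragment-length structure are simulated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    AlignedRead,
    Condition,
    ExpressionTable,
    Genotype,
    SnpRecord,
    Tissue,
    TrioValidationError,
)

#: Inheritance modes, in bin order from "below the low parent" upward.
INHERITANCE_MODES = (
    "outside_low",
    "skewed_low",
    "additive",
    "skewed_high",
    "dominant_high",
    "outside_high",
)

#: d/a support for each mode: a fixed point or an open interval.
_MODE_DA = {
    "outside_low": (-2.0, -1.0),
    "skewed_low": (-1.0, 0.0),
    "additive": 0.0,
    "skewed_high": (0.0, 1.0),
    "dominant_high": 1.0,
    "outside_high": (1.0, 2.0),
}

_BASES = np.array(list("ACGT"))


def _default_inheritance_mix() -> dict[str, float]:
    # Skewed toward the high parent, echoing the genome-wide bias the
    # d/a analysis is designed to detect; small exact-boundary classes
    # exercise the additive/dominant bins.
    return {
        "outside_low": 0.20,
        "skewed_low": 0.20,
        "additive": 0.05,
        "skewed_high": 0.25,
        "dominant_high": 0.05,
        "outside_high": 0.25,
    }


def _default_imbalance_ratios() -> dict[str, float]:
    return {"balanced": 0.5, "high_biased": 0.8, "low_biased": 0.2}


def _default_ase_class_mix() -> dict[str, float]:
    return {"balanced": 0.7, "high_biased": 0.2, "low_biased": 0.1}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trio.

    ``base_expression_log_mean``/``base_expression_log_sd`` are natural-log
    FPKM parameters of the parental log-normal (defaults give a median
    around 4.5 FPKM with a realistic dynamic range). ``noise_cv`` is the
    coefficient of variation of the multiplicative observation noise.
    ``imbalance_ratios`` gives, per gene class, the probability that a
    hybrid read carries the parent-high allele; ``ase_class_mix`` gives
    the class proportions.
    """

    n_genes: int = 200
    inheritance_mix: Mapping[str, float] = field(default_factory=_default_inheritance_mix)
    base_expression_log_mean: float = 1.5
    base_expression_log_sd: float = 1.0
    noise_cv: float = 0.1
    snps_per_transcript_mean: float = 3.0
    read_depth_per_snp_mean: float = 30.0
    imbalance_ratios: Mapping[str, float] = field(default_factory=_default_imbalance_ratios)
    ase_class_mix: Mapping[str, float] = field(default_factory=_default_ase_class_mix)
    transcript_length: int = 300
    read_length: int = 36
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise TrioValidationError("n_genes must be positive")
        mix_sum = sum(self.inheritance_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise TrioValidationError(f"inheritance_mix must sum to 1, got {mix_sum}")
        unknown = set(self.inheritance_mix) - set(INHERITANCE_MODES)
        if unknown:
            raise TrioValidationError(f"unknown inheritance modes: {sorted(unknown)}")
        if any(p < 0 for p in self.inheritance_mix.values()):
            raise TrioValidationError("inheritance_mix proportions must be >= 0")
        if self.base_expression_log_sd <= 0:
            raise TrioValidationError(
                "base_expression_log_sd must be > 0 (zero spread forces equal "
                "parents and an undefined d/a for every gene)"
            )
        if self.noise_cv < 0:
            raise TrioValidationError("noise_cv must be >= 0")
        if self.snps_per_transcript_mean < 0:
            raise TrioValidationError("snps_per_transcript_mean must be >= 0")
        if self.read_depth_per_snp_mean <= 0:
            raise TrioValidationError("read_depth_per_snp_mean must be > 0")
        for cls, ratio in self.imbalance_ratios.items():
            if not 0.0 < ratio < 1.0:
                raise TrioValidationError(
                    f"imbalance ratio for class {cls!r} must be in (0, 1), got {ratio}"
                )
        cls_sum = sum(self.ase_class_mix.values())
        if abs(cls_sum - 1.0) > 1e-9:
            raise TrioValidationError(f"ase_class_mix must sum to 1, got {cls_sum}")
        if set(self.ase_class_mix) - set(self.imbalance_ratios):
            raise TrioValidationError("every ase class needs an imbalance ratio")
        if self.transcript_length < self.read_length:
            raise TrioValidationError("transcript_length must be >= read_length")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inheritance_mix"] = dict(self.inheritance_mix)
        d["imbalance_ratios"] = dict(self.imbalance_ratios)
        d["ase_class_mix"] = dict(self.ase_class_mix)
        return d


@dataclass
class TruthTable:
    """Ground truth for a simulated gene set.

    ``genes`` is indexed by gene_id with columns ``mode`` (inheritance
    mode), ``true_da`` (the noise-free d/a), ``ase_class`` and
    ``imbalance_ratio``. ``cell_means`` holds the noise-free parental
    and hybrid means per (gene, tissue, condition).
    """

    genes: pd.DataFrame
    cell_means: pd.DataFrame


def _allocate(n: int, proportions: Mapping[str, float], order: tuple[str, ...]) -> list[str]:
    """Deterministic largest-remainder allocation of n items to classes."""
    keys = [k for k in order if proportions.get(k, 0.0) > 0]
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    remaining = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:remaining]:
        counts[k] += 1
    labels: list[str] = []
    for k in keys:
        labels.extend([k] * counts[k])
    return labels


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{str(i + 1).zfill(width)}" for i in range(n)]


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    # mean-one log-normal so noise does not shift expectations
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_trio_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionTable, TruthTable]:
    """Simulate the 12-sample trio expression table with ground truth.

    Inheritance modes are assigned by deterministic largest-remainder
    allocation of ``inheritance_mix`` (the realised composition matches
    the configured proportions exactly up to rounding); each gene's true
    d/a ``t`` is drawn once and applied in all four (tissue, condition)
    cells, while parental means are drawn independently per cell.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    modes = _allocate(config.n_genes, config.inheritance_mix, INHERITANCE_MODES)

    true_da = np.empty(config.n_genes)
    for i, mode in enumerate(modes):
        support = _MODE_DA[mode]
        true_da[i] = support if isinstance(support, float) else rng.uniform(*support)

    sample_rows = []
    for genotype in Genotype:
        for tissue in Tissue:
            for condition in Condition:
                sample_rows.append(
                    {
                        "sample_id": f"{genotype.value}_{tissue.value}_{condition.value}",
                        "genotype": genotype.value,
                        "tissue": tissue.value,
                        "condition": condition.value,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    values = pd.DataFrame(
        0.0, index=pd.Index(genes, name="gene_id"), columns=samples.index
    )
    mean_rows = []
    for tissue in Tissue:
        for condition in Condition:
            p_low_mean = rng.lognormal(
                config.base_expression_log_mean,
                config.base_expression_log_sd,
                config.n_genes,
            )
            p_high_mean = rng.lognormal(
                config.base_expression_log_mean,
                config.base_expression_log_sd,
                config.n_genes,
            )
            mid = (p_low_mean + p_high_mean) / 2.0
            hybrid_mean = mid + true_da * (p_high_mean - mid)
            # the d/a placement can go negative for wide parental draws in
            # the outside bins; FPKM means must be non-negative, so those
            # gene-cells get fresh parental draws (the gene's true d/a is
            # kept, so truth recovery stays exact)
            for _ in range(1000):
                bad = hybrid_mean < 0
                if not bad.any():
                    break
                n_bad = int(bad.sum())
                p_low_mean[bad] = rng.lognormal(
                    config.base_expression_log_mean,
                    config.base_expression_log_sd,
                    n_bad,
                )
                p_high_mean[bad] = rng.lognormal(
                    config.base_expression_log_mean,
                    config.base_expression_log_sd,
                    n_bad,
                )
                mid[bad] = (p_low_mean[bad] + p_high_mean[bad]) / 2.0
                hybrid_mean[bad] = mid[bad] + true_da[bad] * (p_high_mean[bad] - mid[bad])
            else:
                raise TrioValidationError(
                    "could not place a non-negative hybrid mean; the expression "
                    "spread is too wide for the configured outside-bin d/a range"
                )
            obs = {
                Genotype.PARENT_LOW: p_low_mean
                * _noise_factors(rng, config.noise_cv, config.n_genes),
                Genotype.PARENT_HIGH: p_high_mean
                * _noise_factors(rng, config.noise_cv, config.n_genes),
                Genotype.HYBRID: hybrid_mean
                * _noise_factors(rng, config.noise_cv, config.n_genes),
            }
            for genotype, vec in obs.items():
                sid = f"{genotype.value}_{tissue.value}_{condition.value}"
                values[sid] = vec
            for i, gene in enumerate(genes):
                mean_rows.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue.value,
                        "condition": condition.value,
                        "p_low_mean": p_low_mean[i],
                        "p_high_mean": p_high_mean[i],
                        "hybrid_mean": hybrid_mean[i],
                    }
                )

    truth_genes = pd.DataFrame(
        {"mode": modes, "true_da": true_da},
        index=pd.Index(genes, name="gene_id"),
    )
    truth = TruthTable(genes=truth_genes, cell_means=pd.DataFrame(mean_rows))
    table = ExpressionTable(values=values, samples=samples)
    table.validate()
    return table, truth


def simulate_parental_transcripts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], list[SnpRecord]]:
    """One transcript pair per gene with planted SNPs.

    The two sequences are identical except at Poisson-distributed
    positions where the parent-high copy carries a different base; the
    returned SNP table records exactly the planted differences.
    Transcript ids are ``<gene_id>_t``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    low: dict[str, str] = {}
    high: dict[str, str] = {}
    snps: list[SnpRecord] = []
    length = config.transcript_length
    for gene in genes:
        tid = f"{gene}_t"
        seq = rng.choice(_BASES, size=length)
        n_snps = min(int(rng.poisson(config.snps_per_transcript_mean)), length)
        positions = np.sort(rng.choice(length, size=n_snps, replace=False))
        seq_high = seq.copy()
        for pos0 in positions:
            ref = seq[pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            seq_high[pos0] = alt
            snps.append(
                SnpRecord(
                    transcript_id=tid,
                    gene_id=gene,
                    position=int(pos0) + 1,
                    allele_low=ref,
                    allele_high=alt,
                )
            )
        low[tid] = "".join(seq)
        high[tid] = "".join(seq_high)
    return low, high, snps


def assign_ase_classes(
    config: SimulationConfig, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Deterministic per-gene allelic-imbalance classes and ratios."""
    if gene_ids is None:
        gene_ids = _gene_ids(config.n_genes)
    classes = _allocate(
        len(gene_ids), config.ase_class_mix, tuple(sorted(config.ase_class_mix))
    )
    return pd.DataFrame(
        {
            "ase_class": classes,
            "imbalance_ratio": [config.imbalance_ratios[c] for c in classes],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def simulate_hybrid_reads(
    low_transcripts: Mapping[str, str],
    high_transcripts: Mapping[str, str],
    snps: list[SnpRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ase_truth: pd.DataFrame | None = None,
) -> tuple[list[AlignedRead], list[AlignedRead], pd.DataFrame]:
    """Hybrid reads over planted SNPs, reported against both parents.

    Every SNP gets Poisson coverage; each read is a ``read_length``
    window containing the SNP, copied from the parent-high haplotype
    with the gene's imbalance probability and from the parent-low
    haplotype otherwise, so all SNPs inside the window are phase
    consistent. The same read (id, position, sequence) appears in both
    returned alignment lists — the read is one molecule observed
    against two references. Read ids end in ``|H`` or ``|L`` recording
    the true haplotype. Returns the per-gene ASE truth alongside.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if ase_truth is None:
        gene_ids = sorted({snp.gene_id for snp in snps})
        ase_truth = assign_ase_classes(config, gene_ids)
    reads: list[AlignedRead] = []
    rl = config.read_length
    serial = 0
    for snp in snps:
        seq_low = low_transcripts[snp.transcript_id]
        seq_high = high_transcripts[snp.transcript_id]
        length = len(seq_low)
        ratio = float(ase_truth.at[snp.gene_id, "imbalance_ratio"])
        depth = int(rng.poisson(config.read_depth_per_snp_mean))
        lo = max(1, snp.position - rl + 1)
        hi = min(snp.position, length - rl + 1)
        for _ in range(depth):
            is_high = bool(rng.random() < ratio)
            start = int(rng.integers(lo, hi + 1))
            source = seq_high if is_high else seq_low
            serial += 1
            reads.append(
                AlignedRead(
                    read_id=(
                        f"{snp.gene_id}|{snp.transcript_id}:{snp.position}"
                        f"|{serial}|{'H' if is_high else 'L'}"
                    ),
                    transcript_id=snp.transcript_id,
                    start=start,
                    sequence=source[start - 1 : start - 1 + rl],
                )
            )
    # one molecule, two references: identical lists by construction
    return reads, list(reads), ase_truth


def simulate_de_pvalues(
    n_genes: int,
    signal_fraction: float = 0.1,
    seed: int = 0,
    signal_beta_a: float = 0.1,
    signal_beta_b: float = 4.0,
) -> pd.DataFrame:
    """Per-gene p-values for exercising the DE filter.

    Null genes draw p ~ Uniform(0,1); signal genes draw from a
    Beta(a, b) concentrated near zero. Returns gene_id, p_value and the
    ground-truth ``is_signal`` flag.
    """
    if not 0.0 <= signal_fraction <= 1.0:
        raise TrioValidationError("signal_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_signal = int(round(n_genes * signal_fraction))
    is_signal = np.zeros(n_genes, dtype=bool)
    is_signal[:n_signal] = True
    p = np.where(
        is_signal,
        rng.beta(signal_beta_a, signal_beta_b, n_genes),
        rng.uniform(0.0, 1.0, n_genes),
    )
    return pd.DataFrame(
        {"gene_id": _gene_ids(n_genes), "p_value": p, "is_signal": is_signal}
    )
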