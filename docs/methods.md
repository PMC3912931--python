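# Methods

## The trio design

The package models a three-genotype experiment: two inbred lines (called
`parent_low` and `parent_high`; the latter is the reference parent, i.e. the
denominator parent of the d/a ratio) and their F1 hybrid, each profiled in
two tissues (leaf, root) under two nitrogen regimes (sufficient, limiting) —
twelve samples. Expression values are FPKM-like: non-negative,
length- and depth-normalised, with "expressed" meaning strictly greater
than 1. All analyses are run per (tissue, condition) cell from that cell's
single expression value per genotype; no replicate averaging is assumed.
Gene identifiers are the unit of analysis throughout (isoform-level tables
should be collapsed before input).

## d/a inheritance analysis

For each gene and cell, d/a = (F1 − μ)/(P1 − μ) with μ the parental mean
and P1 the reference parent. Genes enter a cell's analysis when FPKM
exceeds 1 in at least one of the three genotypes (strict inequality) and,
when a whitelist is supplied, the gene belongs to it.

Decisions where the convention was genuinely open:

* **Equal parents.** When |P1 − μ| ≤ ε (default 1e−9), d/a is undefined.
  Such gene-cells are kept in the result table with bin `undefined` and
  counted, but excluded from the bias test and from the open-interval bin
  counts. Silently coercing them into a bin would distort the counts, and
  dropping them silently would hide how often the situation occurs.
* **Boundary values.** Measured expression essentially never lands exactly
  on −1, 0 or 1, but noise-free simulated data does. Values within a
  tolerance (default 1e−9) of a boundary are assigned dedicated bins
  (`dominant_low`, `additive`, `dominant_high`) rather than being folded
  into an adjacent open interval, and are reported separately.
* **Numerics.** The denominator P1 − μ is computed as (P1 − P2)/2, which is
  algebraically identical but negates exactly in floating point when the
  parents are swapped, making the antisymmetry d/a(F1, a, b) =
  −d/a(F1, b, a) hold bit-for-bit; hybrid expression exactly equal to a
  parent short-circuits to ±1. This keeps the defining identities exact
  rather than exact-up-to-rounding.

The genome-wide bias test is a one-sample two-sided Wilcoxon signed-rank
test of median 0 on the defined d/a values of a cell. Zero differences are
dropped; tied absolute values receive average ranks. For n ≤ 25 the exact
null distribution of W+ is enumerated by dynamic programming over doubled
ranks (doubling makes average ranks integral), with the two-sided p-value
defined as twice the smaller tail, capped at 1; larger samples use the
normal approximation with tie-corrected variance and continuity correction.
The implementation is in-package because the exact path must accept ties,
which off-the-shelf exact routines decline; the approximate path is
cross-checked against scipy in the tests. The reported direction
(`toward_high`/`toward_low`) is read from the sample median and only
assigned when the test is significant at alpha 0.05; the test itself is
always two-sided.

## Allele-specific expression

SNP calling compares length-matched parental transcript pairs position by
position (1-based, fully closed coordinates); a position yields a SNP when
both bases are unambiguous A/C/G/T and differ. Positions involving N or
ambiguity codes are skipped and counted. Real de novo assemblies require a
pre-alignment into a common coordinate frame first; that step is outside
this package.

Allele-depth counting scores hybrid reads aligned against the parent-low
transcriptome for the parent-low base and reads aligned against the
parent-high transcriptome for the parent-high base — a read contributes to
a parent's depth only by matching that parent's base at the SNP. Covering
reads matching neither base are tallied as `depth_other` and excluded from
testing. A read overlapping several SNPs contributes once per SNP (no
haplotype vote); a read id contributes at most once per SNP per alignment
file. Only gapless, match-only alignments are accepted; unmapped, gapped
and secondary records are excluded with counts.

Per gene, depths are summed over SNPs and the mean informative depth per
SNP — (total_low + total_high)/n_snps, deliberately excluding
`depth_other` — must strictly exceed 10 (per sample, not pooled across
conditions). The per-gene test is the two-sided binomial exact test
(minimum-likelihood method: the p-value sums the probabilities of all
outcomes no more likely than the observed count) of total_high against
Binomial(n, 0.5), at alpha 0.05 without multiple-testing correction by
default; a `bh` flag applies Benjamini–Hochberg adjustment for users who
want FDR control across genes. Treating read–SNP observations as
independent ignores that overlapping reads at dense SNP clusters are
correlated; with the short (36 bp) reads simulated here the effect is
small, but on real data with long reads the test can be anticonservative.

One ambiguity of the two-alignment counting scheme is acknowledged rather
than resolved: a read that aligns to both parental transcriptomes is
scored in both files, once against each parent's base. The simulator makes
this explicit by emitting every read in both alignment sets; with
base-matching counting each read still increments at most one informative
depth.

## DE acceptance rule

Upstream per-gene p-values (from any pairwise DE model) are BH-adjusted
across the full candidate list; a gene is accepted when FPKM exceeds 1
(strict) in at least one of the two compared samples and the adjusted
p-value is below 0.05 (strict). Direction is the sign of fpkm_b − fpkm_a;
a retained gene with exactly tied FPKM cannot be oriented and is flagged
ambiguous and excluded, with a count. The DE model itself (dispersion
estimation, normalisation) is out of scope: p-values are consumed, not
produced, and the simulator supplies uniform p-values for null genes and
Beta(0.1, 4) p-values for signal genes so the rule is testable.

## Synthetic data generator

The generator is the package's validation instrument: it draws data from
exactly the structure the statistics assume, so recovery failures indicate
implementation errors, not model mismatch.

* **Expression.** Parental means are i.i.d. log-normal per gene-cell
  (defaults: log-mean 1.5, log-sd 1.0 natural-log FPKM, median ≈ 4.5 FPKM
  with a realistic dynamic range). Each gene has one true d/a value `t`
  applied in all four cells: exactly 0 (additive) or 1 (dominant), or
  uniform on the open bin interval, with the outside bins truncated to
  (−2,−1) and (1,2) — unbounded supports add nothing to recovery tests.
  The default inheritance mix (20/20/5/25/5/25% for outside-low,
  skewed-low, additive, skewed-high, dominant-high, outside-high) is
  skewed toward the reference parent, the pattern the bias test is meant
  to detect. Mode labels are assigned by deterministic largest-remainder
  allocation so the realised composition equals the configured mix.
  Hybrid means that would be placed below zero (possible for wide parental
  draws in the outside bins) trigger fresh parental draws for that
  gene-cell, keeping `t` and hence truth recovery intact. Observation
  noise is multiplicative log-normal with mean 1 and configurable CV
  (default 0.1), applied independently to all three genotypes.
* **Transcripts and SNPs.** One transcript pair per gene (default 300 bp),
  identical except at Poisson(3) planted SNP positions. The emitted SNP
  table is the planted truth by construction.
* **Reads.** Per SNP, Poisson(30) reads of fixed length 36 (mirroring
  short-read fragments) covering the SNP, copied from the parent-high
  haplotype with the gene's imbalance probability (defaults: 70% of genes
  balanced at 0.5, 20% biased 0.8 toward the high allele, 10% biased 0.2),
  else from the parent-low haplotype — so multi-SNP windows are phase
  consistent. Each read appears in both SAM outputs at its true position;
  its id encodes the true haplotype. A single NumPy generator seeded from
  the config drives everything; equal configs give byte-identical outputs.

What the generator does **not** emulate: sequencing error, base-quality
structure, mapping bias between the two parental references, fragment-length
and paired-end structure, overdispersion of expression beyond log-normal
noise, and correlated reads at SNP clusters beyond the shared-window effect.
Passing recovery tests therefore demonstrates correctness of the
computations under the stated model, not robustness to real-data artefacts
such as reference bias — the main known hazard for ASE estimates.

## Problem sizes and calibration checks

The validation suite uses sizes chosen to make Monte-Carlo error small
relative to the effects checked: exhaustive binomial-oracle equivalence for
all n ≤ 200; signed-rank enumeration for n ≤ 10; 500-gene noise-free
bundles for end-to-end recovery; 10,000 genes at depth 30 for the type-I
calibration of the imbalance test; 1,000 replicates of 2,000 p-values for
the BH false-discovery calibration. Stochastic calibration checks compare
against the nominal level within three Monte-Carlo standard errors; under
an all-null BH simulation the expected false-discovery rate equals the
nominal 0.05 exactly, so individual runs land on either side of it.

## Pipeline conventions

All thresholds (FPKM gate 1.0, mean SNP depth 10, imbalance alpha 0.05, DE
q 0.05) are configuration keys with those defaults, not constants. Every
stage reports records in, records out, and exclusions by reason, and the
pipeline enforces count conservation between them. Reports are JSON with
sorted keys and no timestamps, so identical configurations produce
byte-identical reports.
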