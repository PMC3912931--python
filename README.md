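# trioexpress

Analysis of gene expression inheritance and allele usage in an F1 hybrid
relative to its two inbred parents, from bulk RNA-seq expression tables and
SNP-level read counts. The package targets the classic crop-genetics trio
design — two inbreds crossed to make a hybrid, profiled across tissues and
treatments (here: leaf and root under sufficient versus limiting nitrogen) —
and answers two questions per gene:

1. **Inheritance mode.** Does the hybrid express the gene additively, like
   one parent, or outside the parental range?
2. **Allele-specific expression (ASE).** Within the hybrid, are the two
   parental alleles of the gene expressed equally?

It also applies the standard acceptance rule for differentially expressed
genes (expression gate plus FDR gate) to externally supplied per-gene
p-values, and ships a synthetic trio generator with known ground truth so
every step can be validated by parameter recovery.

## The statistics

**Dominance-to-additive ratio.** For a gene with hybrid expression $F_1$ and
parental expressions $P_1$ (the designated reference parent) and $P_2$, with
midparent $\mu = (P_1 + P_2)/2$:

$$d/a = \frac{F_1 - \mu}{P_1 - \mu}$$

$d/a = 0$ is additive inheritance, $+1$ complete dominance of the reference
parent, $-1$ dominance of the other parent, and $|d/a| > 1$ expression outside
the parental range. Genes are binned on the four open intervals
$(-\infty,-1)$, $(-1,0)$, $(0,1)$, $(1,\infty)$ (exact boundary values get
their own bins), and a one-sample Wilcoxon signed-rank test on all defined
$d/a$ values asks whether the transcriptome-wide distribution is biased
toward one parent. Genes enter the analysis when FPKM exceeds 1 in at least
one of the three genotypes (optionally restricted to a curated gene
whitelist such as the maize Filtered Gene Set).

**Allelic imbalance.** SNPs are called between length-matched parental
transcript pairs; hybrid reads aligned against each parental transcriptome
are counted at every SNP for the base they carry (a read counts toward a
parent's allele depth only if it matches that parent's base). Depths are
summed per gene, genes with mean informative depth per SNP strictly above 10
are kept, and each gene's allele totals are tested against a balanced 50:50
null with the two-sided binomial exact test at alpha 0.05.

**DE acceptance rule.** A gene is accepted as differentially expressed
between two samples when FPKM exceeds 1 in at least one of them and the
Benjamini–Hochberg adjusted p-value is below 0.05; accepted genes are split
into up- and down-regulated lists.

## Worked example

Run the full pipeline on a 200-gene synthetic trio (the bundled demo
configuration):

```bash
cat > demo.json <<'JSON'
{"simulation": {"n_genes": 200, "seed": 7}}
JSON
trioexpress run --config demo.json --out-dir demo_out
```

This writes the simulated inputs (expression TSV, parental FASTA pair, VCF
of planted SNPs, SAM alignments per condition), all per-stage result tables,
and `report.json`. With seed 7 the report contains, among others:

* `simulate`: 200 genes, 12 samples, 566 planted SNPs, ~17,000 hybrid reads
  per condition;
* `snps`: 566 SNPs called — exactly the planted table;
* `da` bias test in root tissue under sufficient N: W+ = 11719 over 199
  genes, p = 0.0297, direction `toward_high` — the simulated inheritance mix
  is deliberately skewed toward the reference parent, and the signed-rank
  test picks the skew up;
* `ase`: 182 of 200 genes testable; 72 genes with significant allelic
  imbalance under sufficient N and 63 under limiting N, 59 shared (56 with
  the same direction) — the generator plants 30% of genes with an 80:20 or
  20:80 allele ratio;
* `de`: 11 genes up- and 7 down-regulated out of 200 candidates at the
  default 10% signal fraction.

The library surface mirrors the pipeline stages; the one-liners:

```python
>>> from trioexpress import da_ratio, classify_da, binomial_exact_test
>>> da_ratio(8.0, 10.0, 6.0)      # hybrid at midparent of parents 10 and 6
0.0
>>> da_ratio(10.0, 10.0, 6.0)     # hybrid at the reference parent
1.0
>>> classify_da(0.5).value
'skewed_high'
>>> binomial_exact_test(7, 10)    # 7 of 10 reads from one allele
0.34375
```

## Layout

- `src/trioexpress/core_io.py` — data model; TSV/VCF/SAM/FASTA readers and writers
- `src/trioexpress/simulate.py` — synthetic trio generator with truth tables
- `src/trioexpress/dominance.py` — d/a ratio, inheritance bins, Wilcoxon bias test
- `src/trioexpress/ase.py` — SNP calling, allele-depth counting, binomial imbalance test
- `src/trioexpress/defilter.py` — BH adjustment and the DE acceptance rule
- `src/trioexpress/pipeline.py`, `cli.py` — end-to-end orchestration and the
  `trioexpress` command

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
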