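"""Data model and readers/writers for the formats the pipeline touches.

Conventions used throughout the package:

* Coordinates are **1-based and fully closed** on transcript sequences,
  matching SAM and VCF conventions.
* Transcripts are single-stranded references; no reverse-complement
  handling (the read simulator emits forward-strand reads only).
* Expression values are FPKM-like (non-negative, length/depth
  normalised); "expressed" means FPKM strictly greater than the
  threshold (default 1.0).

External formats:

* Expression: a TSV with a ``gene_id`` column plus one column per
  sample, and a companion metadata TSV with columns
  ``sample_id  genotype  tissue  condition``.
* SNP tables: a minimal VCF v4.2 dialect — CHROM is the transcript id,
  POS is 1-based, REF is the parent-low base, ALT the parent-high base,
  and INFO carries ``GENE=<gene_id>``.
* Read alignments: SAM (gapless, match-only alignments accepted).
* Transcripts: FASTA.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


class TrioValidationError(ValueError):
    """An input violates a documented invariant."""


class TrioParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class Genotype(str, Enum):
    PARENT_LOW = "parent_low"
    PARENT_HIGH = "parent_high"
    HYBRID = "hybrid"


class Tissue(str, Enum):
    LEAF = "leaf"
    ROOT = "root"


class Condition(str, Enum):
    SUFFICIENT_N = "sufficient_N"
    LIMITING_N = "limiting_N"


@dataclass(frozen=True)
class SnpRecord:
    """A single-base difference between the two parental transcripts.

    ``position`` is 1-based on the transcript. ``allele_low`` and
    ``allele_high`` are the parent-low and parent-high bases; they must
    be distinct unambiguous nucleotides.
    """

    transcript_id: str
    gene_id: str
    position: int
    allele_low: str
    allele_high: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise TrioValidationError(f"SNP position must be >= 1, got {self.position}")
        for allele in (self.allele_low, self.allele_high):
            if allele not in NUCLEOTIDES:
                raise TrioValidationError(f"allele {allele!r} is not one of A/C/G/T")
        if self.allele_low == self.allele_high:
            raise TrioValidationError(
                f"alleles must differ, got {self.allele_low}/{self.allele_high} "
                f"at {self.transcript_id}:{self.position}"
            )


@dataclass(frozen=True)
class AlignedRead:
    """A gapless read alignment; ``start`` is the 1-based leftmost base."""

    read_id: str
    transcript_id: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TrioValidationError(f"read {self.read_id} has empty sequence")
        if self.start < 1:
            raise TrioValidationError(f"read {self.read_id} start must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost aligned base."""
        return self.start + len(self.sequence) - 1

    def base_at(self, position: int) -> str | None:
        """Base aligned at 1-based transcript ``position``; None if not covered."""
        if self.start <= position <= self.end:
            return self.sequence[position - self.start]
        return None


@dataclass
class ExpressionTable:
    """Per-gene expression (FPKM) for the trio across samples.

    ``values`` is a genes x samples frame of non-negative floats;
    ``samples`` is indexed by sample_id with columns
    ``genotype``/``tissue``/``condition``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> None:
        if (self.values.to_numpy() < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise TrioValidationError(f"negative FPKM for gene {bad!r}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise TrioValidationError(
                f"samples without metadata: {sorted(missing)}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TrioValidationError(f"duplicate gene_id {dup!r}")
        for col in ("genotype", "tissue", "condition"):
            if col not in self.samples.columns:
                raise TrioValidationError(f"sample metadata lacks column {col!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_for(self, genotype: Genotype, tissue: Tissue, condition: Condition) -> str:
        """Sample id for a (genotype, tissue, condition) cell; errors if absent or ambiguous."""
        mask = (
            (self.samples["genotype"] == genotype.value)
            & (self.samples["tissue"] == tissue.value)
            & (self.samples["condition"] == condition.value)
        )
        hits = self.samples.index[mask]
        if len(hits) == 0:
            raise TrioValidationError(
                f"no sample for genotype={genotype.value}, tissue={tissue.value}, "
                f"condition={condition.value}"
            )
        if len(hits) > 1:
            raise TrioValidationError(
                f"multiple samples for genotype={genotype.value}, "
                f"tissue={tissue.value}, condition={condition.value}: {list(hits)}"
            )
        return hits[0]

    def fpkm(self, gene_id: str, sample_id: str) -> float:
        return float(self.values.at[gene_id, sample_id])


@dataclass(frozen=True)
class GeneSet:
    """A whitelist of gene ids, e.g. an analog of the maize Filtered Gene Set."""

    ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise TrioValidationError("GeneSet must be non-empty when supplied")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)


def is_expressed(fpkm: float, threshold: float = 1.0) -> bool:
    """True iff ``fpkm`` is strictly greater than ``threshold``.

    The strict inequality matters: a gene at exactly the threshold is
    not called expressed.
    """
    if fpkm < 0:
        raise TrioValidationError(f"FPKM must be non-negative, got {fpkm}")
    return fpkm > threshold


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path: str | Path, metadata_path: str | Path) -> ExpressionTable:
    """Read an expression TSV plus its sample-metadata TSV.

    The expression file has a header row ``gene_id`` followed by one
    column per sample; all cells must parse as non-negative reals.
    Malformed cells raise :class:`TrioParseError` naming the line.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    if raw.columns[0] != "gene_id":
        raise TrioParseError(f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}")
    raw = raw.set_index("gene_id")
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        row_idx = values.isna().any(axis=1).to_numpy().nonzero()[0][0]
        # +2: header is line 1, data starts at line 2
        raise TrioParseError(f"{path}: unparseable numeric cell at line {row_idx + 2}")
    samples = pd.read_csv(metadata_path, sep="\t", dtype=str, comment="#").set_index("sample_id")
    table = ExpressionTable(values=values.astype(float), samples=samples)
    table.validate()
    return table


def write_expression_table(
    table: ExpressionTable, path: str | Path, metadata_path: str | Path
) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")
    table.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_gene_set(path: str | Path) -> GeneSet:
    """One gene id per line; '#' lines are comments."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return GeneSet(ids=frozenset(ids))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.ids)) + "\n")


# ---------------------------------------------------------------------------
# SNP tables (minimal VCF dialect)


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read SNPs from the minimal VCF dialect.

    Indel and multi-allelic lines are skipped with a logged warning;
    REF == ALT or a missing ``GENE`` INFO tag raise
    :class:`TrioValidationError`.
    """
    records: list[SnpRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                logger.warning(
                    "skipping non-SNP line %s:%d (REF=%s ALT=%s)",
                    rec.chrom, rec.pos, rec.ref, ",".join(alts),
                )
                n_skipped += 1
                continue
            if "GENE" not in rec.info:
                raise TrioValidationError(
                    f"{path}: line for {rec.chrom}:{rec.pos} lacks GENE INFO tag"
                )
            gene = rec.info["GENE"]
            if isinstance(gene, tuple):
                gene = gene[0]
            records.append(
                SnpRecord(
                    transcript_id=rec.chrom,
                    gene_id=str(gene),
                    position=rec.pos,
                    allele_low=rec.ref,
                    allele_high=alts[0],
                )
            )
    if n_skipped:
        logger.info("read_snp_table: skipped %d non-SNP lines", n_skipped)
    return records


def write_snp_table(
    snps: Iterable[SnpRecord],
    path: str | Path,
    transcript_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNPs as minimal VCF v4.2; contig lengths are optional."""
    snps = list(snps)
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">']
    seen: dict[str, int] = {}
    for snp in snps:
        if snp.transcript_id not in seen:
            if transcript_lengths and snp.transcript_id in transcript_lengths:
                seen[snp.transcript_id] = transcript_lengths[snp.transcript_id]
            else:
                seen[snp.transcript_id] = 0
    for tid, length in seen.items():
        if length:
            lines.append(f"##contig=<ID={tid},length={length}>")
        else:
            lines.append(f"##contig=<ID={tid}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for snp in snps:
        lines.append(
            f"{snp.transcript_id}\t{snp.position}\t.\t{snp.allele_low}\t"
            f"{snp.allele_high}\t.\t.\tGENE={snp.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments (SAM)


def read_alignments(path: str | Path) -> tuple[list[AlignedRead], Counter]:
    """Read gapless match-only alignments from a SAM file.

    Returns ``(reads, excluded)`` where ``excluded`` counts records
    rejected by reason (``unmapped``, ``gapped``, ``secondary``).
    Only alignments whose CIGAR is a single match run (M/=/X) spanning
    the whole read are accepted.
    """
    reads: list[AlignedRead] = []
    excluded: Counter = Counter()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                excluded["unmapped"] += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                excluded["secondary"] += 1
                continue
            cig = rec.cigartuples or []
            if len(cig) != 1 or cig[0][0] not in (0, 7, 8):
                excluded["gapped"] += 1
                continue
            reads.append(
                AlignedRead(
                    read_id=rec.query_name,
                    transcript_id=rec.reference_name,
                    start=rec.reference_start + 1,
                    sequence=rec.query_sequence,
                )
            )
    if excluded:
        logger.info("read_alignments(%s): excluded %s", path, dict(excluded))
    return reads, excluded


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str | Path,
    transcript_lengths: Mapping[str, int],
) -> None:
    """Write reads as SAM with @SQ lines from ``transcript_lengths``."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": tid, "LN": length}
            for tid, length in sorted(transcript_lengths.items())
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        tid_index = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        for read in reads:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.sequence
            rec.flag = 0
            rec.reference_id = tid_index[read.transcript_id]
            rec.reference_start = read.start - 1
            rec.mapping_quality = 60
            rec.cigartuples = [(0, len(read.sequence))]
            sam.write(rec)


# ---------------------------------------------------------------------------
# Transcripts (FASTA)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
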