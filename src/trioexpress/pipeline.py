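"""End-to-end orchestration: simulate -> d/a -> SNPs -> ASE -> DE filter.

A single JSON config drives a run. In ``simulation`` mode the synthetic
generator produces every input; in ``inputs`` mode the config points at
real files (expression TSV + metadata, parental FASTA pair or VCF, SAM
alignments). All analysis thresholds (FPKM gate 1.0, mean SNP depth 10,
ASE alpha 0.05, DE q 0.05) are config keys defaulting to the study's
values. The run emits every intermediate file plus a machine-readable
report whose per-stage counts are checked for conservation: records in
equal records out plus documented exclusions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import ase as ase_mod
from . import core_io, defilter, dominance, simulate

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

DEFAULT_THRESHOLDS = {
    "fpkm_threshold": 1.0,
    "min_mean_depth": 10.0,
    "ase_alpha": 0.05,
    "de_q_threshold": 0.05,
}


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the offence."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _check_conservation(stage: str, n_in: int, n_out: int, exclusions: dict) -> None:
    n_excluded = sum(exclusions.values())
    if n_in != n_out + n_excluded:
        raise PipelineStageError(
            stage,
            f"count conservation violated: {n_in} in, {n_out} out, "
            f"{n_excluded} excluded ({exclusions})",
        )


def _da_stage(expr, gene_set, thresholds, report_stages):
    results, exclusions = dominance.da_table(
        expr, gene_set=gene_set, fpkm_threshold=thresholds["fpkm_threshold"]
    )
    n_cells_in = len(expr.gene_ids) * 4
    undefined = exclusions.pop("undefined_da", 0)
    _check_conservation("da", n_cells_in, len(results), exclusions)
    exclusions["undefined_da"] = undefined  # kept in results, reported separately
    summary = dominance.summarize_bins(results)
    bias = {}
    for (tissue, condition), _ in summary.iterrows():
        cell_das = [
            r.da
            for r in results
            if r.tissue.value == tissue and r.condition.value == condition
            and r.da is not None
        ]
        if cell_das:
            test = dominance.wilcoxon_bias_test(cell_das)
            bias[f"{tissue}/{condition}"] = {
                "n_genes": test.n_genes,
                "statistic": test.statistic,
                "p_value": test.p_value,
                "direction": test.direction.value,
            }
    report_stages["da"] = {
        "gene_cells_in": n_cells_in,
        "results": len(results),
        "excluded": dict(exclusions),
        "bin_summary": {
            f"{t}/{c}": row.to_dict() for (t, c), row in summary.iterrows()
        },
        "bias_test": bias,
    }
    return results, summary


def _ase_stage(reads_low, reads_high, snps, thresholds, label, report_stages):
    depths = ase_mod.count_allele_depths(reads_low, reads_high, snps)
    pre, filter_excl = ase_mod.aggregate_and_filter(
        depths, min_mean_depth=thresholds["min_mean_depth"]
    )
    n_genes_in = len({d.snp.gene_id for d in depths})
    _check_conservation(f"ase[{label}]", n_genes_in, len(pre), filter_excl)
    tested, test_excl = ase_mod.test_allelic_imbalance(
        pre, alpha=thresholds["ase_alpha"]
    )
    _check_conservation(f"ase[{label}]", len(pre), len(tested), test_excl)
    n_sig = sum(1 for r in tested if r.significant)
    report_stages.setdefault("ase", {}).setdefault("per_condition", {})[label] = {
        "n_snps": len(snps),
        "genes_with_snps": n_genes_in,
        "excluded_depth_filter": dict(filter_excl),
        "excluded_no_reads": dict(test_excl),
        "tested": len(tested),
        "significant": n_sig,
        "high_higher": sum(
            1 for r in tested if r.direction == ase_mod.AseDirection.HIGH_HIGHER
        ),
        "low_higher": sum(
            1 for r in tested if r.direction == ase_mod.AseDirection.LOW_HIGHER
        ),
    }
    return tested


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    ``config`` is a dict or a path to a JSON file with keys
    ``simulation`` (SimulationConfig fields) or ``inputs`` (file paths),
    plus optional ``thresholds`` and ``de`` sections.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config,
        "thresholds": thresholds,
        "stages": {},
    }
    stages = report["stages"]

    if "simulation" in config:
        sim_cfg = simulate.SimulationConfig(**config["simulation"])
        report["seed"] = sim_cfg.seed
        rng = np.random.default_rng(sim_cfg.seed)
        try:
            expr, truth = simulate.simulate_trio_expression(sim_cfg, rng=rng)
            low_tx, high_tx, snps = simulate.simulate_parental_transcripts(
                sim_cfg, rng=rng
            )
            ase_truth = simulate.assign_ase_classes(sim_cfg)
            reads_by_condition = {}
            for condition in core_io.Condition:
                r_low, r_high, _ = simulate.simulate_hybrid_reads(
                    low_tx, high_tx, snps, sim_cfg, rng=rng, ase_truth=ase_truth
                )
                reads_by_condition[condition.value] = (r_low, r_high)
        except core_io.TrioValidationError as exc:
            raise PipelineStageError("simulate", str(exc)) from exc
        gene_set = None
        tx_lengths = {tid: len(seq) for tid, seq in low_tx.items()}
        core_io.write_expression_table(
            expr, out_dir / "expression.tsv", out_dir / "samples.tsv"
        )
        core_io.write_fasta(low_tx, out_dir / "parent_low.fasta")
        core_io.write_fasta(high_tx, out_dir / "parent_high.fasta")
        core_io.write_snp_table(snps, out_dir / "snps.vcf", tx_lengths)
        for condition, (r_low, r_high) in reads_by_condition.items():
            core_io.write_alignments(
                r_low, out_dir / f"reads_vs_low_{condition}.sam", tx_lengths
            )
            core_io.write_alignments(
                r_high, out_dir / f"reads_vs_high_{condition}.sam", tx_lengths
            )
        truth.genes.join(ase_truth).to_csv(out_dir / "truth_genes.tsv", sep="\t")
        truth.cell_means.to_csv(out_dir / "truth_cell_means.tsv", sep="\t", index=False)
        stages["simulate"] = {
            "n_genes": sim_cfg.n_genes,
            "n_samples": len(expr.samples),
            "n_planted_snps": len(snps),
            "n_reads_per_condition": {
                c: len(r[0]) for c, r in reads_by_condition.items()
            },
        }
    elif "inputs" in config:
        inputs = config["inputs"]
        report["seed"] = config.get("seed", 0)
        try:
            expr = core_io.read_expression_table(
                inputs["expression"], inputs["metadata"]
            )
        except (KeyError, OSError, core_io.TrioParseError) as exc:
            raise PipelineStageError("da", f"expression inputs unreadable: {exc}") from exc
        gene_set = (
            core_io.read_gene_set(inputs["gene_set"]) if "gene_set" in inputs else None
        )
        if "fasta_low" in inputs and "fasta_high" in inputs:
            low_tx = core_io.read_fasta(inputs["fasta_low"])
            high_tx = core_io.read_fasta(inputs["fasta_high"])
            snps = None
        elif "vcf" in inputs:
            low_tx = high_tx = None
            snps = core_io.read_snp_table(inputs["vcf"])
        else:
            raise PipelineStageError(
                "snps", "inputs must provide fasta_low/fasta_high or vcf"
            )
        reads_by_condition = {}
        for condition in core_io.Condition:
            key_low = f"sam_vs_low_{condition.value}"
            key_high = f"sam_vs_high_{condition.value}"
            if key_low in inputs or key_high in inputs:
                if key_low not in inputs or key_high not in inputs:
                    raise PipelineStageError(
                        "ase", f"both {key_low} and {key_high} are required"
                    )
                for key in (key_low, key_high):
                    if not Path(inputs[key]).exists():
                        raise PipelineStageError(
                            "ase", f"SAM file missing: {inputs[key]}"
                        )
                r_low, _ = core_io.read_alignments(inputs[key_low])
                r_high, _ = core_io.read_alignments(inputs[key_high])
                reads_by_condition[condition.value] = (r_low, r_high)
    else:
        raise PipelineStageError("config", "need a 'simulation' or 'inputs' section")

    # --- d/a analysis ------------------------------------------------------
    try:
        da_results, da_summary = _da_stage(expr, gene_set, thresholds, stages)
    except core_io.TrioValidationError as exc:
        raise PipelineStageError("da", str(exc)) from exc
    dominance.results_to_frame(da_results).to_csv(
        out_dir / "da_results.tsv", sep="\t", index=False
    )
    da_summary.to_csv(out_dir / "da_summary.tsv", sep="\t")

    # --- SNP calling -------------------------------------------------------
    if low_tx is not None and high_tx is not None:
        gene_map = {tid: tid.rsplit("_t", 1)[0] for tid in low_tx}
        try:
            called, n_ambig = ase_mod.call_snps(low_tx, high_tx, gene_map=gene_map)
        except core_io.TrioValidationError as exc:
            raise PipelineStageError("snps", str(exc)) from exc
        stages["snps"] = {"n_called": len(called), "n_skipped_ambiguous": n_ambig}
        if snps is None:
            snps = called
        tx_lengths = {tid: len(seq) for tid, seq in low_tx.items()}
        core_io.write_snp_table(called, out_dir / "snps_called.vcf", tx_lengths)
    elif snps is not None:
        stages["snps"] = {"n_from_vcf": len(snps)}

    # --- allele-specific expression ---------------------------------------
    tested_by_condition = {}
    for condition, (r_low, r_high) in reads_by_condition.items():
        tested = _ase_stage(r_low, r_high, snps, thresholds, condition, stages)
        tested_by_condition[condition] = tested
        ase_mod.ase_results_to_frame(tested).to_csv(
            out_dir / f"ase_{condition}.tsv", sep="\t", index=False
        )
    if len(tested_by_condition) == 2:
        a, b = (tested_by_condition[c.value] for c in core_io.Condition)
        overlap = ase_mod.compare_conditions(a, b)
        stages["ase"]["overlap_sufficient_vs_limiting"] = overlap

    # --- differential-expression filter ------------------------------------
    de_cfg = config.get("de", {})
    if "simulation" in config or "de_table" in config.get("inputs", {}):
        if "simulation" in config:
            pvals = simulate.simulate_de_pvalues(
                n_genes=sim_cfg.n_genes,
                signal_fraction=de_cfg.get("signal_fraction", 0.1),
                seed=sim_cfg.seed + 1,
            )
            s_a = expr.sample_for(
                core_io.Genotype.HYBRID, core_io.Tissue.LEAF,
                core_io.Condition.SUFFICIENT_N,
            )
            s_b = expr.sample_for(
                core_io.Genotype.HYBRID, core_io.Tissue.LEAF,
                core_io.Condition.LIMITING_N,
            )
            candidates = [
                defilter.DECandidate(
                    gene_id=row.gene_id,
                    fpkm_a=expr.fpkm(row.gene_id, s_a),
                    fpkm_b=expr.fpkm(row.gene_id, s_b),
                    p_value=row.p_value,
                )
                for row in pvals.itertuples()
            ]
        else:
            import pandas as pd

            de_in = pd.read_csv(config["inputs"]["de_table"], sep="\t")
            candidates = [
                defilter.DECandidate(
                    gene_id=str(r.gene_id), fpkm_a=r.fpkm_a, fpkm_b=r.fpkm_b,
                    p_value=r.p_value,
                )
                for r in de_in.itertuples()
            ]
        de_result = defilter.de_filter(
            candidates,
            fpkm_threshold=thresholds["fpkm_threshold"],
            q_threshold=thresholds["de_q_threshold"],
        )
        de_result.table.to_csv(out_dir / "de_table.tsv", sep="\t", index=False)
        stages["de"] = {
            "candidates": len(candidates),
            "up": len(de_result.up),
            "down": len(de_result.down),
            "ambiguous": de_result.n_ambiguous,
            "not_retained": len(candidates)
            - len(de_result.up) - len(de_result.down) - de_result.n_ambiguous,
        }

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (out_dir / "report.json").write_text(report_json + "\n")
    (out_dir / "report.txt").write_text(_render_text_report(report))
    return report


def _render_text_report(report: dict) -> str:
    lines = [f"trioexpress run report (schema {report['schema_version']})", ""]
    for stage, payload in report["stages"].items():
        lines.append(f"[{stage}]")
        lines.append(json.dumps(payload, indent=2, sort_keys=True))
        lines.append("")
    return "\n".join(lines)
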