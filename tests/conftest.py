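import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from trioexpress.simulate import (
    SimulationConfig,
    assign_ase_classes,
    simulate_hybrid_reads,
    simulate_parental_transcripts,
    simulate_trio_expression,
)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """A small noise-free simulated trio: expression, transcripts, SNPs, reads."""
    cfg = SimulationConfig(n_genes=60, noise_cv=0.0, seed=11)
    rng = np.random.default_rng(cfg.seed)
    expr, truth = simulate_trio_expression(cfg, rng=rng)
    low_tx, high_tx, snps = simulate_parental_transcripts(cfg, rng=rng)
    reads_low, reads_high, ase_truth = simulate_hybrid_reads(
        low_tx, high_tx, snps, cfg, rng=rng
    )
    return {
        "config": cfg,
        "expression": expr,
        "truth": truth,
        "low_tx": low_tx,
        "high_tx": high_tx,
        "snps": snps,
        "reads_low": reads_low,
        "reads_high": reads_high,
        "ase_truth": ase_truth,
    }
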