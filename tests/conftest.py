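import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from slamkinetics.synthetic import SlamSimParams, simulate_cds, simulate_slamseq


@pytest.fixture(scope="session")
def slam_recovery_run():
    """A 2,000-gene chase simulation with fitted half-lives (shared: slow)."""
    from slamkinetics.halflife import apply_qc, fit_halflives

    params = SlamSimParams(n_genes=2000, coverage_per_timepoint=1000.0, seed=42)
    counts, truth = simulate_slamseq(params)
    fits = apply_qc(fit_halflives(counts))
    return params, counts, truth, fits


@pytest.fixture(scope="session")
def coupled_cds_run():
    """2,000 genes with codon usage fully coupled to lognormal half-lives."""
    rng = np.random.default_rng(7)
    genes = [f"g{i:05d}" for i in range(2000)]
    half_lives = pd.Series(4.0 * np.exp(rng.normal(0, 0.6, 2000)), index=genes)
    sequences, codon_truth = simulate_cds(
        half_lives, n_planted_stab=3, n_planted_destab=3,
        cds_length_codons=300, coupling_strength=1.0, seed=7,
    )
    return half_lives, sequences, codon_truth
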