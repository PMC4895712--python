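"""Shared fixtures: simulated panels at several scales.

Session scope keeps the expensive end-to-end simulation to a single run that
many tests share read-only.
"""

import time

import pytest

from panelvar import SimulationConfig, simulate_panel
from panelvar.pipeline import analyze_panel
from panelvar.simulate import generate_reference


@pytest.fixture(scope="session")
def e2e():
    """Full-scale panel (default conditions), analyzed, with wall time."""
    config = SimulationConfig(seed=20240)
    t0 = time.perf_counter()
    sim = simulate_panel(config)
    result = analyze_panel(sim)
    elapsed = time.perf_counter() - t0
    return config, sim, result, elapsed


@pytest.fixture(scope="session")
def small_sim():
    """Compact panel for IO / per-module tests."""
    config = SimulationConfig(
        seed=5,
        n_samples=3,
        chromosome_length=150_000,
        n_genes=8,
        gene_length_range=(1200, 1800),
        snp_rate=5e-4,
        indel_rate=1e-4,
        n_line_specific=4,
        n_gene_deletions=1,
        n_gene_duplications=1,
        n_sv_per_type=1,
        n_lowqual_noise=5,
        n_close_pairs=2,
        n_noise_pairs=10,
    )
    return simulate_panel(config)


@pytest.fixture(scope="session")
def genome20():
    """Reference with 20 genes on both strands (for annotation tests)."""
    config = SimulationConfig(
        seed=11, n_chromosomes=2, chromosome_length=300_000, n_genes=20,
        gene_length_range=(1200, 2400),
    )
    return generate_reference(config)
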