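"""Shared fixtures: scaled-down synthetic datasets for unit tests and a
study-scale cohort (reused across recovery tests) so the expensive
simulation and kinetic fits run once per session."""

from __future__ import annotations

import pytest

from cycledecay.kinetics import fit_decay_table
from cycledecay.qc import compute_size_factors
from cycledecay.synthetic import (
    G2M_NOMINAL_TIME,
    SimulationConfig,
    simulate_counts,
    simulate_facs_snapshot,
    simulate_fucci_traces,
    simulate_ground_truth,
)


@pytest.fixture(scope="module")
def small_sim() -> SimulationConfig:
    """Small but fully featured study: 3 plates, spike-ins, early-S cells.

    Expression raised so that genuine cells stay inside the UMI bounds at
    this reduced panel size; the high-UMI spike-in capture is raised for
    the same reason.
    """
    return SimulationConfig(
        n_g2m_cells=40,
        n_g1_cells=260,
        n_genes_immediate=12,
        n_genes_delayed=12,
        n_genes_stable=120,
        m0_median_decaying=40.0,
        m0_median_stable=100.0,
        m0_sigma_stable=0.4,
        n_traces=20,
        n_early_s_cells=30,
        spikein_high_capture=25.0,
        rng_seed=123,
    )


@pytest.fixture(scope="module")
def small_truth(small_sim):
    return simulate_ground_truth(small_sim)


@pytest.fixture(scope="module")
def small_traces(small_sim, small_truth):
    traces, _ = simulate_fucci_traces(small_sim, small_truth)
    return traces


@pytest.fixture(scope="module")
def small_facs(small_sim, small_truth):
    return simulate_facs_snapshot(small_sim, small_truth)


@pytest.fixture(scope="module")
def small_counts(small_sim, small_truth):
    return simulate_counts(small_sim, small_truth)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Study-scale cohort with known times: 100 decaying genes among a
    stable background, 86 G2/M + 750 G1 cells, NB dispersion 0.3, capture
    CV 20%."""
    sim = SimulationConfig(
        n_g2m_cells=86,
        n_g1_cells=750,
        n_genes_immediate=50,
        n_genes_delayed=50,
        n_genes_stable=3765,
        qc_spikeins=False,
        n_early_s_cells=0,
        rng_seed=0,
    )
    truth = simulate_ground_truth(sim)
    matrix = simulate_counts(sim, truth)
    matrix.size_factors = compute_size_factors(matrix)
    cells = truth.cells[truth.cells["qc_class"] != "snapshot_only"]
    times = cells["cell_cycle_time"].to_numpy().copy()
    times[(cells["phase"] == "G2M").to_numpy()] = G2M_NOMINAL_TIME
    decaying = (truth.genes["wave_group"] != "stable").to_numpy()
    return {
        "config": sim,
        "truth": truth,
        "matrix": matrix,
        "times": times,
        "decaying_mask": decaying,
        "decaying_expr": matrix.normalized[decaying],
        "decaying_genes": truth.genes[decaying].reset_index(drop=True),
    }


@pytest.fixture(scope="session")
def recovery_fits(recovery_cohort):
    """Two-phase decay fits for the 100 planted decaying genes."""
    c = recovery_cohort
    fits = fit_decay_table(c["times"], c["decaying_expr"],
                           c["decaying_genes"]["gene_id"].to_numpy())
    merged = fits.merge(c["decaying_genes"], on="gene_id",
                        suffixes=("", "_true"))
    assert len(merged) == len(fits)
    return merged
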