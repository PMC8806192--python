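"""Seeded synthetic data for the mitosis-to-G1 (M-G1) decay pipeline.

Generates the three kinds of input the pipeline consumes — FUCCI reporter
time traces from live imaging, a FACS sort snapshot, and a genes x cells UMI
count matrix — together with the ground truth used to generate them, so that
every downstream stage (calibration, QC, differential expression, wave
detection, kinetic fitting) can be tested against known parameters.

The generative model mirrors the study design this pipeline targets:

* ~90 microscopy traces of the FUCCI-G1 reporter aligned at the
  metaphase-to-anaphase transition, with per-cell amplitude heterogeneity
  and 31% G1->G2 channel crosstalk;
* three 384-well plates of FACS-sorted cells: G2/M cells, G1 cells spanning
  0-540 min of G1 phase, plus early-S cells that anchor the normalization;
* negative-binomial UMI counts whose per-gene means follow a two-phase decay
  model (constant at m0 until t_onset, then first-order relaxation towards
  mu/gamma), with two onset-time modes (mitotic exit ~10 min and early G1
  ~80 min), log-normal per-cell capture efficiency, and optional QC spike-in
  cells with out-of-bounds UMI totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import model_eval

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "fucci_accumulation",
    "simulate_ground_truth",
    "simulate_fucci_traces",
    "simulate_facs_snapshot",
    "simulate_counts",
    "export_truth",
    "load_truth",
]

#: nominal pre-metaphase time at which G2/M cells are evaluated (minutes)
G2M_NOMINAL_TIME = -10.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic M-G1 study.

    Defaults emulate the study conditions: 3 plates, 86 G2/M + 755 G1 cells
    spanning 0-540 min of G1, a ~3985-gene panel of which 220 decay in two
    onset waves, median half-life 60 min, 31% channel crosstalk.
    """

    # cells and plates
    n_plates: int = 3
    n_g2m_cells: int = 86
    n_g1_cells: int = 755
    g1_time_range: tuple[float, float] = (0.0, 540.0)

    # gene panel
    n_genes_immediate: int = 110
    n_genes_delayed: int = 110
    n_genes_stable: int = 3765
    onset_mode_immediate: float = 10.0
    onset_sd_immediate: float = 5.0
    onset_mode_delayed: float = 80.0
    onset_sd_delayed: float = 10.0
    half_life_median: float = 60.0  # minutes, lognormal median of decaying genes
    half_life_sigma: float = 0.25  # lognormal sigma (log scale)
    ss_fraction_range: tuple[float, float] = (0.03, 0.15)  # (mu/gamma)/m0
    m0_median_decaying: float = 20.0
    m0_sigma_decaying: float = 0.7
    m0_median_stable: float = 5.0
    m0_sigma_stable: float = 1.0

    # count noise model
    nb_dispersion: float = 0.3  # var = mean + dispersion * mean^2
    capture_cv: float = 0.2  # CV of log-normal per-cell capture efficiency

    # FUCCI traces (microscopy)
    crosstalk_fraction: float = 0.31
    trace_amplitude_cv: float = 0.2
    measurement_noise_sd: float = 0.02
    n_traces: int = 90
    trace_t_step: float = 5.0
    trace_t_end: float = 600.0
    g1_end: float = 540.0  # minutes: FUCCI-G2 starts rising here
    # saturation time scale of the G1 reporter: large relative to the G1
    # span so the rise is near-linear with mild concavity, matching the
    # reported monotonic increase through 6-8 hr and timing that stays
    # accurate over the first ~5 hr of G1
    fucci_tau: float = 720.0
    g2_rise_rate: float = 0.5 / 60.0  # G2 channel slope after g1_end

    # FACS snapshot
    n_early_s_cells: int = 50
    facs_gain: float = 2.0  # FACS intensity units per microscopy unit
    facs_noise_sd: float = 0.01  # relative to facs_gain

    # QC spike-ins (cells with out-of-bounds UMI totals)
    qc_spikeins: bool = True
    n_spikein_low: int = 20
    n_spikein_high: int = 10
    spikein_low_capture: float = 0.05
    spikein_high_capture: float = 4.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_plates, self.n_g2m_cells, self.n_g1_cells,
            self.n_genes_immediate, self.n_genes_delayed, self.n_genes_stable,
            self.n_traces, self.n_early_s_cells,
            self.n_spikein_low, self.n_spikein_high,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        lo, hi = self.g1_time_range
        if not (0.0 <= lo < hi <= 540.0):
            raise ValueError("g1_time_range must be within [0, 540] with lo < hi")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.crosstalk_fraction <= 1.0:
            raise ValueError("crosstalk_fraction must be in [0, 1]")
        if self.trace_t_step <= 0:
            raise ValueError("trace time step must be positive")
        if self.measurement_noise_sd < 0 or self.facs_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.n_genes_immediate + self.n_genes_delayed + self.n_genes_stable


@dataclass
class GroundTruth:
    """True generative parameters behind a synthetic dataset.

    ``genes`` columns: gene_id, m0, mu, gamma, t_onset, wave_group
    ({immediate, delayed, stable}).  ``cells`` columns: cell_id, plate_id,
    phase ({G2M, G1}), sort_gate ({G2M, G1, earlyS}), cell_cycle_time
    (minutes; NaN for non-G1), capture_efficiency, qc_class
    ({ok, low_umi, high_umi, snapshot_only}).
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    config: SimulationConfig | None = None


def fucci_accumulation(t, tau: float = 240.0):
    """Monotone saturating FUCCI-G1 accumulation curve, f(0)=0, f(inf)=1."""
    return 1.0 - np.exp(-np.asarray(t, dtype=float) / tau)


def _child_rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per component
    return np.random.default_rng([int(config.rng_seed) % (2**31), stream])


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw per-gene kinetic parameters and per-cell states.

    Decaying genes satisfy mu/gamma < m0 (they relax to a lower steady
    state); onset times are drawn around the two modes and clipped into
    [0, 370], the grid the downstream fit searches.
    """
    rng = _child_rng(config, 0)

    rows = []
    for group, n, mode, sd in (
        ("immediate", config.n_genes_immediate,
         config.onset_mode_immediate, config.onset_sd_immediate),
        ("delayed", config.n_genes_delayed,
         config.onset_mode_delayed, config.onset_sd_delayed),
    ):
        if n == 0:
            continue
        t_onset = np.clip(rng.normal(mode, sd, n), 0.0, 370.0)
        half_life = config.half_life_median * np.exp(
            rng.normal(0.0, config.half_life_sigma, n))
        gamma = np.log(2.0) / half_life
        m0 = config.m0_median_decaying * np.exp(
            rng.normal(0.0, config.m0_sigma_decaying, n))
        ss_frac = rng.uniform(*config.ss_fraction_range, n)
        mu = ss_frac * m0 * gamma
        for i in range(n):
            rows.append((group, m0[i], mu[i], gamma[i], t_onset[i]))
    for i in range(config.n_genes_stable):
        m0 = config.m0_median_stable * np.exp(
            rng.normal(0.0, config.m0_sigma_stable))
        # stable genes: constant mean; encode as gamma=0 sentinel, no onset
        rows.append(("stable", m0, np.nan, 0.0, np.nan))

    genes = pd.DataFrame(rows, columns=["wave_group", "m0", "mu", "gamma", "t_onset"])
    genes.insert(0, "gene_id", [f"gene_{i:05d}" for i in range(len(genes))])

    # cells: G2/M, G1 (uniform ages), optional QC spike-ins, early-S (snapshot only)
    cell_rows = []
    lo, hi = config.g1_time_range
    for i in range(config.n_g2m_cells):
        cell_rows.append((f"g2m_{i:04d}", "G2M", "G2M", np.nan, "ok"))
    g1_times = rng.uniform(lo, hi, config.n_g1_cells)
    for i in range(config.n_g1_cells):
        cell_rows.append((f"g1_{i:04d}", "G1", "G1", g1_times[i], "ok"))
    if config.qc_spikeins:
        low_t = rng.uniform(lo, hi, config.n_spikein_low)
        for i in range(config.n_spikein_low):
            cell_rows.append((f"spikelow_{i:03d}", "G1", "G1", low_t[i], "low_umi"))
        high_t = rng.uniform(lo, hi, config.n_spikein_high)
        for i in range(config.n_spikein_high):
            cell_rows.append((f"spikehigh_{i:03d}", "G1", "G1", high_t[i], "high_umi"))
    for i in range(config.n_early_s_cells):
        cell_rows.append((f"earlys_{i:03d}", "G1", "earlyS", np.nan, "snapshot_only"))

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "phase", "sort_gate", "cell_cycle_time", "qc_class"])
    cells["plate_id"] = [
        f"plate_{i % config.n_plates}" for i in range(len(cells))]

    capture = np.exp(rng.normal(0.0, _lognorm_sigma(config.capture_cv), len(cells)))
    capture /= np.exp(_lognorm_sigma(config.capture_cv) ** 2 / 2)  # mean 1
    capture[cells["qc_class"] == "low_umi"] = config.spikein_low_capture
    capture[cells["qc_class"] == "high_umi"] = config.spikein_high_capture
    cells["capture_efficiency"] = capture

    return GroundTruth(genes=genes, cells=cells, config=config)


def _lognorm_sigma(cv: float) -> float:
    """sigma of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log(1.0 + cv**2)))


def simulate_fucci_traces(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell FUCCI time series aligned at the metaphase-to-anaphase transition.

    The G1 channel is a per-cell amplitude times the accumulation curve plus
    Gaussian noise; the raw G2 channel is the true G2 signal (zero during G1,
    rising after ``g1_end``) plus ``crosstalk_fraction`` x the G1 channel, so
    the crosstalk-correction stage has something to undo.

    Returns (trace table, ground truth).  Columns: cell_id, t_min, g1,
    g2_raw, amplitude.
    """
    if truth is None:
        truth = simulate_ground_truth(config)
    rng = _child_rng(config, 1)

    t = np.arange(0.0, config.trace_t_end + config.trace_t_step / 2,
                  config.trace_t_step)
    base = fucci_accumulation(t, config.fucci_tau)
    g2_true = np.where(t > config.g1_end,
                       (t - config.g1_end) * config.g2_rise_rate, 0.0)

    if config.trace_amplitude_cv > 0:
        s = _lognorm_sigma(config.trace_amplitude_cv)
        amps = np.exp(rng.normal(0.0, s, config.n_traces) - s**2 / 2)
    else:
        amps = np.ones(config.n_traces)

    frames = []
    for i in range(config.n_traces):
        g1 = amps[i] * base
        if config.measurement_noise_sd > 0:
            g1 = g1 + rng.normal(0.0, config.measurement_noise_sd, t.size)
        g2_raw = g2_true + config.crosstalk_fraction * g1
        if config.measurement_noise_sd > 0:
            g2_raw = g2_raw + rng.normal(0.0, config.measurement_noise_sd, t.size)
        frames.append(pd.DataFrame({
            "cell_id": f"trace_{i:03d}", "t_min": t, "g1": g1,
            "g2_raw": g2_raw, "amplitude": amps[i],
        }))
    traces = pd.concat(frames, ignore_index=True)
    return traces, truth


def simulate_facs_snapshot(
    config: SimulationConfig,
    truth: GroundTruth,
    noise_seed: int | None = None,
) -> pd.DataFrame:
    """FACS index-sort snapshot for every cell in the ground truth.

    G1-gated cells carry a G1 intensity read off the accumulation curve at
    their true cell-cycle time (per-cell amplitude heterogeneity included);
    G2/M cells carry a high G2 signal; early-S cells sit in the low-G2,
    high-G1 gate used for normalization.  Intensities are in FACS units
    (``facs_gain`` times the microscopy scale) with additive Gaussian noise.

    ``noise_seed`` only reseeds the measurement noise and nuisance draws;
    true cell states always come from the ground truth.
    """
    if config.n_plates == 0:
        raise ValueError("n_plates must be >= 1")
    rng = (_child_rng(config, 2) if noise_seed is None
           else np.random.default_rng(int(noise_seed) % (2**31)))

    cells = truth.cells
    n = len(cells)
    gain = config.facs_gain
    noise_sd = config.facs_noise_sd * gain

    if config.trace_amplitude_cv > 0:
        s = _lognorm_sigma(config.trace_amplitude_cv)
        amps = np.exp(rng.normal(0.0, s, n) - s**2 / 2)
    else:
        amps = np.ones(n)

    g1 = np.zeros(n)
    g2_true = np.zeros(n)
    gate = cells["sort_gate"].to_numpy()
    times = cells["cell_cycle_time"].to_numpy()

    is_g1 = gate == "G1"
    g1[is_g1] = gain * amps[is_g1] * fucci_accumulation(
        times[is_g1], config.fucci_tau)
    is_g2m = gate == "G2M"
    g2_true[is_g2m] = gain * rng.uniform(1.5, 2.5, int(is_g2m.sum()))
    is_es = gate == "earlyS"
    g1[is_es] = gain * amps[is_es] * fucci_accumulation(
        config.g1_end, config.fucci_tau)
    # early-S G2 signal sits at 3-9% of the snapshot's G2 range (max ~2.5*gain)
    g2_true[is_es] = gain * rng.uniform(0.075, 0.225, int(is_es.sum()))

    g2_raw = g2_true + config.crosstalk_fraction * g1
    if noise_sd > 0:
        g1 = g1 + rng.normal(0.0, noise_sd, n)
        g2_raw = g2_raw + rng.normal(0.0, noise_sd, n)

    return pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "plate_id": cells["plate_id"].to_numpy(),
        "g1": g1,
        "g2_raw": g2_raw,
        "gate_label": gate,
    })


def true_expression(truth: GroundTruth, t: np.ndarray) -> np.ndarray:
    """Evaluate every gene's true mean trajectory m_g(t) (genes x len(t))."""
    genes = truth.genes
    t = np.asarray(t, dtype=float)
    out = np.empty((len(genes), t.size))
    for i, row in enumerate(genes.itertuples(index=False)):
        if row.wave_group == "stable" or row.gamma <= 0:
            out[i] = row.m0
        else:
            out[i] = model_eval(row.m0, row.mu, row.gamma, row.t_onset, t)
    return out


def simulate_counts(
    config: SimulationConfig,
    truth: GroundTruth,
) -> "CountsMatrix":
    """Negative-binomial UMI counts for all sequenced cells.

    count[g, c] ~ NB(mean = capture_c * m_g(t_c), var = mean + a*mean^2)
    with a = ``nb_dispersion``; dispersion below 1e-8 falls back to Poisson.
    G2/M cells are evaluated at a nominal pre-metaphase time (-10 min), where
    every gene still sits at m0.  Early-S snapshot cells are not sequenced.
    """
    from .qc import CountsMatrix  # local import to avoid a cycle

    rng = _child_rng(config, 3)
    seq = truth.cells[truth.cells["qc_class"] != "snapshot_only"].reset_index(drop=True)
    times = seq["cell_cycle_time"].to_numpy().copy()
    times[seq["phase"].to_numpy() == "G2M"] = G2M_NOMINAL_TIME

    mean_traj = true_expression(truth, times)  # genes x cells (per-cell time)
    means = mean_traj * seq["capture_efficiency"].to_numpy()[None, :]
    if np.any(means < 0):
        raise ValueError("negative mean expression from invalid parameter draw")

    if config.nb_dispersion < 1e-8:
        counts = rng.poisson(means)
    else:
        r = 1.0 / config.nb_dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)

    return CountsMatrix(
        gene_ids=truth.genes["gene_id"].to_numpy(),
        cell_ids=seq["cell_id"].to_numpy(),
        counts=counts.astype(np.int64),
        plate_labels=seq["plate_id"].to_numpy(),
    )


def export_truth(truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write gene and cell truth tables as TSV; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out_dir / "truth_genes.tsv",
        "cells": out_dir / "truth_cells.tsv",
    }
    truth.genes.to_csv(paths["genes"], sep="\t", index=False)
    truth.cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths


def load_truth(out_dir: str | Path) -> GroundTruth:
    out_dir = Path(out_dir)
    genes = pd.read_csv(out_dir / "truth_genes.tsv", sep="\t")
    cells = pd.read_csv(out_dir / "truth_cells.tsv", sep="\t")
    return GroundTruth(genes=genes, cells=cells)
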