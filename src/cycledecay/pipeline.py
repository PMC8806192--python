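"""End-to-end orchestration: simulate -> calibrate -> timestamp -> qc -> de
-> waves -> fit-decay -> report.

Every stage parameter defaults to the study's stated constant (31%
crosstalk, UMI bounds 5900/111000, detection mean 2, alpha 0.05, 2-fold,
-0.95 slope threshold, onset grid 0..370 step 10) and is logged verbatim in
the machine-readable run report.  Identical config + seed give an identical
report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import de as de_mod
from . import kinetics, qc, waves
from .synthetic import (
    G2M_NOMINAL_TIME,
    SimulationConfig,
    simulate_counts,
    simulate_facs_snapshot,
    simulate_fucci_traces,
    simulate_ground_truth,
)

__all__ = ["RunConfig", "run_pipeline", "write_report", "read_report",
           "validate_report"]

log = logging.getLogger("cycledecay")


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # calibration / timestamping
    crosstalk_fraction: float = cal.DEFAULT_CROSSTALK
    g2_clip_threshold: float = 0.05  # fraction of corrected G2 range
    confidence_horizon: float = cal.DEFAULT_CONFIDENCE_HORIZON
    robust_gate: bool = False

    # qc
    umi_lower: int = qc.UMI_LOWER
    umi_upper: int = qc.UMI_UPPER
    min_detection_mean: float = qc.MIN_DETECTION_MEAN
    size_factor_method: str = "geometric"

    # differential expression
    de_alpha: float = 0.05
    fold_cut: float = 2.0
    g1_horizon: float = de_mod.DEFAULT_G1_HORIZON
    fc_window: tuple[float, float] = (180.0, 240.0)

    # waves
    wave_threshold: float = waves.WAVE_THRESHOLD
    wave_mode: str = "window"
    immediate_boundary: float = waves.IMMEDIATE_BOUNDARY
    wave_grid_step: float = 1.0
    wave_grid_end: float = 540.0
    spline_lam: float | None = waves.DEFAULT_WAVE_LAM  # None -> GCV

    # kinetics
    onset_grid_start: float = 0.0
    onset_grid_end: float = 370.0
    onset_grid_step: float = 10.0
    g2m_nominal_time: float = G2M_NOMINAL_TIME

    @property
    def rng_seed(self) -> int:
        return self.simulation.rng_seed

    def onset_grid(self) -> np.ndarray:
        return np.arange(self.onset_grid_start,
                         self.onset_grid_end + self.onset_grid_step / 2,
                         self.onset_grid_step)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulation", {}) or {}
        for key in ("g1_time_range", "ss_fraction_range"):
            if key in sim and sim[key] is not None:
                sim[key] = tuple(sim[key])
        if "fc_window" in d and d["fc_window"] is not None:
            d["fc_window"] = tuple(d["fc_window"])
        return cls(simulation=SimulationConfig(**sim), **d)


def _sha(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    traces: pd.DataFrame | None = None,
    facs: pd.DataFrame | None = None,
    counts: qc.CountsMatrix | None = None,
) -> dict:
    """Execute the pipeline and return the run report.

    Pre-supplied inputs (``traces``, ``facs``, ``counts``) skip the
    corresponding simulation; with ``counts=None`` and no simulated counts
    requested, only the calibration/timestamp stages run.  Artifacts are
    written under ``out_dir`` when given.
    """
    report: dict = {"rng_seed": int(config.rng_seed), "stages": {},
                    "parameters": _parameter_log(config)}
    artifacts: dict[str, pd.DataFrame] = {}
    simulate = traces is None and facs is None and counts is None
    truth = None

    if simulate:
        truth = simulate_ground_truth(config.simulation)
        traces, _ = simulate_fucci_traces(config.simulation, truth)
        facs = simulate_facs_snapshot(config.simulation, truth)
        counts = simulate_counts(config.simulation, truth)
        report["stages"]["simulate"] = {
            "n_genes": int(len(truth.genes)),
            "n_cells": int(len(truth.cells)),
            "n_sequenced": int(counts.n_cells),
        }
        log.info("simulate: %d genes, %d cells (%d sequenced)",
                 len(truth.genes), len(truth.cells), counts.n_cells)

    # ---- calibrate ----
    if traces is None:
        raise ValueError("stage calibrate failed: no trace input")
    clipped, clip_time = cal.clip_traces(
        traces, config.crosstalk_fraction, config.g2_clip_threshold)
    curve = cal.fit_mean_trace_polynomial(clipped)
    curve.confidence_horizon = config.confidence_horizon
    curve.timing_sd_table = cal.timing_sd(clipped, curve)
    report["stages"]["calibrate"] = {
        "clip_time": clip_time,
        "coefficients": curve.coefficients.tolist(),
        "valid_time_range": list(curve.valid_time_range),
        "early_s_mean_microscopy": curve.early_s_mean_intensity,
        "mean_timing_sd": float(curve.timing_sd_table["timing_sd"].mean()),
    }
    log.info("calibrate: clip at %.0f min, traces -> cubic on %s",
             clip_time, curve.valid_time_range)

    # ---- timestamp ----
    timed = None
    if facs is not None:
        facs = facs.copy()
        facs["g2_corrected"] = cal.correct_crosstalk(
            facs["g1"], facs["g2_raw"], config.crosstalk_fraction)
        _, facs_es_mean = cal.gate_early_s(facs, robust=config.robust_gate)
        timed = cal.assign_times(facs, curve, facs_es_mean)
        flags = timed["time_flag"].value_counts().to_dict()
        report["stages"]["timestamp"] = {
            "early_s_mean_facs": facs_es_mean,
            "n_cells": int(len(timed)),
            "time_flags": {str(k): int(v) for k, v in flags.items()},
        }
        artifacts["timed_cells"] = timed
        log.info("timestamp: %d cells, FACS early-S mean %.3f",
                 len(timed), facs_es_mean)

    if counts is None or timed is None:
        report["artifact_checksums"] = {k: _sha(v) for k, v in artifacts.items()}
        _maybe_write(artifacts, out_dir, report)
        return report

    # ---- qc ----
    kept, qc_report = qc.filter_cells_by_umi(counts, config.umi_lower,
                                             config.umi_upper)
    kept.size_factors = qc.compute_size_factors(kept, config.size_factor_method)
    timed_seq = timed[timed["cell_id"].isin(kept.cell_ids)].set_index("cell_id")
    timed_seq = timed_seq.loc[list(kept.cell_ids)].reset_index()
    g2m_ids = timed_seq.loc[timed_seq["gate_label"] == "G2M", "cell_id"]
    detected = qc.filter_detected_genes(kept, g2m_ids, config.min_detection_mean)
    filtered = kept.subset_genes(detected)
    report["stages"]["qc"] = {
        **qc_report,
        "n_genes_input": int(counts.n_genes),
        "n_genes_detected": int(detected.sum()),
        "size_factor_method": config.size_factor_method,
    }
    log.info("qc: %d/%d cells kept, %d/%d genes detected",
             qc_report["n_kept"], qc_report["n_input"],
             detected.sum(), counts.n_genes)

    # ---- differential expression ----
    g2m_cells, g1_cells = de_mod.select_de_cells(timed_seq, config.g1_horizon)
    lo, hi = config.fc_window
    in_window = (timed_seq["gate_label"] == "G1") \
        & timed_seq["cell_cycle_time"].between(lo, hi)
    fc_cells = timed_seq.loc[in_window, "cell_id"].to_numpy()
    de_table, threshold = de_mod.run_de(
        filtered, g2m_cells, g1_cells, fc_g1_cells=fc_cells,
        alpha=config.de_alpha, fold_cut=config.fold_cut)
    n_down = int((de_table["direction"] == "down").sum())
    n_up = int((de_table["direction"] == "up").sum())
    report["stages"]["de"] = {
        "n_g2m": int(len(g2m_cells)), "n_g1": int(len(g1_cells)),
        "bonferroni_threshold": float(threshold),
        "n_down": n_down, "n_up": n_up,
        "n_ns": int((de_table["direction"] == "ns").sum()),
    }
    artifacts["de_table"] = de_table
    log.info("de: %d down, %d up of %d genes (threshold %.4g)",
             n_down, n_up, len(de_table), threshold)

    # ---- waves + kinetics on downregulated genes ----
    down_genes = de_table.loc[de_table["direction"] == "down", "gene_id"]
    gene_pos = {g: i for i, g in enumerate(filtered.gene_ids)}
    down_idx = np.array([gene_pos[g] for g in down_genes], dtype=int)
    times = timed_seq["cell_cycle_time"].to_numpy(dtype=float).copy()
    times[(timed_seq["gate_label"] == "G2M").to_numpy()] = config.g2m_nominal_time
    usable = np.isfinite(times)
    expr = filtered.normalized[np.ix_(down_idx, np.flatnonzero(usable))]
    t_use = times[usable]

    wave_table = pd.DataFrame(
        columns=["gene_id", "t_max_decline", "t_cross", "wave_group"])
    fits = pd.DataFrame()
    if len(down_idx):
        wave_table = waves.call_waves(
            t_use, expr, down_genes.to_numpy(),
            grid_end=config.wave_grid_end, grid_step=config.wave_grid_step,
            lam=config.spline_lam, threshold=config.wave_threshold,
            mode=config.wave_mode, boundary=config.immediate_boundary)
        fits = kinetics.fit_decay_table(
            t_use, expr, down_genes.to_numpy(), onset_grid=config.onset_grid())
        summary = kinetics.summarize_fits(fits, wave_table)
    else:
        summary = {"n_fits": 0, "median_half_life": None}
    group_sizes = wave_table["wave_group"].value_counts().to_dict()
    report["stages"]["waves"] = {
        "group_sizes": {str(k): int(v) for k, v in group_sizes.items()},
    }
    report["stages"]["fit_decay"] = summary
    artifacts["wave_table"] = wave_table
    artifacts["decay_fits"] = fits
    log.info("waves: %s; median half-life %.1f min",
             group_sizes, summary.get("median_half_life") or float("nan"))

    report["artifact_checksums"] = {k: _sha(v) for k, v in artifacts.items()}
    _maybe_write(artifacts, out_dir, report, truth=truth, curve=curve)
    return report


def _parameter_log(config: RunConfig) -> dict:
    d = asdict(config)
    d["simulation"] = asdict(config.simulation)
    return json.loads(json.dumps(d, default=list))


def _maybe_write(artifacts, out_dir, report, truth=None, curve=None) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in artifacts.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    if curve is not None:
        curve.to_json(out_dir / "calibration.json")
    if truth is not None:
        from .synthetic import export_truth
        export_truth(truth, out_dir)
    write_report(report, out_dir / "report.json")


def write_report(report: dict, path: str | Path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def read_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Minimal schema check: seed, per-stage dict, logged parameters."""
    for key in ("rng_seed", "stages", "parameters"):
        if key not in report:
            raise ValueError(f"run report missing required key {key!r}")
    if not isinstance(report["stages"], dict):
        raise ValueError("run report 'stages' must be a mapping")
    qc_stage = report["stages"].get("qc")
    if qc_stage is not None:
        total = qc_stage["n_kept"] + qc_stage["n_removed_low_umi"] \
            + qc_stage["n_removed_high_umi"]
        if total != qc_stage["n_input"]:
            raise ValueError("qc stage counts are not conserved")
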