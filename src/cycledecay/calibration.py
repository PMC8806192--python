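"""FUCCI-based absolute cell-cycle time calibration.

Converts FUCCI-G1 reporter fluorescence into minutes since the
metaphase-to-anaphase transition.  The mean of many aligned live-imaging
traces is fit to a third-order polynomial of intensity versus time; both
microscopy and FACS intensities are normalized to the mean FUCCI-G1
intensity of early-S-phase cells so the two instruments share a scale; the
polynomial is then inverted numerically per cell to assign a time.

The G2 channel carries 31% bleed-through from the G1 reporter; it is
corrected by linear subtraction before any gating or trace clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CalibrationCurve",
    "correct_crosstalk",
    "gate_early_s",
    "clip_traces",
    "fit_mean_trace_polynomial",
    "invert_time",
    "timing_sd",
    "assign_times",
]

DEFAULT_CROSSTALK = 0.31
DEFAULT_CONFIDENCE_HORIZON = 300.0  # minutes; accuracy degrades after ~5 hr


@dataclass
class CalibrationCurve:
    """Order-3 polynomial p(t) mapping minutes since metaphase to
    early-S-normalized FUCCI-G1 intensity, strictly increasing on
    ``valid_time_range``."""

    coefficients: np.ndarray  # ascending powers, length 4
    valid_time_range: tuple[float, float]
    early_s_mean_intensity: float
    timing_sd_table: pd.DataFrame | None = None  # columns t_min, timing_sd, flagged
    confidence_horizon: float = DEFAULT_CONFIDENCE_HORIZON

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != 4:
            raise ValueError("calibration polynomial must be order 3 (4 coefficients)")
        if self.early_s_mean_intensity <= 0:
            raise ValueError("early-S mean intensity must be positive")

    def __call__(self, t):
        return np.polynomial.polynomial.polyval(np.asarray(t, float),
                                                self.coefficients)

    def derivative(self, t):
        d = np.polynomial.polynomial.polyder(self.coefficients)
        return np.polynomial.polynomial.polyval(np.asarray(t, float), d)

    def is_monotone(self, n_grid: int = 2000) -> bool:
        t = np.linspace(*self.valid_time_range, n_grid)
        return bool(np.all(self.derivative(t) > 0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "valid_time_range": list(self.valid_time_range),
            "early_s_mean_intensity": self.early_s_mean_intensity,
            "confidence_horizon": self.confidence_horizon,
            "timing_sd_table": (None if self.timing_sd_table is None
                                else self.timing_sd_table.to_dict("list")),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        table = payload["timing_sd_table"]
        return cls(
            coefficients=np.asarray(payload["coefficients"]),
            valid_time_range=tuple(payload["valid_time_range"]),
            early_s_mean_intensity=payload["early_s_mean_intensity"],
            timing_sd_table=None if table is None else pd.DataFrame(table),
            confidence_horizon=payload["confidence_horizon"],
        )


def correct_crosstalk(g1, g2_raw, fraction: float = DEFAULT_CROSSTALK):
    """Remove G1-channel bleed-through: g2_raw - fraction * g1.

    May return negative values; callers decide whether to floor them.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("crosstalk fraction must be in [0, 1]")
    return np.asarray(g2_raw, float) - fraction * np.asarray(g1, float)


def gate_early_s(
    records: pd.DataFrame,
    g1_col: str = "g1",
    g2_col: str = "g2_corrected",
    g2_low: float = 0.025,
    g2_high: float = 0.10,
    g1_low: float = 0.025,
    robust: bool = False,
    min_cells: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Early-S gate: G2 intensity within [2.5%, 10%] of the G2 range and G1
    intensity above 2.5% of the G1 range.

    The per-channel range is max - min over the table (literal reading of
    "range"); ``robust=True`` uses the 0.5-99.5 percentile span instead to
    guard against FACS outliers.  Returns the gated subset and its mean G1
    intensity, the normalization factor shared by microscopy and FACS.
    """
    if len(records) < min_cells:
        raise ValueError("too few cells to gate early-S population")
    g1 = records[g1_col].to_numpy(dtype=float)
    g2 = records[g2_col].to_numpy(dtype=float)
    if robust:
        g1_lo, g1_hi = np.percentile(g1, [0.5, 99.5])
        g2_lo, g2_hi = np.percentile(g2, [0.5, 99.5])
    else:
        g1_lo, g1_hi = g1.min(), g1.max()
        g2_lo, g2_hi = g2.min(), g2.max()
    g1_range = g1_hi - g1_lo
    g2_range = g2_hi - g2_lo
    keep = (
        (g2 >= g2_lo + g2_low * g2_range)
        & (g2 <= g2_lo + g2_high * g2_range)
        & (g1 >= g1_lo + g1_low * g1_range)
    )
    subset = records[keep]
    if subset.empty:
        raise ValueError(
            "early-S gate is empty: no cell has G2 in "
            f"[{g2_low:.1%}, {g2_high:.1%}] of its range with G1 above "
            f"{g1_low:.1%} of its range")
    return subset, float(subset[g1_col].mean())


def clip_traces(
    traces: pd.DataFrame,
    crosstalk_fraction: float = DEFAULT_CROSSTALK,
    g2_threshold_frac: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Clip aligned traces at the end of G1 phase.

    G1 ends shortly after the (crosstalk-corrected) G2 signal starts to
    rise; the clip time is the last time point before the mean corrected G2
    intensity exceeds ``g2_threshold_frac`` of its range.  Returns the
    clipped trace table and the clip time.
    """
    t_col = traces["t_min"]
    g2c = correct_crosstalk(traces["g1"], traces["g2_raw"], crosstalk_fraction)
    mean_g2 = pd.Series(g2c).groupby(t_col.to_numpy()).mean()
    rng_ = mean_g2.max() - mean_g2.min()
    if rng_ <= 0:
        return traces.copy(), float(t_col.max())
    threshold = mean_g2.min() + g2_threshold_frac * rng_
    above = mean_g2[mean_g2 > threshold]
    clip_time = float(t_col.max()) if above.empty else float(above.index.min())
    clipped = traces[t_col < clip_time].copy()
    return clipped, clip_time


def fit_mean_trace_polynomial(
    traces: pd.DataFrame,
    early_s_mean: float | None = None,
) -> CalibrationCurve:
    """Least-squares third-order polynomial of the mean G1 trace vs time.

    ``traces`` must already be clipped at the end of G1.  Intensities are
    normalized by ``early_s_mean`` before fitting (default: the mean trace
    intensity at the last clipped time point, a proxy for the early-S level
    since FUCCI-G1 plateaus around the G1/S boundary).  The fit must be
    strictly increasing over the observed time span.
    """
    mean_trace = traces.groupby("t_min")["g1"].mean()
    if len(mean_trace) < 4:
        raise ValueError("need at least 4 distinct time points for a cubic fit")
    t = mean_trace.index.to_numpy(dtype=float)
    y = mean_trace.to_numpy(dtype=float)
    if early_s_mean is None:
        early_s_mean = float(y[-1])
    if early_s_mean <= 0:
        raise ValueError("early-S normalization factor must be positive")
    y = y / early_s_mean

    p = np.polynomial.Polynomial.fit(t, y, 3).convert()
    curve = CalibrationCurve(
        coefficients=p.coef,
        valid_time_range=(float(t.min()), float(t.max())),
        early_s_mean_intensity=float(early_s_mean),
    )
    if not curve.is_monotone():
        raise ValueError(
            "fitted cubic is not strictly increasing on the valid time range; "
            "reduce the range (clip traces earlier) or inspect the input traces")
    return curve


def invert_time(
    curve: CalibrationCurve,
    normalized_g1: float,
    tol: float = 1e-6,
) -> tuple[float, str]:
    """Unique root of p(t) = normalized_g1 on the valid range.

    Intensities below p(t_min) clamp to t_min (``clamped_low``), above
    p(t_max) to t_max (``clamped_high``); the cubic is never extrapolated.
    Times past the confidence horizon are flagged ``low_confidence``.
    """
    if not curve.is_monotone():
        raise ValueError("calibration curve must be strictly increasing")
    t_min, t_max = curve.valid_time_range
    y = float(normalized_g1)
    y_min, y_max = float(curve(t_min)), float(curve(t_max))
    if y <= y_min:
        return float(t_min), "clamped_low"
    if y >= y_max:
        return float(t_max), "clamped_high"
    t = brentq(lambda x: float(curve(x)) - y, t_min, t_max, xtol=tol)
    flag = "low_confidence" if t > curve.confidence_horizon else "ok"
    return float(t), flag


def timing_sd(
    traces: pd.DataFrame,
    curve: CalibrationCurve,
) -> pd.DataFrame:
    """Per-time-point SD of FUCCI-G1 timing from trace heterogeneity.

    At every time point the mean and SD of the (normalized) trace
    intensities are mapped through the inverse calibration; the timing SD is
    the average absolute time offset of the +1 SD and -1 SD intensities from
    the mean-intensity time.  Time points where mean +/- SD leaves the
    invertible range are clamped and flagged.
    """
    grouped = traces.groupby("t_min")["g1"]
    if traces["cell_id"].nunique() < 2:
        raise ValueError("timing SD needs at least two traces")
    rows = []
    esm = curve.early_s_mean_intensity
    for t, vals in grouped:
        m = vals.mean() / esm
        s = vals.std(ddof=0) / esm
        t_mid, f_mid = invert_time(curve, m)
        t_hi, f_hi = invert_time(curve, m + s)
        t_lo, f_lo = invert_time(curve, m - s)
        flagged = any(f.startswith("clamped") for f in (f_mid, f_hi, f_lo))
        sd = 0.5 * (abs(t_hi - t_mid) + abs(t_lo - t_mid))
        rows.append({"t_min": float(t), "timing_sd": float(sd), "flagged": flagged})
    return pd.DataFrame(rows)


def assign_times(
    records: pd.DataFrame,
    curve: CalibrationCurve,
    facs_early_s_mean: float,
    gate_col: str = "gate_label",
    g1_col: str = "g1",
) -> pd.DataFrame:
    """Assign absolute cell-cycle times to FACS-sorted cells.

    G1-gated cells get normalized_g1 = raw / FACS early-S mean and a time
    from the inverted calibration curve; G2/M (and any other) gates keep
    their record but no G1 time.
    """
    if facs_early_s_mean is None or facs_early_s_mean <= 0:
        raise ValueError("missing or non-positive FACS early-S mean")
    out = records.copy()
    out["normalized_g1"] = out[g1_col].to_numpy(dtype=float) / facs_early_s_mean
    times = np.full(len(out), np.nan)
    flags = np.array(["no_time"] * len(out), dtype=object)
    is_g1 = (out[gate_col] == "G1").to_numpy()
    for i in np.flatnonzero(is_g1):
        times[i], flags[i] = invert_time(curve, out["normalized_g1"].iloc[i])
    out["cell_cycle_time"] = times
    out["time_flag"] = flags
    return out
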