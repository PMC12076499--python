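"""Period estimation, oscillation classification and phase-space scans.

Period is the mean peak-to-peak interval of post-transient local maxima with
parabolic sub-sample refinement, reported in hours.  Classification uses the
per-cycle amplitude-decay ratio of successive peak prominences: sustained
oscillations keep (to a configurable threshold) their amplitude from one
cycle to the next, damped ones lose it, and signals without enough maxima
are "none".  Thresholds travel with every result so scans are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .crn_model import (
    TIME_UNIT_HOURS,
    FlowConditions,
    ReactionNetwork,
    apply_flow,
    build_rhs,
)
from .node_core import NeuralCorrection, SolverConfig, Trajectory, augmented_rhs, solve

__all__ = [
    "OscillationSummary",
    "PhaseDiagram",
    "estimate_period",
    "classify_oscillation",
    "scan_phase_space",
    "diff_phase_diagrams",
    "period_table",
]

DEFAULT_DECAY_THRESHOLD = 0.95
DEFAULT_TRANSIENT_FRACTION = 0.3
DEFAULT_MIN_PEAKS = 3


@dataclass(frozen=True)
class OscillationSummary:
    """Classification of one trajectory: class, period (h) and amplitude."""

    oscillation_class: str  # "sustained" | "damped" | "none"
    period_h: float | None
    amplitude: float
    decay_ratio: float | None
    thresholds: dict = field(default_factory=dict)
    flag: str = ""

    def __post_init__(self) -> None:
        if self.oscillation_class not in ("sustained", "damped", "none"):
            raise ValueError(f"bad class {self.oscillation_class!r}")
        if (self.period_h is not None) != (self.oscillation_class != "none"):
            raise ValueError("period must be present exactly when class != 'none'")
        if self.period_h is not None and self.period_h <= 0:
            raise ValueError("period must be > 0")


def _refined_peaks(
    times_h: np.ndarray, signal: np.ndarray, min_prominence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Peak times with parabolic sub-sample refinement, and their prominences."""
    idx, props = find_peaks(signal, prominence=min_prominence)
    refined = []
    for i in idx:
        if 0 < i < signal.size - 1:
            denom = signal[i - 1] - 2.0 * signal[i] + signal[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (signal[i - 1] - signal[i + 1]) / denom
            dt = 0.5 * (times_h[i + 1] - times_h[i - 1])
            refined.append(times_h[i] + np.clip(shift, -1.0, 1.0) * dt)
        else:
            refined.append(times_h[i])
    return np.asarray(refined), props["prominences"]


def _post_transient(
    trajectory: Trajectory, species: int, transient_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    times_h = trajectory.times * TIME_UNIT_HOURS[trajectory.time_unit]
    t_cut = times_h[0] + transient_fraction * (times_h[-1] - times_h[0])
    keep = times_h >= t_cut
    return times_h[keep], trajectory.states[keep, species]


def estimate_period(
    trajectory: Trajectory,
    species: int,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> float | None:
    """Mean post-transient peak-to-peak interval, in hours; None if too few maxima.

    Invariant to vertical offset and (positive) uniform scaling of the signal.
    """
    times_h, signal = _post_transient(trajectory, species, transient_fraction)
    span = float(signal.max() - signal.min())
    if span <= 0:
        return None
    peak_times, _ = _refined_peaks(times_h, signal, 1e-4 * span)
    if peak_times.size < min_peaks:
        return None
    return float(np.mean(np.diff(peak_times)))


def classify_oscillation(
    trajectory: Trajectory,
    species: int,
    decay_threshold: float = DEFAULT_DECAY_THRESHOLD,
    transient_fraction: float = DEFAULT_TRANSIENT_FRACTION,
    min_peaks: int = DEFAULT_MIN_PEAKS,
    amplitude_floor: float = 0.0,
) -> OscillationSummary:
    """Sustained / damped / none verdict with the thresholds that produced it.

    Sustained requires at least ``min_peaks`` post-transient maxima whose
    median cycle-to-cycle prominence ratio stays at or above
    ``decay_threshold`` (and amplitude above ``amplitude_floor``); maxima that
    fail the ratio make the signal damped; fewer than two maxima mean none.
    Raising the threshold can only demote sustained cells, never promote.
    """
    thresholds = {
        "decay_threshold": decay_threshold,
        "transient_fraction": transient_fraction,
        "min_peaks": min_peaks,
        "amplitude_floor": amplitude_floor,
    }
    times_h, signal = _post_transient(trajectory, species, transient_fraction)
    span = float(signal.max() - signal.min())
    none = OscillationSummary("none", None, 0.0, None, thresholds)
    if span <= 0:
        return none
    peak_times, prominences = _refined_peaks(times_h, signal, max(1e-4 * span, amplitude_floor))
    if peak_times.size < 2:
        return none
    period = float(np.mean(np.diff(peak_times)))
    amplitude = float(np.mean(prominences))
    decay = float(np.median(prominences[1:] / prominences[:-1]))
    sustained = (
        peak_times.size >= min_peaks
        and decay >= decay_threshold
        and amplitude > amplitude_floor
    )
    klass = "sustained" if sustained else "damped"
    return OscillationSummary(klass, period, amplitude, decay, thresholds)


@dataclass(frozen=True)
class PhaseDiagram:
    """Oscillation summaries over the Cartesian product of two inflow grids.

    Axis 1 is the fuel-ester (Fmoc-piperidine) inflow, axis 2 the slow
    inhibitor (phenyl acetate) inflow, both in molar.  ``cells[i][j]``
    corresponds to ``(fmoc_grid[i], pa_grid[j])``.
    """

    fmoc_grid: np.ndarray
    pa_grid: np.ndarray
    cells: tuple[tuple[OscillationSummary, ...], ...]
    model_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fmoc_grid", np.asarray(self.fmoc_grid, dtype=float))
        object.__setattr__(self, "pa_grid", np.asarray(self.pa_grid, dtype=float))
        if len(self.cells) != self.fmoc_grid.size or any(
            len(row) != self.pa_grid.size for row in self.cells
        ):
            raise ValueError("cells must form the Cartesian product of the axis grids")

    def period_matrix(self) -> np.ndarray:
        """Periods (h) where defined, NaN elsewhere."""
        out = np.full((self.fmoc_grid.size, self.pa_grid.size), np.nan)
        for i, row in enumerate(self.cells):
            for j, c in enumerate(row):
                if c.period_h is not None:
                    out[i, j] = c.period_h
        return out

    def class_matrix(self) -> np.ndarray:
        return np.array(
            [[c.oscillation_class for c in row] for row in self.cells], dtype=object
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fmoc_grid):
            for j, p in enumerate(self.pa_grid):
                c = self.cells[i][j]
                rows.append(
                    {
                        "fmoc_in_M": f,
                        "pa_in_M": p,
                        "class": c.oscillation_class,
                        "period_h": np.nan if c.period_h is None else c.period_h,
                        "amplitude": c.amplitude,
                        "flag": c.flag,
                    }
                )
        return pd.DataFrame(rows)


def _cell_flow(template: FlowConditions, fmoc_in: float, pa_in: float) -> FlowConditions:
    inflow = np.array(template.inflow, dtype=float, copy=True)
    inflow[1] = fmoc_in  # species 2, fuel ester
    inflow[3] = pa_in  # species 4, slow inhibitor
    return FlowConditions(inflow=inflow, dilution_rate=template.dilution_rate)


def scan_phase_space(
    network: ReactionNetwork,
    fmoc_grid: Sequence[float],
    pa_grid: Sequence[float],
    flow_template: FlowConditions,
    y0: np.ndarray,
    horizon: float = 240.0,
    n_points: int = 2400,
    species: int = 5,
    correction: NeuralCorrection | None = None,
    solver: SolverConfig | None = None,
    model_tag: str | None = None,
    **classify_kwargs,
) -> PhaseDiagram:
    """One solve plus classification per grid cell.

    A trained correction, when given, is reused unchanged across all cells —
    learned dynamics transfer between experimental settings.  Per-cell solver
    failures yield a flagged "none" cell rather than aborting the scan, and
    cells are independent of evaluation order.
    """
    fmoc_grid = np.asarray(fmoc_grid, dtype=float)
    pa_grid = np.asarray(pa_grid, dtype=float)
    if fmoc_grid.size == 0 or pa_grid.size == 0:
        raise ValueError("axis grids must be nonempty")
    solver = solver or SolverConfig()
    times = np.linspace(0.0, horizon, n_points)
    rows = []
    for f in fmoc_grid:
        row = []
        for p in pa_grid:
            flow = _cell_flow(flow_template, f, p)
            if correction is not None:
                rhs = augmented_rhs(network, correction, flow)
            else:
                rhs = apply_flow(build_rhs(network), flow, network.constant_mask)
            try:
                traj = solve(rhs, y0, times, solver, time_unit=network.time_unit)
            except Exception as exc:  # per-cell failure is data, not fatal
                row.append(
                    OscillationSummary("none", None, 0.0, None, flag=f"solver_failure: {exc}")
                )
                continue
            row.append(classify_oscillation(traj, species, **classify_kwargs))
        rows.append(tuple(row))
    tag = model_tag or (network.name if correction is None else f"{network.name}+correction")
    return PhaseDiagram(fmoc_grid, pa_grid, tuple(rows), model_tag=tag)


def diff_phase_diagrams(a: PhaseDiagram, b: PhaseDiagram) -> np.ndarray:
    """Per-cell period difference ``a - b`` (h) where both cells are sustained.

    Cells where either diagram is not sustained are NaN (undefined).
    """
    if not (
        np.array_equal(a.fmoc_grid, b.fmoc_grid) and np.array_equal(a.pa_grid, b.pa_grid)
    ):
        raise ValueError("phase diagrams are on different grids")
    out = np.full((a.fmoc_grid.size, a.pa_grid.size), np.nan)
    for i in range(a.fmoc_grid.size):
        for j in range(a.pa_grid.size):
            ca, cb = a.cells[i][j], b.cells[i][j]
            if ca.oscillation_class == "sustained" and cb.oscillation_class == "sustained":
                out[i, j] = ca.period_h - cb.period_h
    return out


def period_table(
    models: Mapping[str, tuple[ReactionNetwork, NeuralCorrection | None]],
    settings: Sequence[tuple[float, float]],
    flow_template: FlowConditions,
    y0: np.ndarray,
    horizon: float = 240.0,
    n_points: int = 2400,
    species: int = 5,
    solver: SolverConfig | None = None,
    **classify_kwargs,
) -> pd.DataFrame:
    """Predicted period (h) per (inflow setting, model), one row per setting."""
    solver = solver or SolverConfig()
    times = np.linspace(0.0, horizon, n_points)
    records = []
    for fmoc_in, pa_in in settings:
        rec: dict = {"fmoc_in_M": fmoc_in, "pa_in_M": pa_in}
        for tag, (network, correction) in models.items():
            flow = _cell_flow(flow_template, fmoc_in, pa_in)
            if correction is not None:
                rhs = augmented_rhs(network, correction, flow)
            else:
                rhs = apply_flow(build_rhs(network), flow, network.constant_mask)
            traj = solve(rhs, y0, times, solver, time_unit=network.time_unit)
            summary = classify_oscillation(traj, species, **classify_kwargs)
            rec[f"period_h_{tag}"] = (
                np.nan if summary.period_h is None else summary.period_h
            )
        records.append(rec)
    return pd.DataFrame(records)
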