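"""Fitting the neural correction to noisy concentration measurements.

Measurements arrive as per-time, per-species means and standard deviations
(computed over replicate experiments); synthetic training series are drawn
from the normal distribution those statistics parameterize.  The correction
is trained with an AdaBelief optimizer on a masked MSE over the measured
species, in two phases: first on the leading fraction of every series (the
curriculum that keeps oscillatory fits out of poor local minima), then on the
full series.  The parameters returned are the ones with the best validation
MSE seen at any evaluation point, not the final iterate.

Dropout is deliberately unsupported: stochastic evaluation inside an ODE
solve destabilizes the step-size control.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .crn_model import FlowConditions, ReactionNetwork
from .node_core import NeuralCorrection
from .sensitivity import AdjointSystem, mse_loss_and_grad, rk4_trajectory

__all__ = [
    "MeasurementSeries",
    "TrainingConfig",
    "TrainingData",
    "LossReport",
    "sample_dataset",
    "mse_loss",
    "train",
    "theory_only_mse",
    "AdaBelief",
]


@dataclass(frozen=True)
class MeasurementSeries:
    """Replicate-summary statistics of a concentration time series.

    ``mean`` and ``std`` are time x species matrices covering every species in
    the network ordering; ``measured_mask`` marks the species that were
    actually observed (only those enter losses and the correction's I/O).
    """

    times: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    measured_mask: np.ndarray
    species_names: tuple[str, ...]
    time_unit: str = "h"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        object.__setattr__(self, "measured_mask", np.asarray(self.measured_mask, dtype=bool))
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be >= 0")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("means must be finite")
        if self.measured_mask.sum() < 1:
            raise ValueError("at least one species must be measured")
        if self.mean.shape != self.std.shape or self.mean.shape[0] != self.times.size:
            raise ValueError("mean/std/time shapes are inconsistent")

    @property
    def measured_indices(self) -> np.ndarray:
        return np.flatnonzero(self.measured_mask)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and curriculum settings; dropout is fixed off."""

    n_train: int = 1000
    n_val: int = 100
    n_test: int = 100
    learning_rate: float = 6e-3
    optimizer: str = "adabelief"
    curriculum_fraction: float = 0.10
    steps_per_phase: int = 200
    batch_size: int = 32
    n_sub: int = 4
    y0_mode: str = "sample"  # "sample" | "mean"
    val_every: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.curriculum_fraction <= 1.0):
            raise ValueError("curriculum fraction must be in (0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.y0_mode not in ("sample", "mean"):
            raise ValueError("y0_mode must be 'sample' or 'mean'")


@dataclass(frozen=True)
class TrainingData:
    """A set of sampled series sharing one time grid."""

    times: np.ndarray
    samples: np.ndarray  # (n_series, n_times, n_species)
    measured_indices: np.ndarray
    y0: np.ndarray  # (n_series, n_species)

    @property
    def n_series(self) -> int:
        return self.samples.shape[0]

    def targets(self) -> np.ndarray:
        return self.samples[:, :, self.measured_indices]


@dataclass
class LossReport:
    """Per-step loss trace plus phase bookkeeping."""

    steps: list[int] = field(default_factory=list)
    phases: list[int] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    phase_boundaries: list[int] = field(default_factory=list)
    rejected_steps: list[int] = field(default_factory=list)
    best_step: int = -1
    best_val_mse: float = float("inf")
    wall_time_s: float = 0.0
    seed: int = 0

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "phase": self.phases, "train_mse": self.train_mse}
        )


def sample_dataset(
    measurements: MeasurementSeries,
    n: int,
    seed: int,
    y0_mode: str = "sample",
    clip_negative: bool = True,
) -> TrainingData:
    """Draw ``n`` series, cell-wise ``Normal(mean[t, k], std[t, k])``.

    Negative draws are clipped to zero (concentrations).  The initial state of
    each series is its own (noisy) first time point unless ``y0_mode='mean'``.
    Reproducible per seed; disjoint splits are obtained by spawning distinct
    seeds (see :func:`sample_splits`).
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    draws = rng.normal(
        loc=measurements.mean[None, :, :],
        scale=measurements.std[None, :, :],
        size=(n,) + measurements.mean.shape,
    )
    if clip_negative:
        draws = np.clip(draws, 0.0, None)
    y0 = draws[:, 0, :].copy() if y0_mode == "sample" else np.tile(measurements.mean[0], (n, 1))
    return TrainingData(
        times=measurements.times,
        samples=draws,
        measured_indices=measurements.measured_indices,
        y0=y0,
    )


def sample_splits(
    measurements: MeasurementSeries, config: TrainingConfig
) -> tuple[TrainingData, TrainingData, TrainingData]:
    """Disjoint train/validation/test datasets from one seed stream."""
    train_seed, val_seed, test_seed = np.random.SeedSequence(config.seed).spawn(3)
    mk = lambda n, ss: sample_dataset(
        measurements, n, np.random.default_rng(ss).integers(2**31), config.y0_mode
    )
    return (
        mk(config.n_train, train_seed),
        mk(config.n_val, val_seed),
        mk(config.n_test, test_seed),
    )


def mse_loss(
    predicted: np.ndarray,
    observed: np.ndarray,
    mask: np.ndarray,
    predicted_times: np.ndarray | None = None,
    observed_times: np.ndarray | None = None,
) -> float:
    """Mean squared error over times and masked species.

    Arrays are time x species (or batched with a leading axis); species where
    ``mask`` is false contribute nothing.
    """
    if predicted_times is not None and observed_times is not None:
        if predicted_times.shape != observed_times.shape or not np.allclose(
            predicted_times, observed_times
        ):
            raise ValueError("prediction and observation time grids differ")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    diff = predicted[..., mask] - observed[..., mask]
    return float(np.mean(diff**2))


class AdaBelief:
    """AdaBelief: adaptive moments driven by the surprise ``(g - m)^2``."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-16):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.s: dict[str, np.ndarray] = {}
        self.t = 0

    def update(
        self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for key, p in params.items():
            g = grads[key]
            m = self.m.setdefault(key, np.zeros_like(p))
            s = self.s.setdefault(key, np.zeros_like(p))
            m += (1.0 - self.beta1) * (g - m)
            s += (1.0 - self.beta2) * ((g - m) ** 2 - s) + self.eps
            m_hat = m / (1.0 - self.beta1**self.t)
            s_hat = s / (1.0 - self.beta2**self.t)
            out[key] = p - self.lr * m_hat / (np.sqrt(s_hat) + self.eps)
        return out


def _validation_mse(
    network: ReactionNetwork,
    correction: NeuralCorrection,
    data: TrainingData,
    flow: FlowConditions | None,
    n_sub: int,
    max_series: int = 32,
) -> float:
    sel = slice(0, min(max_series, data.n_series))
    system = AdjointSystem(network, correction, flow)
    states, _, save_idx = rk4_trajectory(system, data.y0[sel], data.times, n_sub)
    pred = states[:, save_idx, :][:, :, data.measured_indices]
    return float(np.mean((pred - data.targets()[sel]) ** 2))


def train(
    network: ReactionNetwork,
    correction: NeuralCorrection,
    data: TrainingData,
    config: TrainingConfig,
    flow: FlowConditions | None = None,
    val_data: TrainingData | None = None,
) -> tuple[NeuralCorrection, LossReport]:
    """Two-phase curriculum fit of theta; returns the best-validation iterate.

    Phase 1 fits only the leading ``curriculum_fraction`` of every series;
    phase 2 (skipped when the fraction is 1.0) fits the full series.  Steps
    whose loss or gradient is non-finite are rejected and logged rather than
    silently applied.
    """
    if data.n_series < 1:
        raise ValueError("empty training dataset")
    if tuple(data.measured_indices) != tuple(correction.measured_indices):
        raise ValueError("dataset and correction disagree on measured species")
    if np.allclose(correction.scale, 1.0):
        scale = np.maximum(
            np.abs(data.samples[:, :, data.measured_indices]).max(axis=(0, 1)), 1e-12
        )
        correction = correction.with_scale(scale)

    rng = np.random.default_rng(config.seed)
    opt = AdaBelief(config.learning_rate)
    report = LossReport(seed=config.seed)
    t_start = _time.perf_counter()

    n_times = data.times.size
    n_prefix = max(2, int(np.ceil(config.curriculum_fraction * n_times)))
    if config.curriculum_fraction >= 1.0:
        phases = [(1, n_times)]
    else:
        phases = [(1, n_prefix), (2, n_times)]

    best = correction
    if val_data is not None:
        report.best_val_mse = _validation_mse(network, correction, val_data, flow, config.n_sub)
        report.best_step = 0
        report.val_steps.append(0)
        report.val_mse.append(report.best_val_mse)

    step = 0
    targets_full = data.targets()
    for phase, n_fit in phases:
        times_fit = data.times[:n_fit]
        for _ in range(config.steps_per_phase):
            step += 1
            batch = rng.choice(data.n_series, size=min(config.batch_size, data.n_series), replace=False)
            loss, grads, _ = mse_loss_and_grad(
                network,
                correction,
                data.y0[batch],
                times_fit,
                targets_full[batch, :n_fit, :],
                flow=flow,
                n_sub=config.n_sub,
            )
            finite = np.isfinite(loss) and all(np.all(np.isfinite(g)) for g in grads.values())
            if not finite:
                # diverged solve: reject the step, fall back to the best known
                # parameters and restart the optimizer moments
                report.rejected_steps.append(step)
                report.steps.append(step)
                report.phases.append(phase)
                report.train_mse.append(float("nan"))
                correction = best
                opt = AdaBelief(config.learning_rate)
                continue
            correction = correction.with_parameters(opt.update(correction.parameters(), grads))
            report.steps.append(step)
            report.phases.append(phase)
            report.train_mse.append(loss)
            if val_data is not None and step % config.val_every == 0:
                v = _validation_mse(network, correction, val_data, flow, config.n_sub)
                report.val_steps.append(step)
                report.val_mse.append(v)
                if v < report.best_val_mse:
                    report.best_val_mse = v
                    report.best_step = step
                    best = correction
        report.phase_boundaries.append(step)
        if val_data is not None:
            v = _validation_mse(network, correction, val_data, flow, config.n_sub)
            report.val_steps.append(step)
            report.val_mse.append(v)
            if v < report.best_val_mse:
                report.best_val_mse = v
                report.best_step = step
                best = correction

    report.wall_time_s = _time.perf_counter() - t_start
    if val_data is None:
        best = correction
        report.best_step = step
    return best, report


def theory_only_mse(
    network: ReactionNetwork,
    data: TrainingData,
    flow: FlowConditions | None = None,
    n_sub: int = 4,
    max_series: int | None = None,
) -> float:
    """Masked MSE of the unaugmented mechanistic model on the same dataset."""
    sel = slice(0, max_series) if max_series else slice(None)
    system = AdjointSystem(network, None, flow)
    states, _, save_idx = rk4_trajectory(system, data.y0[sel], data.times, n_sub)
    pred = states[:, save_idx, :][:, :, data.measured_indices]
    return float(np.mean((pred - data.targets()[sel]) ** 2))
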