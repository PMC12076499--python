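"""Ground-truth simulation and noisy replicate measurements.

A :class:`Scenario` pairs the network that *generates* the data with the
(possibly ablated) network used for *modeling* it, so data/model mismatch —
the hidden-interaction construct — is expressed declaratively.  Measurements
emulate replicate experiments: each replicate adds i.i.d. Gaussian noise to
the true trajectory, and the emitted series carries the per-cell mean and
standard deviation across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .crn_model import (
    FlowConditions,
    ReactionNetwork,
    ablate_reaction,
    apply_flow,
    build_rhs,
    fmoc_oscillator,
    toy_flow_conditions,
    toy_initial_state,
)
from .node_core import SolverConfig, Trajectory, solve
from .training import MeasurementSeries

__all__ = [
    "Scenario",
    "simulate_ground_truth",
    "make_measurements",
    "hidden_interaction_scenario",
    "single_pulse_scenario",
    "oscillation_scenario",
]

#: Tight-tolerance solve used for all ground-truth generation.
GROUND_TRUTH_SOLVER = SolverConfig(method="Radau", rtol=1e-9, atol=1e-12)


@dataclass(frozen=True)
class Scenario:
    """A complete synthetic-experiment description.

    ``generating_network`` produces the data; ``modeling_network`` is what the
    analyst believes (identical unless a hidden interaction is emulated).
    ``noise_sd`` is an absolute per-species standard deviation (M); species
    not in ``measured_indices`` still appear in emitted series but with the
    noise they were assigned (typically 0).
    """

    generating_network: ReactionNetwork
    modeling_network: ReactionNetwork
    mode: str  # "batch" | "flow"
    y0: np.ndarray
    measurement_times: np.ndarray
    noise_sd: np.ndarray
    measured_indices: tuple[int, ...]
    flow: FlowConditions | None = None
    replicates: int = 2
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        object.__setattr__(self, "y0", np.asarray(self.y0, dtype=float))
        object.__setattr__(
            self, "measurement_times", np.asarray(self.measurement_times, dtype=float)
        )
        object.__setattr__(self, "noise_sd", np.asarray(self.noise_sd, dtype=float))
        if self.mode not in ("batch", "flow"):
            raise ValueError("mode must be 'batch' or 'flow'")
        if self.mode == "flow" and self.flow is None:
            raise ValueError("flow mode requires FlowConditions")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise sd must be >= 0")

    @property
    def measured_mask(self) -> np.ndarray:
        mask = np.zeros(self.generating_network.n_species, dtype=bool)
        mask[list(self.measured_indices)] = True
        return mask


def simulate_ground_truth(
    scenario: Scenario, config: SolverConfig = GROUND_TRUTH_SOLVER
) -> Trajectory:
    """Deterministic tight-tolerance solve of the generating network."""
    net = scenario.generating_network
    rhs = build_rhs(net)
    if scenario.mode == "flow":
        rhs = apply_flow(rhs, scenario.flow, net.constant_mask)
    return solve(
        rhs,
        scenario.y0,
        scenario.measurement_times,
        config,
        time_unit=net.time_unit,
        metadata={"model": net.name, "seed": scenario.seed, "mode": scenario.mode},
    )


def make_measurements(
    trajectory: Trajectory,
    noise_sd: np.ndarray | float,
    replicates: int,
    times: np.ndarray,
    seed: int,
    measured_mask: np.ndarray | None = None,
    species_names: Sequence[str] | None = None,
) -> MeasurementSeries:
    """Replicate noisy observations of a trajectory, summarized as mean/std.

    Each replicate is ``y(t, k) + Normal(0, sd_k)`` clipped at zero; the
    sample standard deviation (ddof=1) is taken across replicates, so with two
    replicates ``std = |r1 - r2| / sqrt(2)``.  Requested times must lie inside
    the trajectory's span; values are interpolated linearly between samples.
    """
    times = np.asarray(times, dtype=float)
    if times.min() < trajectory.times[0] or times.max() > trajectory.times[-1]:
        raise ValueError("requested measurement time outside the trajectory")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for a standard deviation")
    n_species = trajectory.n_species
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_species,))
    truth = np.column_stack(
        [np.interp(times, trajectory.times, trajectory.states[:, k]) for k in range(n_species)]
    )
    rng = np.random.default_rng(seed)
    reps = truth[None, :, :] + rng.normal(size=(replicates,) + truth.shape) * sd
    reps = np.clip(reps, 0.0, None)
    if measured_mask is None:
        measured_mask = np.ones(n_species, dtype=bool)
    if species_names is None:
        species_names = [f"species_{k + 1}" for k in range(n_species)]
    return MeasurementSeries(
        times=times,
        mean=reps.mean(axis=0),
        std=reps.std(axis=0, ddof=1),
        measured_mask=np.asarray(measured_mask, dtype=bool),
        species_names=tuple(species_names),
        time_unit=trajectory.time_unit,
    )


def scenario_measurements(scenario: Scenario) -> tuple[Trajectory, MeasurementSeries]:
    """Convenience: ground truth plus its replicate summary in one call."""
    traj = simulate_ground_truth(scenario)
    series = make_measurements(
        traj,
        scenario.noise_sd,
        scenario.replicates,
        scenario.measurement_times,
        scenario.seed,
        scenario.measured_mask,
        scenario.generating_network.names,
    )
    return traj, series


def hidden_interaction_scenario(
    base: Scenario,
    reaction_label: str | None,
    species: Sequence[int] | None = None,
) -> Scenario:
    """Derive a scenario whose modeling network lacks (part of) a reaction.

    The generating network stays complete; only the analyst's model is
    ablated.  ``reaction_label=None`` yields the null scenario (model equals
    generator).  ``species`` holds 1-based indices restricting the removal to
    selected species' equations.
    """
    if reaction_label is None:
        return replace(base, modeling_network=base.generating_network, name=f"{base.name}+null")
    modeling = ablate_reaction(base.generating_network, reaction_label, species)
    return replace(base, modeling_network=modeling, name=f"{base.name}-{reaction_label}")


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

#: Default four measured species of the pulse experiments (0-based positions):
#: piperidine, the fuel ester, dibenzofulvene and the acetylated product.
PULSE_MEASURED = (0, 1, 5, 6)


def single_pulse_scenario(
    noise_sd: float = 5e-4,
    n_times: int = 40,
    t_end: float = 4.0,
    seed: int = 0,
) -> Scenario:
    """Closed-reactor pulse of the toy oscillator chemistry.

    One shot of fuel and fast inhibitor burns through an autocatalytic burst
    and relaxes toward complete acetylation — an aperiodic series over a few
    hours, sampled uniformly.  Concentrations are kept small enough that the
    fast-inhibition mode stays well inside the stability region of the
    fixed-step training integrator at its default substep count.
    """
    net = fmoc_oscillator("toy_oscillator")
    y0 = np.zeros(net.n_species)
    y0[1] = 0.02  # fuel ester
    y0[2] = 0.005  # fast inhibitor
    y0[3] = 1.2  # slow inhibitor reservoir
    y0[4] = 0.2  # constant base catalyst
    sd = np.zeros(net.n_species)
    sd[list(PULSE_MEASURED)] = noise_sd
    return Scenario(
        generating_network=net,
        modeling_network=net,
        mode="batch",
        y0=y0,
        measurement_times=np.linspace(0.0, t_end, n_times),
        noise_sd=sd,
        measured_indices=PULSE_MEASURED,
        replicates=2,
        seed=seed,
        name="single_pulse",
    )


def injected_term_scenario(
    rate: float = 0.35,
    noise_sd: float = 2e-3,
    n_times: int = 40,
    t_end: float = 4.0,
    seed: int = 0,
) -> Scenario:
    """Pulse scenario whose data contain a term the analyst's model lacks.

    The generating network carries an extra uncatalyzed first-order
    deprotection of the fuel ester at the given rate (1/h); the modeling
    network is the plain toy chemistry.  The known injected derivative is
    ``rate * [fuel]`` on species 1 and 6 and its negative on species 2.
    """
    from .crn_model import Reaction

    base = single_pulse_scenario(noise_sd=noise_sd, n_times=n_times, t_end=t_end, seed=seed)
    net = base.generating_network
    extra = Reaction(
        "background_deprotection",
        reactants={2: 1},
        products={1: 1, 6: 1},
        rate_key="k_bg",
    )
    generating = replace(
        net,
        reactions=list(net.reactions) + [extra],
        kappa={**net.kappa, "k_bg": rate},
    )
    return replace(
        base,
        generating_network=generating,
        modeling_network=net,
        name="injected_term",
    )


def oscillation_scenario(
    noise_sd: float = 2e-3,
    n_times: int = 120,
    t_end: float = 60.0,
    seed: int = 0,
) -> Scenario:
    """Open-reactor (CSTR) scenario on the toy limit cycle."""
    net = fmoc_oscillator("toy_oscillator")
    sd = np.zeros(net.n_species)
    sd[list(PULSE_MEASURED)] = noise_sd
    return Scenario(
        generating_network=net,
        modeling_network=net,
        mode="flow",
        y0=toy_initial_state(),
        measurement_times=np.linspace(0.0, t_end, n_times),
        noise_sd=sd,
        measured_indices=PULSE_MEASURED,
        flow=toy_flow_conditions(),
        replicates=2,
        seed=seed,
        name="oscillation",
    )
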