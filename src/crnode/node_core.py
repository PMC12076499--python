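"""Neural correction term, augmented right-hand sides and stiff ODE solving.

The correction ``f_theta`` is a recurrent (LSTM-style) cell with a
32-dimensional hidden state followed by a single affine readout, evaluated
statelessly: hidden and cell state are zeroed at every call so the term is a
pure, memoryless function of the instantaneous concentrations — a requirement
for use inside adaptive step-size solvers, whose accept/reject sequence must
not leak into the dynamics.

The readout is zero-initialized, so a freshly created correction contributes
exactly nothing and the augmented model starts identical to the mechanistic
one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .crn_model import FlowConditions, ReactionNetwork, apply_flow, build_rhs

__all__ = [
    "NeuralCorrection",
    "SolverConfig",
    "Trajectory",
    "SolverFailure",
    "init_correction",
    "eval_correction",
    "augmented_rhs",
    "solve",
    "contribution_series",
    "save_correction",
    "load_correction",
    "lstm_parameter_count",
]

DEFAULT_HIDDEN_SIZE = 32


@dataclass(frozen=True)
class NeuralCorrection:
    """Parameters theta of the correction term and its input scaling.

    Weight layout (hidden size H, I/O width n): ``w_x (4H, n)`` input weights,
    ``w_h (4H, H)`` recurrence weights (carried for checkpoint fidelity; they
    multiply the zeroed hidden state), ``b (4H,)`` gate biases in i, f, g, o
    order, ``w_out (n, H)`` / ``b_out (n,)`` affine readout.  ``scale`` divides
    the inputs before the cell; the output is left in concentration/time units.
    """

    w_x: np.ndarray
    w_h: np.ndarray
    b: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    scale: np.ndarray
    measured_indices: tuple[int, ...]
    seed: int = 0

    @property
    def n_io(self) -> int:
        return self.w_x.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.w_h.shape[1]

    @property
    def n_parameters(self) -> int:
        return sum(
            a.size for a in (self.w_x, self.w_h, self.b, self.w_out, self.b_out)
        )

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "w_x": self.w_x,
            "w_h": self.w_h,
            "b": self.b,
            "w_out": self.w_out,
            "b_out": self.b_out,
        }

    def with_parameters(self, params: Mapping[str, np.ndarray]) -> "NeuralCorrection":
        return replace(self, **{k: np.asarray(v, dtype=float) for k, v in params.items()})

    def with_scale(self, scale: np.ndarray) -> "NeuralCorrection":
        scale = np.asarray(scale, dtype=float)
        if scale.shape != (self.n_io,) or np.any(scale <= 0):
            raise ValueError("scale must be positive with one entry per measured species")
        return replace(self, scale=scale)


def lstm_parameter_count(n_in: int, hidden: int) -> int:
    """Parameters of one LSTM cell (4 gates, one bias vector per gate)."""
    return 4 * hidden * (n_in + hidden) + 4 * hidden


def init_correction(
    n_io: int,
    hidden_size: int = DEFAULT_HIDDEN_SIZE,
    seed: int = 0,
    measured_indices: Sequence[int] | None = None,
) -> NeuralCorrection:
    """Create a correction with random gate weights and a zero readout.

    Zero-initializing ``w_out``/``b_out`` makes the initial correction
    identically zero, so training starts exactly at the mechanistic model.
    Gate weights use a uniform(-1/sqrt(H), 1/sqrt(H)) draw, reproducible per
    seed.
    """
    if n_io < 1:
        raise ValueError("n_io must be >= 1")
    rng = np.random.default_rng(seed)
    bound = 1.0 / np.sqrt(hidden_size)
    if measured_indices is None:
        measured_indices = tuple(range(n_io))
    measured_indices = tuple(int(i) for i in measured_indices)
    if len(measured_indices) != n_io:
        raise ValueError("measured_indices must have length n_io")
    return NeuralCorrection(
        w_x=rng.uniform(-bound, bound, size=(4 * hidden_size, n_io)),
        w_h=rng.uniform(-bound, bound, size=(4 * hidden_size, hidden_size)),
        b=rng.uniform(-bound, bound, size=4 * hidden_size),
        w_out=np.zeros((n_io, hidden_size)),
        b_out=np.zeros(n_io),
        scale=np.ones(n_io),
        measured_indices=measured_indices,
        seed=int(seed),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _cell_forward(c: NeuralCorrection, x: np.ndarray) -> dict[str, np.ndarray]:
    """One stateless cell evaluation; returns all intermediates for backprop.

    With hidden and cell state zeroed, the recurrence weights and the forget
    gate drop out of the forward pass algebraically.
    """
    H = c.hidden_size
    z = x @ c.w_x.T + c.b
    i = _sigmoid(z[..., 0 * H : 1 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = _sigmoid(z[..., 3 * H : 4 * H])
    cell = i * g
    tc = np.tanh(cell)
    h = o * tc
    out = h @ c.w_out.T + c.b_out
    return {"x": x, "i": i, "g": g, "o": o, "tc": tc, "h": h, "out": out}


def eval_correction(correction: NeuralCorrection, y: np.ndarray) -> np.ndarray:
    """f_theta(y): the learned time-derivative correction per measured species.

    ``y`` holds the measured-species concentrations, shape ``(..., n_io)``;
    evaluation is deterministic and stateless.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != correction.n_io:
        raise ValueError(f"expected {correction.n_io} inputs, got {y.shape[-1]}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to the neural correction")
    return _cell_forward(correction, y / correction.scale)["out"]


def correction_vjp(
    correction: NeuralCorrection, y: np.ndarray, upstream: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vector-Jacobian products of ``eval_correction`` w.r.t. input and theta.

    Returns ``(d/dy, {param: d/dparam})`` for upstream cotangent(s) of shape
    ``(..., n_io)``; batch axes are summed into the parameter gradients.
    """
    y = np.asarray(y, dtype=float)
    x = y / correction.scale
    f = _cell_forward(correction, x)
    H = correction.hidden_size
    dout = np.asarray(upstream, dtype=float)

    flat = lambda a: a.reshape(-1, a.shape[-1])
    d_w_out = flat(dout).T @ flat(f["h"])
    d_b_out = flat(dout).sum(axis=0)
    dh = dout @ correction.w_out

    do = dh * f["tc"]
    dcell = dh * f["o"] * (1.0 - f["tc"] ** 2)
    di = dcell * f["g"]
    dg = dcell * f["i"]

    dz = np.zeros(dout.shape[:-1] + (4 * H,))
    dz[..., 0 * H : 1 * H] = di * f["i"] * (1.0 - f["i"])
    dz[..., 2 * H : 3 * H] = dg * (1.0 - f["g"] ** 2)
    dz[..., 3 * H : 4 * H] = do * f["o"] * (1.0 - f["o"])

    d_w_x = flat(dz).T @ flat(x)
    d_b = flat(dz).sum(axis=0)
    dx = dz @ correction.w_x
    dy = dx / correction.scale
    grads = {
        "w_x": d_w_x,
        "w_h": np.zeros_like(correction.w_h),
        "b": d_b,
        "w_out": d_w_out,
        "b_out": d_b_out,
    }
    return dy, grads


def augmented_rhs(
    network: ReactionNetwork,
    correction: NeuralCorrection,
    flow: FlowConditions | None = None,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Mechanistic RHS plus the neural correction scattered onto measured species.

    Unmeasured and constant species keep their mechanistic derivative exactly.
    """
    idx = np.asarray(correction.measured_indices, dtype=int)
    if np.any(idx < 0) or np.any(idx >= network.n_species):
        raise ValueError("measured indices outside the network's species range")
    if np.any(network.constant_mask[idx]):
        raise ValueError("a constant species cannot receive a neural correction")
    base = build_rhs(network)
    if flow is not None:
        base = apply_flow(base, flow, network.constant_mask)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.array(base(t, y), dtype=float, copy=True)
        dy[..., idx] += eval_correction(correction, np.asarray(y)[..., idx])
        return dy

    return rhs


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Adaptive implicit solver settings.

    ``method`` is any stiff-capable scipy method name; the default Radau is a
    fifth-order implicit Runge-Kutta pair, the same family of stiffly accurate
    implicit RK schemes the problem calls for.
    """

    method: str = "Radau"
    rtol: float = 1e-6
    atol: float = 1e-8
    max_steps: int = 100_000
    first_step: float | None = None
    dense_output: bool = False

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be > 0")


class SolverFailure(RuntimeError):
    """The integrator gave up; carries the time at which it failed."""

    def __init__(self, message: str, t_failure: float):
        super().__init__(f"{message} (t = {t_failure:.6g})")
        self.t_failure = t_failure


@dataclass(frozen=True)
class Trajectory:
    """Solution samples: strictly increasing times and a time x species matrix."""

    times: np.ndarray
    states: np.ndarray
    time_unit: str = "h"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("states must have one row per time")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory states must be finite")

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    def species_column(self, index: int) -> np.ndarray:
        """Concentration series of a species by 0-based column."""
        return self.states[:, index]


def solve(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    save_times: np.ndarray,
    config: SolverConfig | None = None,
    time_unit: str = "h",
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate an IVP and sample it at ``save_times``.

    Raises :class:`SolverFailure` with the failure time if the integrator
    cannot complete.
    """
    config = config or SolverConfig()
    y0 = np.asarray(y0, dtype=float)
    save_times = np.asarray(save_times, dtype=float)
    if np.any(np.diff(save_times) <= 0):
        raise ValueError("save_times must be strictly increasing")
    t0 = float(save_times[0])
    t1 = float(save_times[-1])
    last_t = [t0]

    def tracked(t, y):
        last_t[0] = t
        return rhs(t, y)

    sol = solve_ivp(
        tracked,
        (t0, t1),
        y0,
        method=config.method,
        t_eval=save_times,
        rtol=config.rtol,
        atol=config.atol,
        first_step=config.first_step,
        dense_output=config.dense_output,
    )
    if not sol.success:
        raise SolverFailure(f"solver {config.method} failed: {sol.message}", last_t[0])
    meta = dict(metadata or {})
    meta.setdefault("solver", config.method)
    traj = Trajectory(
        times=sol.t, states=sol.y.T, time_unit=time_unit, metadata=meta
    )
    if config.dense_output:
        object.__setattr__(traj, "metadata", {**traj.metadata, "dense": sol.sol})
    return traj


def contribution_series(
    correction: NeuralCorrection,
    trajectory: Trajectory,
    network: ReactionNetwork | None = None,
) -> np.ndarray:
    """f_theta evaluated along a trajectory: one row per time, one column per
    measured species.

    Equivalently the residual between the augmented and mechanistic
    derivatives at each saved state; ``network`` is accepted for signature
    symmetry but the direct evaluation is exact by construction.
    """
    idx = np.asarray(correction.measured_indices, dtype=int)
    return eval_correction(correction, trajectory.states[:, idx])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_correction(correction: NeuralCorrection, path) -> None:
    """Write theta plus all metadata needed to rebuild the correction (JSON)."""
    doc = {
        "format_version": _CHECKPOINT_VERSION,
        "n_io": correction.n_io,
        "hidden_size": correction.hidden_size,
        "measured_indices": list(correction.measured_indices),
        "seed": correction.seed,
        "scale": correction.scale.tolist(),
        "parameters": {k: v.tolist() for k, v in correction.parameters().items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_correction(path) -> NeuralCorrection:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {doc.get('format_version')}")
    params = {k: np.asarray(v, dtype=float) for k, v in doc["parameters"].items()}
    return NeuralCorrection(
        w_x=params["w_x"],
        w_h=params["w_h"],
        b=params["b"],
        w_out=params["w_out"],
        b_out=params["b_out"],
        scale=np.asarray(doc["scale"], dtype=float),
        measured_indices=tuple(doc["measured_indices"]),
        seed=int(doc["seed"]),
    )
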