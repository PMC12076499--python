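"""Differentiable fixed-step integration for training the neural correction.

Adaptive implicit solvers (see :mod:`crnode.node_core`) are used for
simulation and analysis; gradients for training instead flow through a
classical fixed-step RK4 discretization whose adjoint is derived by hand.
Backpropagating through the discrete solve (discretize-then-optimize) gives
the exact gradient of the computed loss, is deterministic, and vectorizes
over a batch of sampled series — all at the cost of the caller choosing a
step count fine enough for the dynamics at hand.

All vector-Jacobian products (mass action, CSTR balance, the recurrent
correction cell) are analytic; no finite differences are involved.
"""

from __future__ import annotations



import numpy as np

from .crn_model import FlowConditions, ReactionNetwork
from .node_core import NeuralCorrection, _cell_forward, correction_vjp

__all__ = ["AdjointSystem", "rk4_trajectory", "mse_loss_and_grad"]


class AdjointSystem:
    """Batched RHS evaluation plus analytic VJPs w.r.t. state, theta and kappa."""

    def __init__(
        self,
        network: ReactionNetwork,
        correction: NeuralCorrection | None = None,
        flow: FlowConditions | None = None,
    ):
        self.network = network
        self.correction = correction
        self.k = network.rate_vector()
        self.E = network.exponent_matrix()
        self.S_eff = network.stoichiometric_matrix(effective=True)
        self.rate_keys = [r.rate_key for r in network.reactions]
        self.active = ~network.constant_mask
        if flow is not None:
            self.D = float(flow.dilution_rate)
            self.y_in = np.asarray(flow.inflow, dtype=float)
        else:
            self.D = 0.0
            self.y_in = None
        self.idx = (
            np.asarray(correction.measured_indices, dtype=int)
            if correction is not None
            else None
        )
        # d(monomial_j)/dy_s needs prod_s' y^(E[j, s'] - [s == s']); precompute
        # the exponent tensor and the (j, s) entries where the derivative is
        # structurally nonzero
        R, S = self.E.shape
        self._dE = self.E[:, None, :] - np.eye(S)[None, :, :]
        self._dmask = self.E > 0  # (R, S)

    # -- forward -----------------------------------------------------------

    def _monomials(self, y: np.ndarray) -> np.ndarray:
        base = y[..., None, :]
        if not np.all(self.E == np.round(self.E)):
            base = np.clip(base, 0.0, None)
        return np.prod(np.power(base, self.E), axis=-1)

    def f(self, y: np.ndarray) -> np.ndarray:
        # NaN/overflow is allowed to propagate here: a diverged training solve
        # surfaces as a non-finite loss and the step is rejected upstream
        with np.errstate(all="ignore"):
            v = self.k * self._monomials(y)
            dy = v @ self.S_eff.T
            if self.y_in is not None:
                dy += self.active * (self.D * (self.y_in - y))
            if self.correction is not None:
                c = self.correction
                out = _cell_forward(c, y[..., self.idx] / c.scale)["out"]
                dy[..., self.idx] += out
        return dy

    # -- reverse -----------------------------------------------------------

    def vjp(
        self,
        y: np.ndarray,
        lam: np.ndarray,
        theta_grads: dict[str, np.ndarray] | None,
        kappa_grad: dict[str, float] | None,
    ) -> np.ndarray:
        """lam^T dF/dy, accumulating lam^T dF/dtheta and lam^T dF/dkappa in place."""
        w = lam @ self.S_eff  # (..., n_reactions): weight on each rate
        with np.errstate(all="ignore"):
            mono = self._monomials(y)
            if kappa_grad is not None:
                contrib = w * mono  # (..., R)
                for j, key in enumerate(self.rate_keys):
                    kappa_grad[key] += float(np.sum(contrib[..., j]))
            # dmono (..., R, S); entries with zero exponent are structurally 0
            # (computed defensively: y = 0 with E - 1 < 0 would otherwise give inf)
            base = y[..., None, None, :]
            dmono = self.E * np.prod(np.power(base, self._dE), axis=-1)
            dmono = np.where(self._dmask, dmono, 0.0)
            ybar = np.einsum("...j,j,...js->...s", w, self.k, dmono)
        if self.y_in is not None:
            ybar -= self.D * (lam * self.active)
        if self.correction is not None:
            dy_m, grads = correction_vjp(self.correction, y[..., self.idx], lam[..., self.idx])
            ybar[..., self.idx] += dy_m
            if theta_grads is not None:
                for key, g in grads.items():
                    theta_grads[key] += g
        return ybar


def _substep_grid(times: np.ndarray, n_sub: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly refine each save interval into ``n_sub`` RK4 steps."""
    nodes = [np.asarray(times[:1], dtype=float)]
    for a, b in zip(times[:-1], times[1:]):
        nodes.append(np.linspace(a, b, n_sub + 1)[1:])
    grid = np.concatenate(nodes)
    save_idx = np.arange(0, grid.size, n_sub)
    return grid, save_idx


def rk4_trajectory(
    system: AdjointSystem, y0: np.ndarray, times: np.ndarray, n_sub: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4 solve storing every substep node.

    Returns ``(node_states (..., n_nodes, n_species), node_times, save_idx)``
    where ``save_idx`` addresses the requested ``times`` within the nodes.
    """
    grid, save_idx = _substep_grid(np.asarray(times, dtype=float), n_sub)
    y = np.asarray(y0, dtype=float)
    states = np.empty(y.shape[:-1] + (grid.size, y.shape[-1]))
    states[..., 0, :] = y
    for m in range(grid.size - 1):
        h = grid[m + 1] - grid[m]
        k1 = system.f(y)
        k2 = system.f(y + 0.5 * h * k1)
        k3 = system.f(y + 0.5 * h * k2)
        k4 = system.f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        states[..., m + 1, :] = y
    return states, grid, save_idx


def _rk4_step_backward(
    system: AdjointSystem,
    y: np.ndarray,
    h: float,
    g_next: np.ndarray,
    theta_grads: dict[str, np.ndarray] | None,
    kappa_grad: dict[str, float] | None,
) -> np.ndarray:
    """Adjoint of one RK4 step, recomputing the stage states from ``y``."""
    k1 = system.f(y)
    u2 = y + 0.5 * h * k1
    k2 = system.f(u2)
    u3 = y + 0.5 * h * k2
    u4 = y + h * system.f(u3)

    gy = g_next.copy()
    gk1 = (h / 6.0) * g_next
    gk2 = (h / 3.0) * g_next
    gk3 = (h / 3.0) * g_next
    gk4 = (h / 6.0) * g_next

    du4 = system.vjp(u4, gk4, theta_grads, kappa_grad)
    gy += du4
    gk3 = gk3 + h * du4

    du3 = system.vjp(u3, gk3, theta_grads, kappa_grad)
    gy += du3
    gk2 = gk2 + 0.5 * h * du3

    du2 = system.vjp(u2, gk2, theta_grads, kappa_grad)
    gy += du2
    gk1 = gk1 + 0.5 * h * du2

    gy += system.vjp(y, gk1, theta_grads, kappa_grad)
    return gy


def mse_loss_and_grad(
    network: ReactionNetwork,
    correction: NeuralCorrection,
    y0: np.ndarray,
    times: np.ndarray,
    targets: np.ndarray,
    flow: FlowConditions | None = None,
    n_sub: int = 4,
    with_kappa: bool = False,
) -> tuple[float, dict[str, np.ndarray], dict[str, float] | None]:
    """Masked-MSE loss of the augmented solve against targets, with gradients.

    ``y0`` is ``(batch, n_species)`` (a single series may be passed as shape
    ``(n_species,)``), ``targets`` is ``(batch, n_times, n_measured)`` aligned
    with ``times`` and the correction's measured species.  The returned loss
    is the mean squared error over batch, time and measured species; gradients
    are exact for the RK4-discretized solve.
    """
    y0 = np.atleast_2d(np.asarray(y0, dtype=float))
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 2:
        targets = targets[None, ...]
    system = AdjointSystem(network, correction, flow)
    idx = system.idx
    with np.errstate(all="ignore"):
        states, grid, save_idx = rk4_trajectory(system, y0, times, n_sub)
        pred = states[:, save_idx, :][:, :, idx]
        resid = pred - targets
        loss = float(np.mean(resid**2))
    if not np.isfinite(loss):
        # diverged solve; report it without walking the adjoint through infs
        nan_grads = {k: np.full_like(v, np.nan) for k, v in correction.parameters().items()}
        return loss, nan_grads, ({key: np.nan for key in network.kappa} if with_kappa else None)

    theta_grads = {k: np.zeros_like(v) for k, v in correction.parameters().items()}
    kappa_grad: dict[str, float] | None = (
        {key: 0.0 for key in network.kappa} if with_kappa else None
    )
    cot = np.zeros((y0.shape[0], len(times), y0.shape[1]))
    cot[:, :, idx] = 2.0 * resid / resid.size

    save_set = {int(m): t for t, m in enumerate(save_idx)}
    g = cot[:, save_set[int(save_idx[-1])], :].copy()
    with np.errstate(all="ignore"):
        for m in range(grid.size - 2, -1, -1):
            h = grid[m + 1] - grid[m]
            g = _rk4_step_backward(system, states[:, m, :], h, g, theta_grads, kappa_grad)
            if m in save_set:
                g += cot[:, save_set[m], :]
    return loss, theta_grads, kappa_grad
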