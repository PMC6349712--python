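"""Parameter identification by RMSprop gradient descent.

The unknowns are P = (A, tau_out[.], tau_close[.], tau[.]) in R^{1+3*N_H}:
one global amplitude plus three distributed fields.  The cost is the
mean-centered least squares misfit between simulated and target body-surface
recordings,

    J(P) = 1/2 sum_k sum_j [ (phi_T(y_j,t_k) - mean_j phi_T(t_k))
                           - (phi*(y_j,t_k) - mean_j phi*(t_k)) ]^2,

whose per-time electrode-mean subtraction removes the reference-potential
freedom of both signals.  The gradient is assembled analytically by the
chain rule through the (linear) electrode centering, the transfer matrix,
the node-mean extracellular map and the ansatz partial derivatives; updates
use RMSprop with a per-iteration learning-rate search on a fixed log grid.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field

import numpy as np

from .ap import MSParameters
from .forward import BodySurfaceRecording, _forward_eval, build_transfer
from .mesh import ElectrodeSet, SurfaceMesh

__all__ = [
    "TAU_OUT_MIN",
    "TAU_CLOSE_MIN",
    "ParameterField",
    "OptimizerState",
    "StoppingRule",
    "InverseDiagnostics",
    "cost",
    "cost_and_gradient",
    "cost_gradient",
    "rmsprop_update",
    "select_learning_rate",
    "default_eta_grid",
    "solve_inverse",
]

TAU_OUT_MIN = 0.5  # ms, lower clip for the repolarization-speed constant
TAU_CLOSE_MIN = 10.0  # ms, lower clip for the plateau-duration constant


@dataclass
class ParameterField:
    """The unknown vector: global A plus distributed tau_out/tau_close/tau.

    Packing order into R^{1+3N}: [A, tau_out[0..N), tau_close[0..N), tau[0..N)].
    """

    A: float
    tau_out: np.ndarray
    tau_close: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.tau_out = np.asarray(self.tau_out, dtype=float).ravel()
        self.tau_close = np.asarray(self.tau_close, dtype=float).ravel()
        self.tau = np.asarray(self.tau, dtype=float).ravel()
        n = self.tau.size
        if self.tau_out.size != n or self.tau_close.size != n:
            raise ValueError("tau_out, tau_close and tau must have equal length")

    @property
    def n_nodes(self) -> int:
        return self.tau.size

    @classmethod
    def default_init(cls, n_nodes: int, tau0: float = 60.0) -> "ParameterField":
        """The standard initial guess: A=10, tau_out=6 ms, tau_close=150 ms,
        constant activation tau0.  Uniform over nodes, so the initial torso
        potentials vanish identically."""
        return cls(
            A=10.0,
            tau_out=np.full(n_nodes, 6.0),
            tau_close=np.full(n_nodes, 150.0),
            tau=np.full(n_nodes, float(tau0)),
        )

    def pack(self) -> np.ndarray:
        return np.concatenate([[self.A], self.tau_out, self.tau_close, self.tau])

    @classmethod
    def unpack(cls, vector: np.ndarray, n_nodes: int) -> "ParameterField":
        vector = np.asarray(vector, dtype=float).ravel()
        if vector.size != 1 + 3 * n_nodes:
            raise ValueError(
                f"vector length {vector.size} != 1 + 3*{n_nodes}"
            )
        return cls(
            A=float(vector[0]),
            tau_out=vector[1:1 + n_nodes].copy(),
            tau_close=vector[1 + n_nodes:1 + 2 * n_nodes].copy(),
            tau=vector[1 + 2 * n_nodes:].copy(),
        )

    def copy(self) -> "ParameterField":
        return ParameterField(self.A, self.tau_out.copy(), self.tau_close.copy(),
                              self.tau.copy())


def clip_packed(vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Enforce tau_out >= 0.5 ms and tau_close >= 10 ms on a packed vector."""
    out = vector.copy()
    out[1:1 + n_nodes] = np.maximum(out[1:1 + n_nodes], TAU_OUT_MIN)
    out[1 + n_nodes:1 + 2 * n_nodes] = np.maximum(
        out[1 + n_nodes:1 + 2 * n_nodes], TAU_CLOSE_MIN
    )
    return out


@dataclass
class OptimizerState:
    """RMSprop state: packed parameters, accumulator and bookkeeping."""

    P: np.ndarray
    kappa: np.ndarray
    eta: float = 0.0
    gamma: float = 0.9
    epsilon: float = 1e-7
    iteration: int = 0
    J_history: list = dc_field(default_factory=list)


@dataclass
class StoppingRule:
    """Stop when J flattens (relative change below tolerance for a window of
    consecutive iterations) or at max_iterations."""

    max_iterations: int = 500
    flat_tolerance: float = 1e-6
    flat_window: int = 10

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.flat_tolerance <= 0:
            raise ValueError("flat_tolerance must be positive")


@dataclass
class InverseDiagnostics:
    j_history: np.ndarray
    grad_norm_history: np.ndarray
    eta_history: np.ndarray
    n_iterations: int
    wall_time_s: float
    converged: bool

    def to_csv(self, path) -> None:
        n = len(self.eta_history)
        rows = np.column_stack(
            [np.arange(n), self.j_history[1:n + 1], self.grad_norm_history[:n],
             self.eta_history]
        )
        np.savetxt(path, rows, delimiter=",", fmt="%.17g",
                   header="iteration,J,grad_norm,eta", comments="")


# ---------------------------------------------------------------------------
# cost and gradient
# ---------------------------------------------------------------------------

def _check_target(target: BodySurfaceRecording, electrodes: ElectrodeSet) -> None:
    if target.n_electrodes != electrodes.n_electrodes:
        raise ValueError(
            f"target has {target.n_electrodes} electrodes but the electrode set "
            f"has {electrodes.n_electrodes}"
        )


def _centered_residual(phi: np.ndarray, target_phi: np.ndarray) -> np.ndarray:
    return (phi - phi.mean(axis=0)) - (target_phi - target_phi.mean(axis=0))


def cost(
    field: ParameterField,
    target: BodySurfaceRecording,
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet,
    transfer: np.ndarray | None = None,
    dt_template: float = 0.05,
    params: MSParameters | None = None,
) -> float:
    """Mean-centered least-squares misfit J >= 0."""
    _check_target(target, electrodes)
    rec, _ = _forward_eval(mesh, electrodes, field, target.times, transfer,
                           dt_template, params)
    r = _centered_residual(rec.phi, target.phi)
    return 0.5 * float(np.sum(r * r))


def cost_and_gradient(
    field: ParameterField,
    target: BodySurfaceRecording,
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet,
    transfer: np.ndarray | None = None,
    dt_template: float = 0.05,
    params: MSParameters | None = None,
) -> tuple[float, np.ndarray]:
    """J and its analytic gradient in packing order [A, tau_out, tau_close, tau].

    Backpropagation chain: residual -> electrode centering (I - 11^T/N_T,
    symmetric) -> transfer transpose -> node centering (11^T/N_H - I,
    symmetric) -> ansatz partials per node.
    """
    _check_target(target, electrodes)
    rec, aux = _forward_eval(mesh, electrodes, field, target.times, transfer,
                             dt_template, params, with_sens=True)
    r = _centered_residual(rec.phi, target.phi)
    J = 0.5 * float(np.sum(r * r))

    w = r - r.mean(axis=0)  # dJ/dphi_T
    q = aux["transfer"].T @ w  # dJ/dphi_e
    g_vm = q.mean(axis=0) - q  # dJ/dVm, shape (N_H, T)

    A = float(field.A)
    g_A = float(np.sum(g_vm * aux["v_eval"]))
    g_tau = np.sum(g_vm * (-A * aux["slope_eval"]), axis=1)
    g_tau_out = np.sum(g_vm * (A * aux["s_out_eval"]), axis=1)
    g_tau_close = np.sum(g_vm * (A * aux["s_close_eval"]), axis=1)
    grad = np.concatenate([[g_A], g_tau_out, g_tau_close, g_tau])
    return J, grad


def cost_gradient(*args, **kwargs) -> np.ndarray:
    """Gradient only; see :func:`cost_and_gradient`."""
    return cost_and_gradient(*args, **kwargs)[1]


# ---------------------------------------------------------------------------
# RMSprop
# ---------------------------------------------------------------------------

def rmsprop_update(
    state: OptimizerState, gradient: np.ndarray, eta: float, n_nodes: int | None = None
) -> OptimizerState:
    """One RMSprop step (all operations elementwise)::

        kappa <- gamma*kappa + (1-gamma) * g (.) g
        P     <- P - eta * g (/) (kappa^(1/2) + epsilon)

    followed by clipping tau_out/tau_close to their lower bounds when
    ``n_nodes`` is given.
    """
    g = np.asarray(gradient, dtype=float)
    if g.shape != state.P.shape:
        raise ValueError("gradient shape mismatch")
    kappa = state.gamma * state.kappa + (1.0 - state.gamma) * g * g
    P = state.P - eta * g / (np.sqrt(kappa) + state.epsilon)
    if n_nodes is not None:
        P = clip_packed(P, n_nodes)
    return OptimizerState(
        P=P,
        kappa=kappa,
        eta=eta,
        gamma=state.gamma,
        epsilon=state.epsilon,
        iteration=state.iteration + 1,
        J_history=state.J_history,
    )


def default_eta_grid(n_points: int = 15) -> np.ndarray:
    """Log-spaced learning-rate candidates spanning [1e-5, 1e2]."""
    return np.geomspace(1e-5, 1e2, n_points)


def select_learning_rate(
    state: OptimizerState,
    gradient: np.ndarray,
    cost_evaluator,
    eta_grid: np.ndarray | None = None,
    n_nodes: int | None = None,
) -> float:
    """Pick the eta on the grid whose tentative update minimizes J.

    ``cost_evaluator`` maps a packed parameter vector to J.  Ties break to
    the smaller eta; the best candidate is returned even if every candidate
    raises J (plain RMSprop behavior would take a fixed step regardless).
    """
    grid = default_eta_grid() if eta_grid is None else np.asarray(eta_grid)
    g = np.asarray(gradient, dtype=float)
    kappa = state.gamma * state.kappa + (1.0 - state.gamma) * g * g
    denom = np.sqrt(kappa) + state.epsilon
    costs = np.empty(grid.size)
    for m, eta in enumerate(grid):
        P = state.P - eta * g / denom
        if n_nodes is not None:
            P = clip_packed(P, n_nodes)
        costs[m] = cost_evaluator(P)
    return float(grid[int(np.argmin(costs))])


# ---------------------------------------------------------------------------
# full solve
# ---------------------------------------------------------------------------

def solve_inverse(
    target: BodySurfaceRecording,
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet,
    init: ParameterField | None = None,
    stop: StoppingRule | None = None,
    tau0: float = 60.0,
    eta_grid: np.ndarray | None = None,
    dt_template: float = 0.05,
    params: MSParameters | None = None,
    callback=None,
) -> tuple[ParameterField, InverseDiagnostics]:
    """Identify (A, tau_out, tau_close, tau) from a body-surface recording.

    Iterates {analytic gradient -> learning-rate grid search -> RMSprop
    update} from the default uniform initial guess (or ``init``) until the
    cost flattens or ``stop.max_iterations`` is reached.
    """
    _check_target(target, electrodes)
    stop = stop or StoppingRule()
    n = mesh.n_vertices
    field = init.copy() if init is not None else ParameterField.default_init(n, tau0)
    transfer = build_transfer(mesh, electrodes)
    grid = default_eta_grid() if eta_grid is None else np.asarray(eta_grid)

    def J_of(P_vec: np.ndarray) -> float:
        return cost(ParameterField.unpack(P_vec, n), target, mesh, electrodes,
                    transfer, dt_template, params)

    t0 = time.perf_counter()
    state = OptimizerState(P=clip_packed(field.pack(), n), kappa=np.zeros(1 + 3 * n))
    J = J_of(state.P)
    j_hist = [J]
    g_hist: list[float] = []
    eta_hist: list[float] = []
    converged = False
    flat = 0
    for _ in range(stop.max_iterations):
        J, grad = cost_and_gradient(
            ParameterField.unpack(state.P, n), target, mesh, electrodes,
            transfer, dt_template, params,
        )
        if not np.isfinite(J) or not np.all(np.isfinite(grad)):
            raise RuntimeError(
                f"non-finite cost or gradient at iteration {state.iteration}; "
                f"J={J}, |grad|_max={np.abs(grad).max() if grad.size else 'n/a'}"
            )
        gnorm = float(np.linalg.norm(grad))
        g_hist.append(gnorm)
        if J <= 0.0 or gnorm == 0.0:
            converged = True
            break
        eta = select_learning_rate(state, grad, J_of, grid, n_nodes=n)
        state = rmsprop_update(state, grad, eta, n_nodes=n)
        J_new = J_of(state.P)
        eta_hist.append(eta)
        j_hist.append(J_new)
        if callback is not None:
            callback(state.iteration, J_new, gnorm, eta)
        if abs(J_new - J) / max(J, 1e-300) < stop.flat_tolerance:
            flat += 1
            if flat >= stop.flat_window:
                converged = True
                break
        else:
            flat = 0

    diag = InverseDiagnostics(
        j_history=np.asarray(j_hist),
        grad_norm_history=np.asarray(g_hist),
        eta_history=np.asarray(eta_hist),
        n_iterations=state.iteration,
        wall_time_s=time.perf_counter() - t0,
        converged=converged,
    )
    return ParameterField.unpack(state.P, n), diag
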