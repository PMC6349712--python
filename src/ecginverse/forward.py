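"""Forward model: transmembrane voltages -> extracellular -> body surface.

The node-wise transmembrane voltage Vm(x_i, t) is first mapped to an
extracellular potential by subtracting it from its unweighted spatial mean
over all heart-surface vertices,

    phi_e(x_i, t) = (1/N_H) sum_k Vm(x_k, t) - Vm(x_i, t),

and then projected to the electrodes through the infinite homogeneous
medium kernel

    phi_T(y_j, t) = sum_i  phi_e(x_i, t) / (4 pi ||x_i - y_j||).

Potentials carry arbitrary units: the conductivity ratios of the underlying
bidomain reduction are folded into the global amplitude A of the ansatz.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from ._kernels import rk4_forward, rk4_forward_sens
from .ap import MSParameters, interp_with_slope
from .mesh import ElectrodeSet, SurfaceMesh

__all__ = [
    "build_transfer",
    "HeartPotentialSet",
    "BodySurfaceRecording",
    "vm_to_extracellular",
    "extracellular_to_body",
    "simulate_bspm",
    "read_recording_csv",
]


@dataclass
class HeartPotentialSet:
    """Extracellular potentials on the heart surface plus the Vm spatial mean."""

    phi_e: np.ndarray  # (N_H, T)
    vm_mean: np.ndarray  # (T,)


@dataclass
class BodySurfaceRecording:
    """Electrode-by-time potential matrix on a uniform ms grid."""

    phi: np.ndarray  # (N_T, T)
    times: np.ndarray  # (T,) ms, strictly increasing

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size < 2:
            raise ValueError("a recording needs at least 2 time samples")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if self.phi.shape[1] != self.times.size:
            raise ValueError(
                f"phi has {self.phi.shape[1]} samples but times has {self.times.size}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.phi.shape[0]

    def to_csv(self, path) -> None:
        """First row = times (ms); following rows = one electrode each."""
        np.savetxt(path, np.vstack([self.times, self.phi]), delimiter=",", fmt="%.17g")

    def to_npz(self, path) -> None:
        np.savez(path, phi=self.phi, times=self.times)


def read_recording_csv(path) -> BodySurfaceRecording:
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return BodySurfaceRecording(phi=data[1:], times=data[0])


def read_recording_npz(path) -> BodySurfaceRecording:
    with np.load(path) as z:
        return BodySurfaceRecording(phi=z["phi"], times=z["times"])


def build_transfer(mesh: SurfaceMesh, electrodes: ElectrodeSet) -> np.ndarray:
    """Transfer matrix T[j, i] = 1 / (4 pi ||x_i - y_j||), shape (N_T, N_H)."""
    d = cdist(electrodes.positions, mesh.vertices)
    if (d == 0).any():
        j, i = np.argwhere(d == 0)[0]
        raise ValueError(f"electrode {j} coincides with mesh vertex {i}")
    return 1.0 / (4.0 * np.pi * d)


def vm_to_extracellular(vm: np.ndarray) -> HeartPotentialSet:
    """phi_e = mean_over_nodes(Vm) - Vm; columns of phi_e sum to zero."""
    vm = np.atleast_2d(np.asarray(vm, dtype=float))
    vm_mean = vm.mean(axis=0)
    return HeartPotentialSet(phi_e=vm_mean[None, :] - vm, vm_mean=vm_mean)


def extracellular_to_body(
    hp: HeartPotentialSet, transfer: np.ndarray, times: np.ndarray
) -> BodySurfaceRecording:
    """Project heart-surface potentials to the electrodes (linear map)."""
    if transfer.shape[1] != hp.phi_e.shape[0]:
        raise ValueError(
            f"transfer expects {transfer.shape[1]} nodes, phi_e has {hp.phi_e.shape[0]}"
        )
    return BodySurfaceRecording(phi=transfer @ hp.phi_e, times=times)


# ---------------------------------------------------------------------------
# ansatz-driven simulation
# ---------------------------------------------------------------------------

_PAIR_DECIMALS = 6  # template dedup resolution, ms


def _template_duration(times: np.ndarray, tau: np.ndarray) -> float:
    """Template span: covers max(t) - min(tau, 0), rounded up to 50 ms chunks."""
    need = float(np.max(times)) - min(0.0, float(np.min(tau)))
    return max(50.0, 50.0 * np.ceil(need / 50.0))


def _forward_eval(
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet | None,
    field,
    times: np.ndarray,
    transfer: np.ndarray | None = None,
    dt_template: float = 0.05,
    params: MSParameters | None = None,
    with_sens: bool = False,
):
    """Simulate the BSPM and return the per-node evaluation products.

    ``field`` needs attributes A (scalar), tau_out, tau_close, tau (each a
    scalar or length-N_H array).  Unique (tau_out, tau_close) pairs, rounded
    to 1e-6 ms, are integrated once as an ensemble and shared between nodes.
    """
    params = params or MSParameters()
    n = mesh.n_vertices
    times = np.asarray(times, dtype=float)
    tau_out = np.broadcast_to(np.asarray(field.tau_out, dtype=float), (n,))
    tau_close = np.broadcast_to(np.asarray(field.tau_close, dtype=float), (n,))
    tau = np.broadcast_to(np.asarray(field.tau, dtype=float), (n,))
    A = float(field.A)

    pairs = np.column_stack(
        [np.round(tau_out, _PAIR_DECIMALS), np.round(tau_close, _PAIR_DECIMALS)]
    )
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    duration = _template_duration(times, tau)
    n_steps = int(round(duration / dt_template))
    args = (
        np.ascontiguousarray(uniq[:, 0]),
        np.ascontiguousarray(uniq[:, 1]),
        params.tau_in,
        params.tau_open,
        params.v_gate,
        0.15,
        1.0,
        dt_template,
        n_steps,
    )
    if with_sens:
        V, _, SVO, _, SVC, _ = rk4_forward_sens(*args)
    else:
        V, _ = rk4_forward(*args)
        SVO = SVC = None
    tgrid = np.arange(n_steps + 1) * dt_template

    t_len = times.size
    v_eval = np.empty((n, t_len))
    slope_eval = np.empty((n, t_len))
    s_out_eval = np.empty((n, t_len)) if with_sens else None
    s_close_eval = np.empty((n, t_len)) if with_sens else None
    for i in range(n):
        s = times - tau[i]
        row = inv[i]
        v_eval[i], slope_eval[i] = interp_with_slope(tgrid, V[row], s)
        if with_sens:
            s_out_eval[i], _ = interp_with_slope(tgrid, SVO[row], s)
            s_close_eval[i], _ = interp_with_slope(tgrid, SVC[row], s)

    vm = A * v_eval
    hp = vm_to_extracellular(vm)
    if transfer is None:
        if electrodes is None:
            raise ValueError("either electrodes or a transfer matrix is required")
        transfer = build_transfer(mesh, electrodes)
    recording = extracellular_to_body(hp, transfer, times)
    aux = {
        "vm": vm,
        "phi_e": hp,
        "v_eval": v_eval,
        "slope_eval": slope_eval,
        "s_out_eval": s_out_eval,
        "s_close_eval": s_close_eval,
        "transfer": transfer,
    }
    return recording, aux


def simulate_bspm(
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet,
    field,
    times: np.ndarray,
    transfer: np.ndarray | None = None,
    dt_template: float = 0.05,
    params: MSParameters | None = None,
) -> BodySurfaceRecording:
    """Forward-simulate the body-surface recording for a parameter field.

    Composition of the ansatz Vm(x_i, t) = A v(t - tau_i), the node-mean
    extracellular map and the 1/(4 pi r) electrode projection.
    """
    recording, _ = _forward_eval(
        mesh, electrodes, field, times, transfer, dt_template, params
    )
    return recording
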