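"""Synthetic ground-truth scenarios: pacing, parameter fields, recordings.

Monodomain reaction-diffusion data are emulated at desk scale: activation
spreads geodesically from the pacing sites at a constant conduction
velocity, the repolarization parameters vary smoothly with endo-epi and
apex-base gradients plus spatially smoothed noise, and the recording is the
package's own forward projection with optional additive Gaussian noise and
optional model mismatch (a refined generating mesh, or a generating
template with perturbed fixed constants) to break the inverse crime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .ap import MSParameters
from .evaluation import extract_repolarization_times
from .forward import BodySurfaceRecording, _forward_eval
from .inverse import ParameterField
from .mesh import ENDO, ElectrodeSet, SurfaceMesh, subdivide

__all__ = [
    "FieldSpec",
    "Scenario",
    "GroundTruth",
    "make_activation_map",
    "make_parameter_fields",
    "synthesize_recording",
]

TAU_OUT_RANGE = (2.0, 20.0)  # ms, physiological bounds for generated fields
TAU_CLOSE_RANGE = (50.0, 300.0)  # ms


@dataclass
class FieldSpec:
    """Base values plus gradient/noise amplitudes for the generated fields.

    ``d_*_endo_epi`` is added on ENDO vertices; ``d_*_apex_base`` scales with
    the normalized apex height (0 at the apex, 1 at the base).  Noise is
    vertex-wise Gaussian smoothed by ``smoothing_rounds`` rounds of 1-ring
    averaging.
    """

    A: float = 10.0
    tau_out_base: float = 6.0
    tau_close_base: float = 150.0
    d_tau_close_endo_epi: float = 0.0  # ms
    d_tau_close_apex_base: float = 0.0  # ms
    d_tau_out_endo_epi: float = 0.0
    d_tau_out_apex_base: float = 0.0
    noise_tau_close: float = 0.0  # ms std before smoothing
    noise_tau_out: float = 0.0
    smoothing_rounds: int = 3


@dataclass
class Scenario:
    """One synthetic validation case."""

    pacing: list  # [(vertex index, onset ms), ...]
    conduction_velocity: float = 0.6  # mm/ms
    field_spec: FieldSpec = dc_field(default_factory=FieldSpec)
    noise_snr_db: float | None = None
    mismatch: str = "none"  # none | refined-mesh | perturbed-template
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conduction_velocity <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.mismatch not in ("none", "refined-mesh", "perturbed-template"):
            raise ValueError(f"unknown mismatch mode {self.mismatch!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class GroundTruth:
    """Reference values accompanying a synthetic recording."""

    tau: np.ndarray  # per-vertex activation times, ms
    field: ParameterField
    rt: np.ndarray  # per-vertex reference repolarization times, ms


def make_activation_map(mesh: SurfaceMesh, pacing, cv: float) -> np.ndarray:
    """tau_i = min over sites (onset + geodesic(site, i) / cv), ms."""
    if cv <= 0:
        raise ValueError("conduction velocity must be positive")
    sites = [int(s) for s, _ in pacing]
    onsets = np.array([float(o) for _, o in pacing])
    for s in sites:
        if not 0 <= s < mesh.n_vertices:
            raise IndexError(f"pacing vertex {s} out of range")
    d = dijkstra(mesh.edge_graph(), directed=False, indices=sites)
    d = np.atleast_2d(d)
    tau = (onsets[:, None] + d / cv).min(axis=0)
    if not np.isfinite(tau).all():
        raise ValueError(
            f"vertices unreachable from all pacing sites: "
            f"{np.flatnonzero(~np.isfinite(tau)).tolist()}"
        )
    return tau


def _smooth(mesh: SurfaceMesh, x: np.ndarray, rounds: int) -> np.ndarray:
    """Replace each value by the mean over the vertex and its 1-ring, k times."""
    neigh = mesh.neighbor_lists()
    for _ in range(rounds):
        x = np.array(
            [(x[i] + x[nb].sum()) / (1 + len(nb)) for i, nb in enumerate(neigh)]
        )
    return x


def _apex_height(mesh: SurfaceMesh) -> np.ndarray:
    z = mesh.vertices[:, 2]
    span = z.max() - z.min()
    if span == 0:
        return np.zeros_like(z)
    return (z - z.min()) / span


def make_parameter_fields(
    mesh: SurfaceMesh, spec: FieldSpec, seed: int
) -> ParameterField:
    """Smoothly varying tau_out/tau_close fields, deterministic per seed."""
    rng = np.random.default_rng(seed)
    endo = (mesh.surface_label == ENDO).astype(float)
    height = _apex_height(mesh)

    def build(base, d_ee, d_ab, noise_amp):
        x = base + d_ee * endo + d_ab * height
        if noise_amp > 0:
            x = x + _smooth(mesh, rng.normal(0.0, noise_amp, mesh.n_vertices),
                            spec.smoothing_rounds)
        return x

    tau_close = build(spec.tau_close_base, spec.d_tau_close_endo_epi,
                      spec.d_tau_close_apex_base, spec.noise_tau_close)
    tau_out = build(spec.tau_out_base, spec.d_tau_out_endo_epi,
                    spec.d_tau_out_apex_base, spec.noise_tau_out)
    for name, arr, (lo, hi) in (
        ("tau_out", tau_out, TAU_OUT_RANGE),
        ("tau_close", tau_close, TAU_CLOSE_RANGE),
    ):
        if arr.min() < lo or arr.max() > hi:
            warnings.warn(
                f"generated {name} outside [{lo}, {hi}] ms; clipping", stacklevel=2
            )
            np.clip(arr, lo, hi, out=arr)
    return ParameterField(A=spec.A, tau_out=tau_out, tau_close=tau_close,
                          tau=np.zeros(mesh.n_vertices))


def synthesize_recording(
    scenario: Scenario,
    mesh: SurfaceMesh,
    electrodes: ElectrodeSet,
    times: np.ndarray,
    dt_template: float = 0.05,
) -> tuple[BodySurfaceRecording, GroundTruth]:
    """Generate a recording plus its ground truth for one scenario.

    With ``mismatch='refined-mesh'`` the forward projection runs on a
    once-subdivided copy of the mesh (original vertices keep their indices,
    so ground truth restricts to them); with ``'perturbed-template'`` the
    generating ionic constants are tau_in=0.35 ms, v_gate=0.15.  Reference
    repolarization times come from the clean extracellular potentials via
    the maximum-positive-slope rule.
    """
    times = np.asarray(times, dtype=float)
    gen_mesh = subdivide(mesh) if scenario.mismatch == "refined-mesh" else mesh
    gen_params = (
        MSParameters(tau_in=0.35, v_gate=0.15)
        if scenario.mismatch == "perturbed-template"
        else MSParameters()
    )
    tau = make_activation_map(gen_mesh, scenario.pacing,
                              scenario.conduction_velocity)
    fields = make_parameter_fields(gen_mesh, scenario.field_spec, scenario.seed)
    fields.tau = tau
    clean, aux = _forward_eval(gen_mesh, electrodes, fields, times,
                               dt_template=dt_template, params=gen_params)
    n = mesh.n_vertices  # original vertices come first after subdivision
    rt = extract_repolarization_times(aux["phi_e"].phi_e[:n], tau[:n], times)
    truth = GroundTruth(
        tau=tau[:n],
        field=ParameterField(fields.A, fields.tau_out[:n], fields.tau_close[:n],
                             tau[:n]),
        rt=rt,
    )
    phi = clean.phi
    if scenario.noise_snr_db is not None:
        rng = np.random.default_rng(scenario.seed + 1)
        p_signal = float(np.mean(phi**2))
        sigma = np.sqrt(p_signal / 10.0 ** (scenario.noise_snr_db / 10.0))
        phi = phi + rng.normal(0.0, sigma, phi.shape)
    return BodySurfaceRecording(phi=phi, times=times), truth
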