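"""Mitchell-Schaeffer action-potential ansatz.

The two-current model describes a dimensionless voltage ``v`` and a gating
variable ``h``::

    v' = h v^2 (1 - v) / tau_in - v / tau_out
    h' = (1 - h) / tau_open   if v < v_gate
    h' = -h / tau_close       if v >= v_gate

Integrated from (v, h) = (0.15, 1) the voltage traces out a single action
potential; the resting state is (0, 1).  The transmembrane-voltage ansatz
used throughout the package is the time-shifted, amplitude-rescaled solution

    Vm(t) = A * v(t - tau),    with v(s) = 0 for s < 0,

so that each heart-surface node is described by its activation time ``tau``
and by the repolarization parameters ``tau_out`` and ``tau_close``.  The
remaining constants (tau_in, tau_open, v_gate) shape the upstroke and the
recovery and are kept fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import rk4_forward, rk4_forward_sens

__all__ = [
    "MSParameters",
    "APTemplate",
    "AnsatzEval",
    "integrate_ms",
    "eval_ansatz",
]


@dataclass(frozen=True)
class MSParameters:
    """Constants of the two-variable model (all times in ms)."""

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    v_gate: float = 0.13

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.v_gate < 1.0:
            raise ValueError(f"v_gate must lie in (0, 1), got {self.v_gate}")


@dataclass
class APTemplate:
    """One integrated action potential on a uniform time grid.

    ``s_out`` / ``s_close`` are the forward sensitivities dv/dtau_out and
    dv/dtau_close; they are ``None`` unless the template was built with
    ``with_sensitivities=True``.
    """

    times: np.ndarray  # ms, uniform step dt
    v: np.ndarray
    h: np.ndarray
    dt: float
    params: MSParameters = field(default_factory=MSParameters)
    s_out: np.ndarray | None = None
    s_close: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def to_csv(self, path) -> None:
        """Dump (t, v) as two-column CSV for plotting/debugging."""
        np.savetxt(path, np.column_stack([self.times, self.v]), delimiter=",",
                   header="t_ms,v", comments="")


@dataclass
class AnsatzEval:
    """Ansatz values and partial derivatives at the query times."""

    vm: np.ndarray
    d_dA: np.ndarray
    d_dtau: np.ndarray
    d_dtau_out: np.ndarray | None
    d_dtau_close: np.ndarray | None


def integrate_ms(
    params: MSParameters | None = None,
    duration: float = 500.0,
    dt_template: float = 0.05,
    with_sensitivities: bool = False,
    v0: float = 0.15,
    h0: float = 1.0,
) -> APTemplate:
    """Integrate the model with fixed-step RK4 from (v0, h0).

    ``duration`` should exceed the action-potential duration (>= 400 ms for
    default-magnitude parameters); ``dt_template`` above 0.5 ms leaves the
    ~1 ms upstroke under-resolved and triggers a warning.
    """
    params = params or MSParameters()
    if duration <= 0 or dt_template <= 0:
        raise ValueError("duration and dt_template must be positive")
    if dt_template > 0.5:
        warnings.warn(
            f"dt_template={dt_template} ms under-resolves the upstroke; "
            "use <= 0.1 ms",
            stacklevel=2,
        )
    n_steps = int(round(duration / dt_template))
    to = np.array([params.tau_out])
    tc = np.array([params.tau_close])
    args = (to, tc, params.tau_in, params.tau_open, params.v_gate,
            float(v0), float(h0), float(dt_template), n_steps)
    times = np.arange(n_steps + 1) * dt_template
    if with_sensitivities:
        V, H, SVO, _, SVC, _ = rk4_forward_sens(*args)
        return APTemplate(times, V[0], H[0], dt_template, params, SVO[0], SVC[0])
    V, H = rk4_forward(*args)
    return APTemplate(times, V[0], H[0], dt_template, params)


def interp_with_slope(tgrid: np.ndarray, y: np.ndarray, s: np.ndarray):
    """Linear interpolation of a template trace plus its segment slope.

    Queries at s < 0 return value 0 and slope 0 (the ansatz is completed by
    zero before onset); queries beyond the grid end return the final value
    with zero slope.
    """
    s = np.asarray(s, dtype=float)
    dt = tgrid[1] - tgrid[0]
    val = np.interp(s, tgrid, y, left=0.0)
    idx = np.clip(np.searchsorted(tgrid, s, side="right") - 1, 0, len(tgrid) - 2)
    slope = (y[idx + 1] - y[idx]) / dt
    outside = (s < 0.0) | (s >= tgrid[-1])
    slope = np.where(outside, 0.0, slope)
    val = np.where(s < 0.0, 0.0, val)
    return val, slope


def eval_ansatz(
    template: APTemplate,
    A: float,
    tau: float,
    query_times: np.ndarray,
) -> AnsatzEval:
    """Evaluate Vm(t) = A*v(t - tau) and its parameter derivatives.

    dVm/dA = v(t - tau); dVm/dtau = -A * v'(t - tau) with v' the slope of the
    linear interpolant (a finite subgradient across the onset jump);
    dVm/dtau_out and dVm/dtau_close use the co-integrated sensitivity traces
    and are ``None`` when the template lacks them.  All derivative traces are
    identically zero where t < tau.
    """
    t = np.asarray(query_times, dtype=float)
    s = t - tau
    v, dv = interp_with_slope(template.times, template.v, s)
    vm = A * v
    out = AnsatzEval(vm=vm, d_dA=v, d_dtau=-A * dv, d_dtau_out=None, d_dtau_close=None)
    if template.s_out is not None:
        so, _ = interp_with_slope(template.times, template.s_out, s)
        out.d_dtau_out = A * so
    if template.s_close is not None:
        sc, _ = interp_with_slope(template.times, template.s_close, s)
        out.d_dtau_close = A * sc
    return out
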