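"""Comparison metrics between reconstructed and reference maps/recordings.

Conventions: CC is the Pearson correlation coefficient; RE is the global
relative L2 error ||rec - ref|| / ||ref||; RMSE is per time sample across
electrodes.  Repolarization times are extracted from extracellular
potentials as the time of highest positive slope after the plateau, applied
identically to reference and reconstruction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .ap import APTemplate
from .mesh import ENDO, EPI, EndoEpiPairing, SurfaceMesh, geodesic_distances

__all__ = [
    "EvaluationReport",
    "map_metrics",
    "relative_error",
    "bspm_metrics",
    "extract_repolarization_times",
    "compute_apd90",
    "endo_epi_delays",
    "localize_earliest_site",
    "localization_distance",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: correlation undefined (NaN)", stacklevel=3)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def relative_error(rec: np.ndarray, ref: np.ndarray) -> float:
    """||rec - ref||_2 / ||ref||_2."""
    ref = np.asarray(ref, dtype=float)
    return float(np.linalg.norm(np.asarray(rec, dtype=float) - ref)
                 / np.linalg.norm(ref))


def map_metrics(
    reconstructed: np.ndarray,
    reference: np.ndarray,
    labels: np.ndarray | None = None,
) -> dict:
    """CC and RE of a per-vertex map, plus per-sub-surface CCs when labeled."""
    rec = np.asarray(reconstructed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if rec.size != ref.size or rec.size < 3:
        raise ValueError("maps must have equal length >= 3")
    out = {"cc": _pearson(rec, ref), "re": relative_error(rec, ref),
           "cc_epi": float("nan"), "cc_endo": float("nan")}
    if labels is not None:
        labels = np.asarray(labels)
        epi = labels == EPI
        endo = labels == ENDO
        if epi.sum() >= 3:
            out["cc_epi"] = _pearson(rec[epi], ref[epi])
        if endo.sum() >= 3:
            out["cc_endo"] = _pearson(rec[endo], ref[endo])
    return out


def bspm_metrics(reconstructed, reference) -> dict:
    """Per-time CC (across electrodes) and RMSE, plus their mean +/- sd."""
    if reconstructed.phi.shape != reference.phi.shape or not np.array_equal(
        reconstructed.times, reference.times
    ):
        raise ValueError("recordings must share electrode count and time grid")
    rec, ref = reconstructed.phi, reference.phi
    t_len = rec.shape[1]
    cc = np.empty(t_len)
    for k in range(t_len):
        if rec[:, k].std() == 0 or ref[:, k].std() == 0:
            cc[k] = np.nan
        else:
            cc[k] = np.corrcoef(rec[:, k], ref[:, k])[0, 1]
    rmse = np.sqrt(np.mean((rec - ref) ** 2, axis=0))
    return {
        "cc": cc,
        "rmse": rmse,
        "cc_mean": float(np.nanmean(cc)),
        "cc_sd": float(np.nanstd(cc)),
        "rmse_mean": float(rmse.mean()),
        "rmse_sd": float(rmse.std()),
    }


def extract_repolarization_times(
    phi_e: np.ndarray,
    tau: np.ndarray,
    times: np.ndarray,
    plateau_guard: float = 50.0,
) -> np.ndarray:
    """Per-node time of highest positive slope of phi_e after the plateau.

    The search window is [tau_i + plateau_guard, end]; the guard keeps the
    depolarization upslope out of the search.  Nodes with no strictly
    positive slope in the window (e.g. a flat trace) get NaN.
    """
    phi_e = np.atleast_2d(np.asarray(phi_e, dtype=float))
    times = np.asarray(times, dtype=float)
    tau = np.asarray(tau, dtype=float)
    dphi = np.gradient(phi_e, times, axis=1)
    rt = np.full(phi_e.shape[0], np.nan)
    empty = 0
    for i in range(phi_e.shape[0]):
        mask = times >= tau[i] + plateau_guard
        if not mask.any():
            empty += 1
            continue
        seg = dphi[i, mask]
        k = int(np.argmax(seg))
        if seg[k] > 0:
            rt[i] = times[mask][k]
    if empty:
        warnings.warn(f"{empty} nodes had an empty repolarization window",
                      stacklevel=2)
    return rt


def compute_apd90(template: APTemplate) -> float:
    """Action-potential duration at 90% repolarization from the peak (ms).

    Start marker: the upward v_gate crossing (t=0 when the trace starts
    above the gate); end marker: first fall below 0.1*v_peak after the peak.
    Both crossings are linearly interpolated; NaN when the trace never
    exceeds v_gate or never repolarizes within the template.
    """
    v = template.v
    t = template.times
    vg = template.params.v_gate
    if v.max() <= vg:
        return float("nan")
    if v[0] >= vg:
        t_act = float(t[0])
    else:
        i = int(np.argmax(v >= vg))  # first sample at/above the gate
        t_act = float(t[i - 1] + (t[i] - t[i - 1]) * (vg - v[i - 1]) / (v[i] - v[i - 1]))
    p = int(np.argmax(v))
    thresh = 0.1 * v[p]
    below = np.flatnonzero(v[p:] < thresh)
    if below.size == 0:
        return float("nan")
    j = p + below[0]
    t_end = float(t[j - 1] + (t[j] - t[j - 1]) * (v[j - 1] - thresh) / (v[j - 1] - v[j]))
    return t_end - t_act


def endo_epi_delays(pairing: EndoEpiPairing, tau: np.ndarray) -> dict:
    """Activation delay epi-minus-paired-endo per EPI vertex + box-plot stats."""
    tau = np.asarray(tau, dtype=float)
    delays = tau[pairing.epi_indices] - tau[pairing.endo_partner]
    q1, med, q3 = np.percentile(delays, [25, 50, 75])
    return {
        "delays": delays,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(delays.min()),
        "max": float(delays.max()),
    }


def localize_earliest_site(
    mesh: SurfaceMesh,
    tau: np.ndarray,
    restrict_to: str = "ALL",
    exclude_isolated: bool = False,
    isolation_threshold: float = 30.0,
) -> int:
    """Vertex with the earliest activation time on the requested sub-surface.

    ``exclude_isolated`` drops candidate vertices whose 1-ring mean AT
    exceeds the vertex AT by more than ``isolation_threshold`` ms (an
    automatic analog of excluding isolated early activations by eye).
    Ties break to the smallest vertex index.
    """
    tau = np.asarray(tau, dtype=float)
    if restrict_to == "ALL":
        idx = np.arange(mesh.n_vertices)
    elif restrict_to == "EPI":
        idx = mesh.epi_indices
    elif restrict_to == "ENDO":
        idx = mesh.endo_indices
    else:
        raise ValueError(f"restrict_to must be EPI, ENDO or ALL, got {restrict_to!r}")
    if idx.size == 0:
        raise ValueError(f"no vertices labeled {restrict_to}")
    if not np.isfinite(tau[idx]).all():
        raise ValueError("activation times must be finite on the restricted set")
    if exclude_isolated:
        neigh = mesh.neighbor_lists()
        keep = np.array(
            [np.mean(tau[neigh[i]]) - tau[i] <= isolation_threshold for i in idx]
        )
        if keep.any():
            idx = idx[keep]
    return int(idx[int(np.argmin(tau[idx]))])


def localization_distance(mesh: SurfaceMesh, true_idx: int, found_idx: int) -> float:
    """Geodesic distance (mm) between true and identified pacing sites."""
    return float(geodesic_distances(mesh, true_idx)[found_idx])


@dataclass
class EvaluationReport:
    """Flat summary of one reconstruction-vs-reference comparison."""

    cc_at: float = float("nan")
    re_at: float = float("nan")
    cc_rt: float = float("nan")
    re_rt: float = float("nan")
    cc_at_epi: float = float("nan")
    cc_at_endo: float = float("nan")
    cc_rt_epi: float = float("nan")
    cc_rt_endo: float = float("nan")
    cc_bspm_mean: float = float("nan")
    cc_bspm_sd: float = float("nan")
    rmse_bspm_mean: float = float("nan")
    rmse_bspm_sd: float = float("nan")
    delay_median: float = float("nan")
    delay_q1: float = float("nan")
    delay_q3: float = float("nan")
    localization_mm: float = float("nan")
    j_reduction_percent: float = float("nan")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    def to_csv_row(self) -> str:
        d = asdict(self)
        return ",".join(d.keys()) + "\n" + ",".join(f"{v:.6g}" for v in d.values())
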