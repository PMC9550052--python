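"""Quantities of interest from a voltage solution.

Implements activation and repolarization maps (threshold crossings with
linear interpolation between output samples), the normalized apex-to-base
activation time, the pseudo-ECG (infinite-volume-conductor lead field), the
per-element repolarization-gradient magnitude, and the high repolarization
gradient volume (HRGV): the volume of healthy/BZ tissue within a proximity
radius of scar whose repolarization gradient exceeds a threshold — a
surrogate for pacing-induced arrhythmia risk around infarcts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import BZ, HEALTHY, LabeledMesh, SCAR
from .monodomain import VoltageSolution, element_conductivities, SimulationConfig
from .surface import points_within_surface_distance


@dataclass
class QoiConfig:
    """Thresholds and probe geometry for QoI extraction.

    Defaults: activation detected at the -20 mV upstroke crossing,
    repolarization at the return below -70 mV, repolarization gradients
    thresholded at 30 ms/cm (25 ms/cm as the sensitivity alternative), and
    scar proximity of 1 cm.
    """

    activation_threshold: float = -20.0  # mV
    repolarization_threshold: float = -70.0  # mV
    gradient_threshold: float = 30.0  # ms/cm
    scar_proximity_radius: float = 1.0  # cm
    base_probe_point: tuple[float, float, float] | None = None
    electrode_positions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gradient_threshold <= 0:
            raise ValueError("gradient_threshold must be positive")
        if self.scar_proximity_radius <= 0:
            raise ValueError("scar_proximity_radius must be positive")


def activation_map(sol: VoltageSolution, cfg: QoiConfig) -> np.ndarray:
    """Per-node first upward crossing time (ms) of the activation threshold.

    Linearly interpolated between output samples; NaN where the node never
    crosses the threshold from below.
    """
    v = sol.voltage
    thr = cfg.activation_threshold
    above = v >= thr
    crossing = above[1:] & ~above[:-1]  # (T-1, N)
    out = np.full(sol.n_nodes, np.nan)
    has = crossing.any(axis=0)
    if not has.any():
        return out
    idx = crossing.argmax(axis=0)  # first crossing interval
    cols = np.flatnonzero(has)
    i = idx[cols]
    v0 = v[i, cols]
    v1 = v[i + 1, cols]
    t0 = sol.times[i]
    t1 = sol.times[i + 1]
    frac = (thr - v0) / (v1 - v0)
    out[cols] = t0 + frac * (t1 - t0)
    return out


def repolarization_map(sol: VoltageSolution, cfg: QoiConfig,
                       act: np.ndarray | None = None) -> np.ndarray:
    """Per-node first time (ms) after activation with V below the
    repolarization threshold; NaN for unactivated or unrepolarized nodes."""
    if act is None:
        act = activation_map(sol, cfg)
    v = sol.voltage
    thr = cfg.repolarization_threshold
    out = np.full(sol.n_nodes, np.nan)
    cols = np.flatnonzero(np.isfinite(act))
    if cols.size == 0:
        return out
    # only samples strictly after activation count
    after = sol.times[:, None] > act[cols][None, :]
    below = v[:, cols] < thr
    hit = below & after
    has = hit.any(axis=0)
    sel = cols[has]
    j = hit[:, has].argmax(axis=0)
    j = np.maximum(j, 1)
    v0 = v[j - 1, sel]
    v1 = v[j, sel]
    t0 = sol.times[j - 1]
    t1 = sol.times[j]
    denom = np.where(v1 != v0, v1 - v0, 1.0)
    frac = np.clip((thr - v0) / denom, 0.0, 1.0)
    out[sel] = t0 + frac * (t1 - t0)
    # crossing must not precede activation (guard for nodes already below
    # threshold in the sample right after activation)
    out[sel] = np.maximum(out[sel], act[sel])
    return out


def normalized_activation_time(act: np.ndarray, mesh: LabeledMesh,
                               pacing_node: int, probe_point) -> float:
    """Activation time at the node nearest ``probe_point`` divided by its
    distance (cm) to the pacing node — the heart-size-normalized global
    activation measure (ms/cm)."""
    probe_point = np.asarray(probe_point, dtype=float)
    probe_node = int(np.linalg.norm(mesh.nodes - probe_point, axis=1).argmin())
    dist = float(np.linalg.norm(mesh.nodes[probe_node] - mesh.nodes[pacing_node]))
    if dist <= 0:
        raise ValueError("probe node coincides with the pacing node")
    t = act[probe_node]
    if not np.isfinite(t):
        raise ValueError("probe node was never activated")
    return float(t) / dist


def pseudo_ecg(sol: VoltageSolution, mesh: LabeledMesh, electrode,
               config: SimulationConfig | None = None, k: float = 1.0) -> np.ndarray:
    """Far-field extracellular potential proxy at one electrode.

    phi(t) = -k * sum_e vol_e * (sigma_e grad V_m) . grad(1/r) evaluated at
    the element centroid (single-point quadrature, per-element constant P1
    gradient).  Units are arbitrary but consistent; only relative errors
    and lags are consumed downstream.  The lead vector is precomputed so
    the trace is a single matrix-vector product per time sample.
    """
    electrode = np.asarray(electrode, dtype=float)
    rvec = mesh.centroids - electrode[None, :]
    r = np.linalg.norm(rvec, axis=1)
    if r.min() < mesh.mean_edge_length:
        raise ValueError("electrode lies inside or on the tissue mesh")
    if config is None:
        config = SimulationConfig()
    sigma = element_conductivities(mesh, config)
    grad_inv_r = -rvec / (r**3)[:, None]  # grad_x (1/|x - electrode|) at centroids
    w = np.einsum("eij,ej->ei", sigma, grad_inv_r)  # sigma^T g (sigma symmetric)
    per_elem_node = np.einsum("ei,eij->ej", w, mesh.shape_gradients)
    per_elem_node *= mesh.element_volumes[:, None]
    lead = np.zeros(mesh.n_nodes)
    np.add.at(lead, mesh.elements.ravel(), per_elem_node.ravel())
    return -k * sol.voltage @ lead


def repolarization_gradient(repol: np.ndarray, mesh: LabeledMesh) -> np.ndarray:
    """Per-element |grad T_rep| (ms/cm) from the P1 interpolant.

    Exact for nodal data linear in space; NaN for elements with any
    undefined nodal repolarization time.
    """
    vals = repol[mesh.elements]  # (M, 4)
    g = np.einsum("eij,ej->ei", mesh.shape_gradients, vals)
    mag = np.linalg.norm(g, axis=1)
    mag[~np.isfinite(vals).all(axis=1)] = np.nan
    return mag


def hrgv(grad: np.ndarray, mesh: LabeledMesh, cfg: QoiConfig) -> float:
    """High repolarization gradient volume (cm^3).

    Sum of element volumes that are (a) healthy or BZ, (b) centroid within
    ``scar_proximity_radius`` of the scar boundary surface, and (c) have
    repolarization-gradient magnitude above ``gradient_threshold``.
    Returns 0 for meshes without scar (empty proximity region).
    """
    scar_mask = mesh.tissue_class == SCAR
    if not scar_mask.any():
        return 0.0
    excitable = (mesh.tissue_class == HEALTHY) | (mesh.tissue_class == BZ)
    near = np.zeros(mesh.n_elements, dtype=bool)
    sel = np.flatnonzero(excitable)
    near[sel] = points_within_surface_distance(mesh, mesh.centroids[sel],
                                               scar_mask, cfg.scar_proximity_radius)
    with np.errstate(invalid="ignore"):
        high = np.nan_to_num(grad, nan=0.0) > cfg.gradient_threshold
    take = excitable & near & high
    return float(mesh.element_volumes[take].sum())
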