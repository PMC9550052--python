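"""Input perturbations for the uncertainty study.

Personalized-input uncertainty: the border zone is contracted (BZ elements
near the healthy interface relabeled healthy) or expanded (healthy elements
near the BZ/scar boundary relabeled BZ) by a morphological distance,
mirroring plausible segmentation error in BZ extent.  The scar is never
altered, because pacing locations are defined by distance to scar.

Non-personalized-input uncertainty: fiber conductivity is retuned so the
planar conduction velocity hits 80% / 120% of baseline, keeping the
fiber-to-cross anisotropy ratio fixed.

All operators are pure: the input mesh/config is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import BZ, HEALTHY, LabeledMesh, SCAR
from .monodomain import CvSlabSpec, SimulationConfig, measure_planar_cv, tune_conductivity_to_cv
from .surface import interface_faces, point_triangle_distances, region_boundary_faces

#: Default morphological distances (cm): contract by 0.5 mm, expand by 1 mm.
DEFAULT_CONTRACT_DIST = 0.05
DEFAULT_EXPAND_DIST = 0.1


def contract_bz(mesh: LabeledMesh, dist: float = DEFAULT_CONTRACT_DIST) -> LabeledMesh:
    """Relabel BZ elements within ``dist`` of the BZ-healthy interface as healthy.

    Distance is measured from the BZ element centroid to the triangulated
    interface surface (faces shared by a BZ and a healthy element).  Scar
    is untouched; a mesh without BZ is returned unchanged (as a copy).
    """
    if dist < 0:
        raise ValueError("contraction distance must be non-negative")
    tc = mesh.tissue_class.copy()
    bz_mask = tc == BZ
    if dist == 0 or not bz_mask.any():
        return mesh.with_tissue_class(tc)
    faces = interface_faces(mesh, bz_mask, tc == HEALTHY)
    if faces.shape[0] == 0:
        return mesh.with_tissue_class(tc)
    sel = np.flatnonzero(bz_mask)
    d = point_triangle_distances(mesh.centroids[sel], mesh.nodes[faces])
    tc[sel[d <= dist]] = HEALTHY
    return mesh.with_tissue_class(tc)


def expand_bz(mesh: LabeledMesh, dist: float = DEFAULT_EXPAND_DIST) -> LabeledMesh:
    """Relabel healthy elements within ``dist`` of the BZ/scar region as BZ.

    Distance is measured from the healthy element centroid to the boundary
    surface of the union region (BZ or scar).  Scar is untouched.
    """
    if dist < 0:
        raise ValueError("expansion distance must be non-negative")
    tc = mesh.tissue_class.copy()
    union = (tc == BZ) | (tc == SCAR)
    if dist == 0 or not union.any():
        return mesh.with_tissue_class(tc)
    faces = region_boundary_faces(mesh, union)
    sel = np.flatnonzero(tc == HEALTHY)
    if sel.size == 0 or faces.shape[0] == 0:
        return mesh.with_tissue_class(tc)
    d = point_triangle_distances(mesh.centroids[sel], mesh.nodes[faces])
    tc[sel[d <= dist]] = BZ
    return mesh.with_tissue_class(tc)


def bz_variants(mesh: LabeledMesh,
                contract_dist: float = DEFAULT_CONTRACT_DIST,
                expand_dist: float = DEFAULT_EXPAND_DIST) -> dict[str, LabeledMesh]:
    """The three BZ representations: contracted, original, expanded."""
    return {
        "contracted": contract_bz(mesh, contract_dist),
        "original": mesh,
        "expanded": expand_bz(mesh, expand_dist),
    }


@dataclass
class ConductivityVariant:
    """A tuned conductivity configuration with its provenance."""

    name: str
    config: SimulationConfig
    cv_factor: float
    measured_cv: float


def conductivity_variants(config: SimulationConfig,
                          cv_factors: tuple[float, float] = (0.8, 1.2),
                          slab: CvSlabSpec | None = None) -> dict[str, ConductivityVariant]:
    """(low, baseline, high) configs hitting the CV factors within tolerance.

    The baseline planar CV is measured on the calibration slab, targets are
    ``factor * baseline``, and the fiber conductivity is retuned for each;
    both conductivities scale by the same factor so the anisotropy ratio is
    preserved exactly.
    """
    slab = slab or CvSlabSpec()
    baseline_cv = measure_planar_cv(config, slab)
    out = {"baseline": ConductivityVariant("baseline", config, 1.0, baseline_cv)}
    for name, factor in zip(("low", "high"), cv_factors):
        tuned = tune_conductivity_to_cv(factor * baseline_cv, config, slab)
        out[name] = ConductivityVariant(name, tuned, factor,
                                        measure_planar_cv(tuned, slab))
    return out
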