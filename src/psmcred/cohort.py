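"""Synthetic virtual cohort of patient-like infarcted tissue slabs.

The external image-derived left-ventricular cohorts that motivate this
package are not redistributable, so this module generates analytic
stand-ins: box-shaped myocardial slabs with an embedded spherical scar core,
a surrounding border-zone (BZ) shell, and transmurally rotating fibers.
Every label has a closed-form ground truth (ball and shell volumes), which
makes each downstream operation checkable against brute-force oracles.

Geometry conventions: the slab occupies ``[0, Lx] x [0, Ly] x [0, Lz]`` with
``Lz`` the wall thickness; z is the transmural (endo-to-epi) direction and
fibers lie in the x-y plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh import (
    BZ,
    HEALTHY,
    KUHN_EDGE_FACTOR,
    LabeledMesh,
    SCAR,
    build_slab_mesh,
)
from .surface import distance_to_region_surface, distance_to_scar_surface


class InfeasibleGeometryError(ValueError):
    """Scar plus border zone do not fit inside the tissue domain."""


@dataclass
class PatientSpec:
    """Analytic description of one synthetic patient.

    Lengths in cm.  ``fiber_rotation`` is the (endocardial, epicardial)
    fiber angle pair in degrees; the angle interpolates linearly across the
    wall.  The default BZ shell thickness is of the order of the ~1 mm
    cohort-average BZ thickness reported for image-derived infarct models.
    """

    patient_id: str
    wall_thickness: float = 0.4
    domain_extent: tuple[float, float, float] = (1.2, 1.0, 0.4)
    scar_center: tuple[float, float, float] = (0.6, 0.5, 0.2)
    scar_radius: float = 0.12
    bz_thickness: float = 0.07
    fiber_rotation: tuple[float, float] = (-60.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.scar_radius <= 0:
            raise ValueError("scar_radius must be positive")
        if self.bz_thickness < 0:
            raise ValueError("bz_thickness must be non-negative")
        ext = np.asarray(self.domain_extent, float)
        if abs(ext[2] - self.wall_thickness) > 1e-12:
            raise ValueError("domain_extent[2] must equal wall_thickness")
        c = np.asarray(self.scar_center, float)
        r = self.scar_radius + self.bz_thickness
        if np.any(c - r < -1e-12) or np.any(c + r > ext + 1e-12):
            raise InfeasibleGeometryError(
                f"scar ball (radius {self.scar_radius} cm) plus BZ shell "
                f"({self.bz_thickness} cm) at {tuple(c)} does not fit inside "
                f"domain extent {tuple(ext)}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PatientSpec":
        d = dict(d)
        for k in ("domain_extent", "scar_center", "fiber_rotation"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class MeshFamily:
    """Nested-resolution meshes of one patient, coarsest to finest."""

    patient_id: str
    edge_lengths: list[float]
    meshes: list[LabeledMesh] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.edge_lengths) < 2:
            raise ValueError("a mesh family needs at least 2 edge lengths")
        diffs = np.diff(self.edge_lengths)
        if np.any(diffs >= 0):
            raise ValueError("edge lengths must be strictly decreasing")

    @property
    def finest(self) -> LabeledMesh:
        return self.meshes[-1]


def generate_patient(spec: PatientSpec, target_edge_length: float) -> LabeledMesh:
    """Labeled tetrahedral slab for one synthetic patient.

    ``target_edge_length`` is the desired mean edge length (cm); the grid
    spacing is chosen so the structured tetrahedralization matches it.
    Elements are classified by centroid: inside the scar ball -> SCAR,
    inside the surrounding shell of width ``bz_thickness`` -> BZ, else
    HEALTHY.  Deterministic given (spec, target_edge_length).
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    spacing = target_edge_length / KUHN_EDGE_FACTOR
    if spacing > spec.wall_thickness / 2:
        raise ValueError(
            f"edge length {target_edge_length} cm too coarse: fewer than 2 "
            f"elements span the {spec.wall_thickness} cm wall"
        )
    nodes, elements = build_slab_mesh(spec.domain_extent, spacing)
    mesh = LabeledMesh(
        nodes=nodes,
        elements=elements,
        tissue_class=np.zeros(elements.shape[0], dtype=np.uint8),
        fiber=np.tile([1.0, 0.0, 0.0], (elements.shape[0], 1)),
        resolution_tag=f"{target_edge_length:g}cm",
        patient_id=spec.patient_id,
    )
    r = np.linalg.norm(mesh.centroids - np.asarray(spec.scar_center), axis=1)
    tc = np.full(mesh.n_elements, HEALTHY, dtype=np.uint8)
    tc[r <= spec.scar_radius + spec.bz_thickness] = BZ
    tc[r <= spec.scar_radius] = SCAR
    mesh.tissue_class = tc
    return assign_fibers(mesh, spec.fiber_rotation)


def generate_mesh_family(spec: PatientSpec, edge_lengths) -> MeshFamily:
    """Nested-resolution family sharing the identical analytic geometry."""
    family = MeshFamily(patient_id=spec.patient_id, edge_lengths=list(edge_lengths))
    family.meshes = [generate_patient(spec, h) for h in family.edge_lengths]
    return family


def assign_fibers(mesh: LabeledMesh, rotation: tuple[float, float]) -> LabeledMesh:
    """Rule-based fibers: in-plane angle rotating linearly across the wall.

    The transmural coordinate is the normalized z-depth of the element
    centroid; the fiber angle interpolates from ``rotation[0]`` (endo, z=0)
    to ``rotation[1]`` (epi, z=thickness), measured from the +x axis in the
    x-y plane.
    """
    z = mesh.nodes[:, 2]
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin <= 0:
        raise ValueError("degenerate transmural coordinate: zero wall thickness")
    depth = (mesh.centroids[:, 2] - zmin) / (zmax - zmin)
    ang = np.deg2rad(rotation[0] + depth * (rotation[1] - rotation[0]))
    fiber = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    mesh.fiber = fiber
    return mesh


def select_pacing_sites(mesh: LabeledMesh, distances, tolerance=None) -> list[int]:
    """Node indices at prescribed Euclidean distances from the scar surface.

    For each requested distance ``d`` the candidate nodes are those incident
    to at least one HEALTHY element; among candidates whose distance to the
    triangulated scar boundary surface lies within the tolerance (default:
    the larger of 10% of ``d`` and one mean edge length) of ``d``, the
    lowest node index is returned (deterministic tie-break).
    """
    scar_mask = mesh.tissue_class == SCAR
    if not scar_mask.any():
        raise ValueError("mesh has no scar elements")
    healthy_nodes = np.unique(mesh.elements[mesh.tissue_class == HEALTHY])
    if healthy_nodes.size == 0:
        raise ValueError("mesh has no healthy elements")
    dist = distance_to_scar_surface(mesh, mesh.nodes[healthy_nodes])
    edge = mesh.mean_edge_length
    out = []
    for d in distances:
        tol = tolerance if tolerance is not None else max(0.1 * d, edge)
        ok = np.abs(dist - d) <= tol
        if not ok.any():
            raise ValueError(
                f"no healthy node within {tol:g} cm of requested scar distance "
                f"{d:g} cm (achievable range {dist.min():g}..{dist.max():g} cm)"
            )
        out.append(int(healthy_nodes[ok].min()))
    return out


def bz_thickness_stats(mesh: LabeledMesh) -> tuple[float, float]:
    """(mean, max) BZ thickness proxy over BZ element centroids, cm.

    The proxy for each BZ element is the distance from its centroid to the
    healthy-region surface plus the distance to the scar-region surface;
    for a uniform shell this sums to the shell thickness.  Returns (0, 0)
    when the mesh has no BZ elements.
    """
    bz_mask = mesh.tissue_class == BZ
    if not bz_mask.any():
        return 0.0, 0.0
    pts = mesh.centroids[bz_mask]
    d_h = distance_to_region_surface(mesh, pts, mesh.tissue_class == HEALTHY)
    d_s = distance_to_region_surface(mesh, pts, mesh.tissue_class == SCAR)
    thick = np.where(np.isfinite(d_h), d_h, 0.0) + np.where(np.isfinite(d_s), d_s, 0.0)
    return float(thick.mean()), float(thick.max())


# ---------------------------------------------------------------------------
# Cohort randomization
# ---------------------------------------------------------------------------

#: Uniform sampling ranges for per-patient geometry (cm / degrees).  These
#: define the synthetic population; the BZ-thickness range is of the order
#: of the ~1 mm average reported for image-derived infarct cohorts, and the
#: scar ball plus BZ shell always fits inside the wall (radius + shell
#: <= wall_thickness / 2 for every combination of range endpoints).
DEFAULT_COHORT_RANGES = {
    "domain_x": (1.1, 1.3),
    "domain_y": (0.9, 1.1),
    "wall_thickness": (0.40, 0.44),
    "scar_radius": (0.10, 0.12),
    "bz_thickness": (0.05, 0.07),
    "endo_angle": (-70.0, -50.0),
    "epi_angle": (50.0, 70.0),
}


def make_cohort_specs(n_patients: int, seed: int, ranges: dict | None = None) -> list[PatientSpec]:
    """Draw a reproducible synthetic cohort from one master seed.

    One :class:`numpy.random.SeedSequence` spawns a child per patient, so
    the whole cohort is reproducible from a single integer and individual
    patients are independent of the cohort size ordering.
    """
    rng_ranges = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        rng_ranges.update(ranges)
    children = np.random.SeedSequence(seed).spawn(n_patients)
    specs = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        u = {k: rng.uniform(*v) for k, v in rng_ranges.items()}
        wall = u["wall_thickness"]
        ext = (u["domain_x"], u["domain_y"], wall)
        scar_r = u["scar_radius"]
        bz = u["bz_thickness"]
        specs.append(
            PatientSpec(
                patient_id=f"synth{i + 1:02d}",
                wall_thickness=wall,
                domain_extent=ext,
                scar_center=(ext[0] / 2, ext[1] / 2, wall / 2),
                scar_radius=scar_r,
                bz_thickness=bz,
                fiber_rotation=(u["endo_angle"], u["epi_angle"]),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return specs


def write_cohort(specs: list[PatientSpec], edge_lengths, out_dir) -> dict:
    """Write per-patient VTU meshes and a JSON manifest; return the manifest."""
    from . import vtu

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for spec in specs:
        entry = {"patient_id": spec.patient_id, "spec": spec.to_dict(), "meshes": []}
        for h in edge_lengths:
            mesh = generate_patient(spec, h)
            path = out_dir / f"{spec.patient_id}_h{h:g}.vtu"
            vtu.write_vtu(path, mesh)
            entry["meshes"].append({"edge_length_cm": h, "path": path.name})
        manifest["patients"].append(entry)
    with open(out_dir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_cohort(in_dir) -> list[MeshFamily]:
    """Read a cohort written by :func:`write_cohort` (or user-supplied
    labeled .vtu meshes listed in a ``cohort_manifest.json``) back into
    per-patient mesh families, coarsest to finest."""
    from . import vtu

    in_dir = Path(in_dir)
    manifest_path = in_dir / "cohort_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    families = []
    for entry in manifest["patients"]:
        meshes, lengths = [], []
        for m in sorted(entry["meshes"], key=lambda m: -m["edge_length_cm"]):
            mesh, _, _ = vtu.read_vtu(in_dir / m["path"])
            mesh.patient_id = entry["patient_id"]
            mesh.resolution_tag = f"{m['edge_length_cm']:g}cm"
            meshes.append(mesh)
            lengths.append(m["edge_length_cm"])
        fam = MeshFamily(patient_id=entry["patient_id"], edge_lengths=lengths)
        fam.meshes = meshes
        families.append(fam)
    return families
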