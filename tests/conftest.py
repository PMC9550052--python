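"""Shared fixtures: small analytic meshes with known labels."""

import numpy as np
import pytest

from psmcred.cohort import PatientSpec, generate_patient
from psmcred.mesh import BZ, HEALTHY, SCAR, LabeledMesh, build_slab_mesh


@pytest.fixture(scope="session")
def default_spec() -> PatientSpec:
    return PatientSpec(patient_id="fix01")


@pytest.fixture(scope="session")
def labeled_mesh(default_spec) -> LabeledMesh:
    """Default patient at a moderate resolution (scar ball + BZ shell)."""
    return generate_patient(default_spec, 0.08)


@pytest.fixture(scope="session")
def fine_mesh(default_spec) -> LabeledMesh:
    return generate_patient(default_spec, 0.05)


def make_plain_slab(extent=(1.0, 0.4, 0.4), spacing=0.05) -> LabeledMesh:
    """Homogeneous healthy slab with fibers along +x."""
    nodes, elements = build_slab_mesh(extent, spacing)
    m = elements.shape[0]
    return LabeledMesh(
        nodes=nodes,
        elements=elements,
        tissue_class=np.zeros(m, dtype=np.uint8),
        fiber=np.tile([1.0, 0.0, 0.0], (m, 1)),
        resolution_tag="slab",
        patient_id="slab",
    )


def make_scar_block_slab(extent=(1.0, 0.6, 0.3), spacing=0.05,
                         scar_lo=(0.4, 0.2, 0.0), scar_hi=(0.6, 0.4, 0.3),
                         bz_pad=0.0) -> LabeledMesh:
    """Slab with an axis-aligned scar block (and optional BZ padding shell).

    Box-shaped regions keep every label decidable by closed-form centroid
    tests, which the brute-force oracles in the tests rely on.
    """
    mesh = make_plain_slab(extent, spacing)
    c = mesh.centroids
    lo, hi = np.asarray(scar_lo), np.asarray(scar_hi)
    inside = np.all((c >= lo) & (c <= hi), axis=1)
    tc = np.full(mesh.n_elements, HEALTHY, dtype=np.uint8)
    if bz_pad > 0:
        in_bz = np.all((c >= lo - bz_pad) & (c <= hi + bz_pad), axis=1)
        tc[in_bz] = BZ
    tc[inside] = SCAR
    mesh.tissue_class = tc
    return mesh


@pytest.fixture(scope="session")
def study1_results():
    """Scaled-down multi-patient convergence study (shared across tests)."""
    from psmcred.pipeline import Study1Config, run_study_1

    return run_study_1(Study1Config(n_patients=3, seed=1))


@pytest.fixture(scope="session")
def study2_results():
    """Scaled-down robustness study (shared across tests)."""
    from psmcred.pipeline import Study2Config, run_study_2

    return run_study_2(Study2Config(n_patients=5, seed=1))
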