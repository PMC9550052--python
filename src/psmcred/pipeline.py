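"""End-to-end orchestration of the two credibility studies.

Study 1 (verification): multi-patient mesh-convergence analysis — each
synthetic patient is meshed at nested resolutions, paced apically, and
discretization errors in normalized activation time and pseudo-ECG are
tabulated with their across-patient coefficients of variation.

Study 2 (uncertainty quantification): does the cohort-level conclusion
"HRGV is greater pacing near scar than far from it" survive plausible
errors in a personalized input (border-zone extent) and a non-personalized
input (tissue conductivity)?  The full scenario battery of systematic,
worst-case, Monte-Carlo and continuous-CV tests is executed on the
synthetic cohort.

Desk-scale defaults (3 patients x 3 resolutions; 5 patients for the
robustness study) are chosen so both studies complete in minutes on one
CPU; all sizes are configuration knobs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cellmodel import CellModelParams
from .cohort import (
    MeshFamily,
    PatientSpec,
    generate_mesh_family,
    generate_patient,
    make_cohort_specs,
    select_pacing_sites,
)
from .convergence import (
    ConvergenceStudyConfig,
    cov_table,
    run_convergence_study,
)
from .monodomain import CvSlabSpec, SimulationConfig, Stimulus, run_monodomain
from .perturb import bz_variants, conductivity_variants
from .qoi import QoiConfig, activation_map, hrgv, repolarization_gradient, repolarization_map
from .robustness import (
    HrgvPanel,
    RobustnessConfig,
    ScenarioResult,
    cv_normal_sampling,
    mc_fraction_significant,
    paired_t_one_sided,
    systematic_scenario_test,
    worst_case_test,
)

log = logging.getLogger(__name__)


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Study 1
# ---------------------------------------------------------------------------

@dataclass
class Study1Config:
    """Multi-patient mesh-convergence study configuration."""

    n_patients: int = 3
    seed: int = 1
    #: nested mean edge lengths (cm), coarsest to finest; the range mirrors
    #: the ~0.10 -> 0.03 cm span used in full-scale resolution studies
    edge_lengths: tuple[float, ...] = (0.10, 0.05, 0.025)
    duration: float = 45.0  # ms, covers full slab activation
    dt: float = 0.05  # ms, fixed across resolutions (spatial study only)
    output_interval: float = 0.5  # ms
    out_dir: str | None = None


def _study1_family_config(spec: PatientSpec, cfg: Study1Config):
    ext = np.asarray(spec.domain_extent)
    sim = SimulationConfig(duration=cfg.duration, dt=cfg.dt,
                           output_interval=cfg.output_interval)
    # apical pacing analogue: center of the x=0 face; base probe at the
    # opposite face; V1-like electrode 4 cm from the domain centroid on +x
    return ConvergenceStudyConfig(
        sim=sim,
        qoi=QoiConfig(),
        pacing_point=(0.0, ext[1] / 2, ext[2] / 2),
        probe_point=(ext[0], ext[1] / 2, ext[2] / 2),
        electrode=(ext[0] / 2 + 4.0, ext[1] / 2, ext[2] / 2),
    )


def run_study_1(cfg: Study1Config) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort -> simulations at all resolutions -> error table -> COV table."""
    specs = make_cohort_specs(cfg.n_patients, cfg.seed)
    families = [generate_mesh_family(s, cfg.edge_lengths) for s in specs]
    by_id = {s.patient_id: s for s in specs}

    def cfg_for(family: MeshFamily) -> ConvergenceStudyConfig:
        return _study1_family_config(by_id[family.patient_id], cfg)

    errors = run_convergence_study(families, cfg_for)
    if errors.empty or errors["patient_id"].nunique() < 2:
        raise RuntimeError("study 1 failed: fewer than 2 patients succeeded")
    cov = cov_table(errors)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        errors.to_csv(out / "study1_errors.csv", index=False)
        cov.to_csv(out / "study1_cov.csv")
        (out / "study1_report.md").write_text(
            render_convergence_markdown(errors, cov, families))
        provenance = {
            "study": "mesh_convergence",
            "seed": cfg.seed,
            "config_hash": _config_hash(vars(cfg)),
            "n_patients": cfg.n_patients,
            "edge_lengths_cm": list(cfg.edge_lengths),
        }
        (out / "study1_provenance.json").write_text(json.dumps(provenance, indent=2))
    return errors, cov


def render_convergence_markdown(errors: pd.DataFrame, cov: pd.DataFrame,
                                families=None) -> str:
    """Text report: per-resolution mesh statistics and error COVs."""
    lines = ["# Mesh-convergence report", ""]
    if families:
        lines += ["## Mesh families", "",
                  "| resolution (cm) | mean edge (cm) | elements (mean) |",
                  "|---|---|---|"]
        edge_lengths = families[0].edge_lengths
        for i, h in enumerate(edge_lengths):
            edges = np.mean([f.meshes[i].mean_edge_length for f in families])
            elems = np.mean([f.meshes[i].n_elements for f in families])
            lines.append(f"| {h:g} | {edges:.4f} | {elems:.0f} |")
        lines.append("")
    lines += ["## Discretization errors vs the finest mesh", "",
              "```", errors.to_string(index=False), "```", "",
              "## Coefficients of variation across patients", "",
              "```", cov.to_string(), "```", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Study 2
# ---------------------------------------------------------------------------

#: Per-patient ranges for the robustness cohort: a long slab so pacing
#: 4.5 cm from scar fits, with the scar near one end.  The near pacing
#: site ends up transmurally/cross-fiber adjacent to the scar while the
#: far site lies along the fiber axis — the geometric substrate for the
#: near-vs-far repolarization-gradient effect.
STUDY2_RANGES = {
    "domain_x": (5.8, 6.2),
    "domain_y": (1.1, 1.3),
    "wall_thickness": (0.68, 0.72),
    "scar_radius": (0.14, 0.17),
    "bz_thickness": (0.12, 0.16),
    "endo_angle": (-65.0, -55.0),
    "epi_angle": (55.0, 65.0),
}


def make_study2_specs(n_patients: int, seed: int) -> list[PatientSpec]:
    """Synthetic robustness cohort: long slabs with scar near one end."""
    specs = make_cohort_specs(n_patients, seed, STUDY2_RANGES)
    out = []
    for s in specs:
        ext = s.domain_extent
        out.append(replace(s, scar_center=(1.0, ext[1] / 2, s.wall_thickness / 2)))
    return out


@dataclass
class Study2Config:
    """Uncertainty-quantification study configuration."""

    n_patients: int = 5
    seed: int = 1
    edge_length: float = 0.12  # cm, single (medium-analogue) resolution
    pacing_distances: tuple[float, float] = (0.2, 4.5)  # cm from scar
    contract_dist: float = 0.05  # cm (0.5 mm)
    expand_dist: float = 0.1  # cm (1 mm)
    cv_factors: tuple[float, float] = (0.8, 1.2)
    duration: float = 420.0  # ms, covers activation + full repolarization
    dt: float = 0.1  # ms
    output_interval: float = 2.0  # ms
    stimulus_radius: float = 0.15  # cm
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)
    qoi: QoiConfig = field(default_factory=QoiConfig)
    cell: CellModelParams = field(default_factory=CellModelParams)
    cv_slab: CvSlabSpec = field(default_factory=CvSlabSpec)
    out_dir: str | None = None


def _hrgv_for_run(mesh, sim_cfg: SimulationConfig, pacing_xyz, qoi_cfg: QoiConfig) -> float:
    cfg = replace(sim_cfg, stimulus=Stimulus(center=tuple(pacing_xyz),
                                             radius=sim_cfg.stimulus.radius
                                             if sim_cfg.stimulus else 0.15))
    sol = run_monodomain(mesh, cfg)
    act = activation_map(sol, qoi_cfg)
    rep = repolarization_map(sol, qoi_cfg, act)
    grad = repolarization_gradient(rep, mesh)
    return hrgv(grad, mesh, qoi_cfg)


def run_study_2(cfg: Study2Config) -> tuple[dict, dict]:
    """Full robustness pipeline.

    Returns ``(panels, report)`` where ``panels`` maps input names to
    :class:`HrgvPanel` objects and ``report`` is the consolidated JSON-able
    scenario report (baseline test + 8 scenario entries).
    """
    base_sim = SimulationConfig(duration=cfg.duration, dt=cfg.dt,
                                output_interval=cfg.output_interval,
                                cell=cfg.cell,
                                stop_when_repolarized=True,
                                stimulus=Stimulus(center=(0, 0, 0),
                                                  radius=cfg.stimulus_radius))

    log.info("tuning conductivity variants (factors %s)", cfg.cv_factors)
    cond = conductivity_variants(base_sim, cfg.cv_factors, cfg.cv_slab)
    cv_levels = tuple(cond[k].measured_cv for k in ("low", "baseline", "high"))

    specs = make_study2_specs(cfg.n_patients, cfg.seed)
    bz_names = ("contracted", "original", "expanded")
    cond_names = ("low", "baseline", "high")
    near_bz = np.zeros((len(specs), 3))
    far_bz = np.zeros_like(near_bz)
    near_cond = np.zeros_like(near_bz)
    far_cond = np.zeros_like(near_bz)

    ok: list[int] = []
    for i, spec in enumerate(specs):
        log.info("patient %s", spec.patient_id)
        try:
            mesh = generate_patient(spec, cfg.edge_length)
            near_node, far_node = select_pacing_sites(mesh, cfg.pacing_distances)
            sites = {"near": mesh.nodes[near_node], "far": mesh.nodes[far_node]}
            variants = bz_variants(mesh, cfg.contract_dist, cfg.expand_dist)

            cache: dict[tuple, float] = {}

            def run(key_mesh, key_cfg_name, sim, site_name):
                key = (key_mesh, key_cfg_name, site_name)
                if key not in cache:
                    cache[key] = _hrgv_for_run(
                        variants[key_mesh] if key_mesh in variants else mesh,
                        sim, sites[site_name], cfg.qoi)
                return cache[key]

            for j, vname in enumerate(bz_names):
                for site, arr in (("near", near_bz), ("far", far_bz)):
                    arr[i, j] = run(vname, "baseline", cond["baseline"].config, site)
            for j, cname in enumerate(cond_names):
                for site, arr in (("near", near_cond), ("far", far_cond)):
                    if cname == "baseline":
                        arr[i, j] = run("original", "baseline",
                                        cond["baseline"].config, site)
                    else:
                        arr[i, j] = run("original", cname, cond[cname].config, site)
            ok.append(i)
        except Exception:
            log.exception("patient %s failed; excluded from the panels",
                          spec.patient_id)

    if len(ok) < 2:
        raise RuntimeError("study 2 failed: fewer than 2 patients succeeded")
    ids = tuple(specs[i].patient_id for i in ok)
    panel_bz = HrgvPanel(near_bz[ok], far_bz[ok], bz_names, ids, baseline_index=1)
    panel_cond = HrgvPanel(near_cond[ok], far_cond[ok], cond_names, ids,
                           baseline_index=1)

    rob = replace(cfg.robustness, cv_levels=cv_levels)
    t0, p0, degen0 = paired_t_one_sided(panel_bz.near[:, 1], panel_bz.far[:, 1])
    baseline = ScenarioResult(scenario="baseline_original", t=t0, p=p0,
                              significant=p0 < rob.alpha, degenerate=degen0)

    scenarios = {
        "bz": [
            systematic_scenario_test(panel_bz, "contracted", rob),
            systematic_scenario_test(panel_bz, "expanded", rob),
            worst_case_test(panel_bz, rob),
            mc_fraction_significant(panel_bz, rob),
        ],
        "conductivity": [
            systematic_scenario_test(panel_cond, "low", rob),
            systematic_scenario_test(panel_cond, "high", rob),
            mc_fraction_significant(panel_cond, rob),
            cv_normal_sampling(panel_cond, rob),
        ],
    }

    report = {
        "study": "hrgv_robustness",
        "seed": cfg.seed,
        "alpha": rob.alpha,
        "n_patients": panel_bz.n_patients,
        "config_hash": _config_hash({"edge": cfg.edge_length,
                                     "pacing": cfg.pacing_distances,
                                     "cv_factors": cfg.cv_factors,
                                     "seed": cfg.seed}),
        "cv_levels_cm_per_s": list(cv_levels),
        "conductivity_variants": {
            k: {"cv_factor": v.cv_factor, "measured_cv": v.measured_cv,
                "sigma_f": v.config.conductivity_fiber,
                "sigma_c": v.config.conductivity_cross}
            for k, v in cond.items()
        },
        "baseline": baseline.to_dict(),
        "scenarios": {
            inp: [s.to_dict() for s in entries]
            for inp, entries in scenarios.items()
        },
    }
    validate_report(report)

    panels = {"bz": panel_bz, "conductivity": panel_cond}
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, panel in panels.items():
            panel.to_frame().to_csv(out / f"study2_panel_{name}.csv", index=False)
        (out / "study2_report.json").write_text(json.dumps(report, indent=2))
        (out / "study2_report.md").write_text(render_report_markdown(report))
    return panels, report


# ---------------------------------------------------------------------------
# Report schema / rendering
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": ["study", "seed", "alpha", "n_patients", "baseline", "scenarios"],
    "scenario_required": ["scenario", "degenerate"],
    "n_scenario_entries": 8,
}


def validate_report(report: dict) -> None:
    """Structural validation of the robustness report against the schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key: {key}")
    entries = [e for v in report["scenarios"].values() for e in v]
    if len(entries) != REPORT_SCHEMA["n_scenario_entries"]:
        raise ValueError(
            f"report must contain exactly {REPORT_SCHEMA['n_scenario_entries']} "
            f"scenario entries, found {len(entries)}")
    for e in entries + [report["baseline"]]:
        for key in REPORT_SCHEMA["scenario_required"]:
            if key not in e:
                raise ValueError(f"scenario entry missing key: {key}")
        if "fraction_significant" in e and not 0 <= e["fraction_significant"] <= 1:
            raise ValueError("fraction_significant out of [0, 1]")
        if "p" in e and not 0 <= e["p"] <= 1:
            raise ValueError("p-value out of [0, 1]")


def render_report_markdown(report: dict) -> str:
    lines = [
        "# HRGV robustness report",
        "",
        f"- patients: {report['n_patients']}",
        f"- seed: {report['seed']}, alpha: {report['alpha']}",
        f"- config hash: {report.get('config_hash', 'n/a')}",
        "",
        "## Baseline (original inputs)",
        _scenario_line(report["baseline"]),
    ]
    for inp, entries in report["scenarios"].items():
        lines += ["", f"## Input: {inp}"]
        lines += [_scenario_line(e) for e in entries]
    lines.append("")
    return "\n".join(lines)


def _scenario_line(e: dict) -> str:
    if "fraction_significant" in e:
        return (f"- {e['scenario']}: fraction significant = "
                f"{e['fraction_significant']:.4f} (n = {e['n_samples']}, "
                f"seed = {e['seed']})")
    flag = "significant" if e.get("significant") else "not significant"
    degen = ", degenerate" if e.get("degenerate") else ""
    return f"- {e['scenario']}: t = {e['t']:.4g}, p = {e['p']:.4g} ({flag}{degen})"
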