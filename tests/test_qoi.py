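"""QoI extraction: maps, gradients, HRGV, pseudo-ECG properties."""

import numpy as np
import pytest

from psmcred.mesh import BZ, HEALTHY, SCAR
from psmcred.monodomain import SimulationConfig, VoltageSolution
from psmcred.qoi import (
    QoiConfig,
    activation_map,
    hrgv,
    normalized_activation_time,
    pseudo_ecg,
    repolarization_gradient,
    repolarization_map,
)
from psmcred.surface import distance_to_scar_surface

from conftest import make_plain_slab, make_scar_block_slab


def synthetic_solution(times, voltages):
    """VoltageSolution from an explicit (T, N) array."""
    return VoltageSolution(times=np.asarray(times, dtype=float),
                           voltage=np.asarray(voltages, dtype=float))


class TestActivationMap:
    def test_linear_interpolation_of_crossing(self):
        # node crosses -20 mV halfway between t=1 and t=2
        sol = synthetic_solution([0, 1, 2], [[-85.0], [-40.0], [0.0]])
        amap = activation_map(sol, QoiConfig())
        assert amap[0] == pytest.approx(1.5)

    def test_quiescent_all_sentinels(self):
        sol = synthetic_solution([0, 1, 2], np.full((3, 4), -85.0))
        assert np.isnan(activation_map(sol, QoiConfig())).all()

    def test_threshold_above_peak_all_sentinels(self):
        sol = synthetic_solution([0, 1], [[-85.0, -85.0], [-30.0, -25.0]])
        amap = activation_map(sol, QoiConfig(activation_threshold=10.0))
        assert np.isnan(amap).all()


class TestRepolarizationMap:
    def test_ordering_invariant(self):
        v = np.array([[-85.0], [0.0], [20.0], [-60.0], [-80.0]])
        sol = synthetic_solution([0, 1, 2, 3, 4], v)
        cfg = QoiConfig()
        act = activation_map(sol, cfg)
        rep = repolarization_map(sol, cfg, act)
        assert rep[0] > act[0]
        # crossing of -70 between t=3 (-60) and t=4 (-80): interpolate
        assert rep[0] == pytest.approx(3.5)

    def test_truncated_run_gives_sentinel(self):
        v = np.array([[-85.0], [0.0], [20.0], [10.0]])
        sol = synthetic_solution([0, 1, 2, 3], v)
        cfg = QoiConfig()
        rep = repolarization_map(sol, cfg)
        assert np.isnan(rep[0])

    def test_unactivated_node_sentinel(self):
        v = np.full((5, 1), -85.0)
        sol = synthetic_solution(np.arange(5.0), v)
        assert np.isnan(repolarization_map(sol, QoiConfig())[0])

    def test_apd_matches_fine_reference_integration(self):
        """Tissue-free check: 0-D action potential duration at -70 mV agrees
        with an independent scipy LSODA integration within 2 ms."""
        from scipy.integrate import solve_ivp

        from psmcred.cellmodel import (
            CellModelParams,
            apd_at_threshold,
            simulate_single_cell,
        )

        cell = CellModelParams()
        p = cell.healthy
        times, u = simulate_single_cell(p, 400.0, dt=0.01)
        apd = apd_at_threshold(times, u, cell.u_at(-20.0), cell.u_at(-70.0))

        def rhs(t, y):
            uu, h = y
            du = h * uu * uu * (1 - uu) / p.tau_in - uu / p.tau_out
            if t < 1.0:
                du += 1.0
            dh = (1 - h) / p.tau_open if uu < p.u_gate else -h / p.tau_close
            return [du, dh]

        ref = solve_ivp(rhs, (0, 400), [0.0, 1.0], max_step=0.5,
                        dense_output=True, rtol=1e-8, atol=1e-10)
        tt = np.linspace(0, 400, 40_001)
        apd_ref = apd_at_threshold(tt, ref.sol(tt)[0], cell.u_at(-20.0), cell.u_at(-70.0))
        assert apd == pytest.approx(apd_ref, abs=2.0)


class TestNormalizedActivationTime:
    def test_arithmetic(self):
        mesh = make_plain_slab((1.0, 0.2, 0.2), 0.1)
        act = np.full(mesh.n_nodes, np.nan)
        # probe at (1, 0.1, 0.1); pacing node at origin-> nearest node 0
        probe = (1.0, 0.1, 0.1)
        probe_node = int(np.linalg.norm(mesh.nodes - np.array(probe), axis=1).argmin())
        act[probe_node] = 10.0
        dist = np.linalg.norm(mesh.nodes[probe_node] - mesh.nodes[0])
        assert normalized_activation_time(act, mesh, 0, probe) == pytest.approx(10.0 / dist)

    def test_zero_distance_rejected(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        act = np.zeros(mesh.n_nodes)
        with pytest.raises(ValueError):
            normalized_activation_time(act, mesh, 0, tuple(mesh.nodes[0]))

    def test_unactivated_probe_rejected(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        act = np.full(mesh.n_nodes, np.nan)
        with pytest.raises(ValueError):
            normalized_activation_time(act, mesh, 0, (0.4, 0.2, 0.2))


class TestRepolarizationGradient:
    def test_exact_on_linear_field_x(self):
        mesh = make_plain_slab((0.6, 0.4, 0.2), 0.1)
        rep = 40.0 * mesh.nodes[:, 0]
        g = repolarization_gradient(rep, mesh)
        np.testing.assert_allclose(g, 40.0, rtol=1e-12)

    def test_zero_on_constant_field(self):
        mesh = make_plain_slab((0.6, 0.4, 0.2), 0.1)
        g = repolarization_gradient(np.full(mesh.n_nodes, 7.0), mesh)
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_exact_magnitude_on_general_linear_field(self):
        mesh = make_plain_slab((0.6, 0.4, 0.2), 0.1)
        a, b, c = 12.0, -30.0, 5.0
        rep = a * mesh.nodes[:, 0] + b * mesh.nodes[:, 1] + c * mesh.nodes[:, 2]
        g = repolarization_gradient(rep, mesh)
        np.testing.assert_allclose(g, np.sqrt(a * a + b * b + c * c), rtol=1e-12)

    def test_undefined_nodes_mark_elements(self):
        mesh = make_plain_slab((0.6, 0.4, 0.2), 0.1)
        rep = 40.0 * mesh.nodes[:, 0]
        rep[0] = np.nan
        g = repolarization_gradient(rep, mesh)
        touching = np.any(mesh.elements == 0, axis=1)
        assert np.isnan(g[touching]).all()
        assert np.isfinite(g[~touching]).all()


@pytest.fixture(scope="module")
def scar_slab():
    return make_scar_block_slab(extent=(2.4, 0.6, 0.3), spacing=0.06,
                                scar_lo=(0.3, 0.18, 0.0), scar_hi=(0.66, 0.42, 0.3))


class TestHrgv:

    def test_matches_brute_force_condition_sum(self, scar_slab):
        mesh = scar_slab
        rep = 40.0 * mesh.nodes[:, 0]  # gradient 40 ms/cm everywhere
        g = repolarization_gradient(rep, mesh)
        cfg = QoiConfig()
        got = hrgv(g, mesh, cfg)
        # exhaustive per-element oracle over conditions (a)-(c)
        d = distance_to_scar_surface(mesh, mesh.centroids)
        w = 0.0
        for e in range(mesh.n_elements):
            if mesh.tissue_class[e] == SCAR:
                continue
            if d[e] > cfg.scar_proximity_radius:
                continue
            if not (g[e] > cfg.gradient_threshold):
                continue
            w += mesh.element_volumes[e]
        assert got == pytest.approx(w, rel=1e-12)
        assert 0 < got < mesh.element_volumes.sum()

    def test_gradient_below_threshold_gives_zero(self, scar_slab):
        mesh = scar_slab
        g = repolarization_gradient(20.0 * mesh.nodes[:, 0], mesh)
        assert hrgv(g, mesh, QoiConfig()) == 0.0

    def test_no_scar_gives_zero(self):
        mesh = make_plain_slab((0.6, 0.4, 0.2), 0.1)
        g = np.full(mesh.n_elements, 100.0)
        assert hrgv(g, mesh, QoiConfig()) == 0.0

    def test_monotone_in_threshold(self, scar_slab):
        mesh = scar_slab
        rng = np.random.default_rng(4)
        rep = 35.0 * mesh.nodes[:, 0] + rng.normal(0, 1.0, mesh.n_nodes)
        g = repolarization_gradient(rep, mesh)
        v30 = hrgv(g, mesh, QoiConfig(gradient_threshold=30.0))
        v25 = hrgv(g, mesh, QoiConfig(gradient_threshold=25.0))
        assert v25 >= v30

    def test_bounded_by_proximity_volume(self, scar_slab):
        mesh = scar_slab
        g = np.full(mesh.n_elements, 1e9)
        cfg = QoiConfig()
        total = hrgv(g, mesh, cfg)
        d = distance_to_scar_surface(mesh, mesh.centroids)
        bound = mesh.element_volumes[(mesh.tissue_class != SCAR)
                                     & (d <= cfg.scar_proximity_radius)].sum()
        assert total == pytest.approx(bound, rel=1e-12)


class TestPseudoEcg:
    def test_uniform_voltage_gives_zero_trace(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        sol = synthetic_solution([0, 1], np.full((2, mesh.n_nodes), -30.0))
        phi = pseudo_ecg(sol, mesh, (3.0, 0.1, 0.1))
        np.testing.assert_allclose(phi, 0.0, atol=1e-9)

    def test_linearity_in_voltage(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, mesh.n_nodes))
        phi1 = pseudo_ecg(synthetic_solution([0, 1, 2], v), mesh, (3.0, 0.1, 0.1))
        phi2 = pseudo_ecg(synthetic_solution([0, 1, 2], 2 * v), mesh, (3.0, 0.1, 0.1))
        np.testing.assert_allclose(phi2, 2 * phi1, rtol=1e-12)

    def test_amplitude_decays_with_distance(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        v = np.tile(-85.0 + 120.0 / (1 + np.exp(-(0.2 - mesh.nodes[:, 0]) / 0.05)),
                    (2, 1))
        near = pseudo_ecg(synthetic_solution([0, 1], v), mesh, (2.0, 0.1, 0.1))
        far = pseudo_ecg(synthetic_solution([0, 1], v), mesh, (4.0, 0.1, 0.1))
        assert np.abs(far).max() < np.abs(near).max()

    def test_wavefront_approaching_electrode_is_positive(self):
        """Sign convention on a tiny fixture, checked against direct
        numerical evaluation of the lead-field integral."""
        mesh = make_plain_slab((0.4, 0.1, 0.1), 0.05)
        # sigmoidal upstroke front at x0 = 0.2 moving toward electrode at +x
        x = mesh.nodes[:, 0]
        v = -85.0 + 120.0 / (1 + np.exp(-(0.2 - x) / 0.03))
        sol = synthetic_solution([0.0, 1.0], np.tile(v, (2, 1)))
        cfg = SimulationConfig()
        phi = pseudo_ecg(sol, mesh, (3.0, 0.05, 0.05), config=cfg)
        assert phi[0] > 0
        # direct evaluation: -k sum vol * (sigma grad V) . grad(1/r)
        from psmcred.monodomain import element_conductivities

        sigma = element_conductivities(mesh, cfg)
        grads = np.einsum("eij,ej->ei", mesh.shape_gradients, v[mesh.elements])
        rvec = mesh.centroids - np.array([3.0, 0.05, 0.05])
        r = np.linalg.norm(rvec, axis=1)
        ginv = -rvec / (r**3)[:, None]
        direct = -np.sum(mesh.element_volumes
                         * np.einsum("ei,ei->e", np.einsum("eij,ej->ei", sigma, grads), ginv))
        assert phi[0] == pytest.approx(direct, rel=1e-9)

    def test_electrode_inside_mesh_rejected(self):
        mesh = make_plain_slab((0.4, 0.2, 0.2), 0.1)
        sol = synthetic_solution([0], np.zeros((1, mesh.n_nodes)))
        with pytest.raises(ValueError):
            pseudo_ecg(sol, mesh, (0.2, 0.1, 0.1))
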