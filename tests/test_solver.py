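"""Darcy pressure stage and implicit transport stage."""

import numpy as np
import pytest

from cedsim import (
    SimulationConfig,
    SimulationState,
    SourceSpec,
    TransportOperator,
    advance_concentration,
    run_simulation,
    solve_pressure,
    ul_per_min,
)
from cedsim.fields import ScalarField, SymmetricTensorField, mat_to_vec6
from cedsim.mesh import build_mesh


def ball_mesh(n, h=1.2):
    idx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2
    mask = np.sqrt(((idx - c) ** 2).sum(axis=0)) <= (n - 1) / 2
    return build_mesh(mask, h)


def iso_field(kappa, mesh):
    return SymmetricTensorField.constant(
        kappa * np.eye(3), mesh.shape, mesh.voxel_size, mesh.mask
    )


def test_rate_conversion():
    assert ul_per_min(0.3) == pytest.approx(0.005)


class TestPressure:
    def test_zero_rate_gives_uniform_pressure(self):
        mesh = ball_mesh(15)
        src = SourceSpec(voxel=(7, 7, 7), segments=[(0.0, 0.0)], p_boundary=40.0)
        sol = solve_pressure(mesh, iso_field(1e-6, mesh), src)
        np.testing.assert_allclose(sol.pressure, 40.0, atol=1e-6)
        assert np.abs(sol.interior_flux).max() < 1e-16

    def test_point_source_matches_analytic_ball_solution(self):
        """p - p_b = Q/(4 pi kappa) (1/r - 1/R) for a central source in a
        homogeneous ball with p = p_b on the surface."""
        n, h, kappa, q = 25, 1.2, 1e-6, 0.005
        mesh = ball_mesh(n, h)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, q)])
        sol = solve_pressure(mesh, iso_field(kappa, mesh), src)
        r = np.linalg.norm((mesh.cells - (n - 1) / 2) * h, axis=1)
        R = (n - 1) / 2 * h
        band = (r >= 3 * h) & (r <= R / 2)
        exact = q / (4 * np.pi * kappa) * (1 / r[band] - 1 / R)
        rel = np.abs(sol.pressure[band] - exact) / exact
        assert rel.max() < 0.05

    def test_discrete_conservation_and_global_balance(self):
        mesh = ball_mesh(15)
        src = SourceSpec(voxel=(7, 7, 7), segments=[(0.0, 0.01)])
        sol = solve_pressure(mesh, iso_field(2e-6, mesh), src)
        assert sol.conservation_residual() < 1e-10
        assert sol.boundary_flux.sum() == pytest.approx(0.01, rel=1e-8)

    def test_conductivity_scaling_linearity(self):
        """Fixed-rate Darcy: scaling kappa by s scales (p - p_b) by 1/s."""
        mesh = ball_mesh(13)
        src = SourceSpec(voxel=(6, 6, 6), segments=[(0.0, 0.02)], p_boundary=0.0)
        p1 = solve_pressure(mesh, iso_field(1e-6, mesh), src).pressure
        p2 = solve_pressure(mesh, iso_field(5e-6, mesh), src).pressure
        np.testing.assert_allclose(p1, 5.0 * p2, rtol=1e-8)

    def test_rotation_equivariance_of_anisotropic_solve(self):
        """Rotating an anisotropic conductivity field by 90 degrees rotates
        the pressure field identically."""
        n = 12
        rng = np.random.default_rng(8)
        mask = np.ones((n, n, n), dtype=bool)
        a = rng.standard_normal((n, n, n, 3, 3))
        spd = 1e-6 * (np.einsum("...ik,...jk->...ij", a, a) / 3 + 0.3 * np.eye(3))
        mesh = build_mesh(mask, 1.0)
        src = SourceSpec(voxel=(5, 4, 6), segments=[(0.0, 0.01)])
        sol = solve_pressure(mesh, SymmetricTensorField.from_matrices(spd, 1.0, mask), src)
        p_vol = mesh.cells_to_volume(sol.pressure)

        # rotate 90 degrees about z: (x, y, z) -> (y, N-1-x, z)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        spd_r = np.einsum("ij,...jk,lk->...il", rot, spd, rot)
        spd_r = np.rot90(spd_r, k=1, axes=(0, 1))
        src_r = SourceSpec(voxel=(n - 1 - 4, 5, 6), segments=[(0.0, 0.01)])
        sol_r = solve_pressure(
            mesh, SymmetricTensorField.from_matrices(spd_r, 1.0, mask), src_r
        )
        p_vol_r = mesh.cells_to_volume(sol_r.pressure)
        np.testing.assert_allclose(np.rot90(p_vol, k=1, axes=(0, 1)), p_vol_r, atol=1e-6 * np.abs(p_vol).max())

    def test_fixed_dp_mode_recovers_rate(self):
        """Prescribing the Δp that a fixed-rate solve produced recovers the
        same rate (the two source modes are consistent)."""
        mesh = ball_mesh(15)
        k = iso_field(1e-6, mesh)
        src = SourceSpec(voxel=(7, 7, 7), segments=[(0.0, 0.01)])
        sol = solve_pressure(mesh, k, src)
        dp = sol.pressure[sol.source_cells[0]] - src.p_boundary
        src_dp = SourceSpec(voxel=(7, 7, 7), mode="fixed_dp", dp=float(dp))
        sol2 = solve_pressure(mesh, k, src_dp)
        assert sol2.rate == pytest.approx(0.01, rel=1e-6)
        np.testing.assert_allclose(
            sol2.pressure, sol.pressure, rtol=1e-4, atol=1e-5 * sol.pressure.max()
        )

    def test_source_outside_mask_raises(self):
        mesh = ball_mesh(15)
        with pytest.raises(ValueError):
            solve_pressure(
                mesh, iso_field(1e-6, mesh), SourceSpec(voxel=(0, 0, 0), segments=[(0.0, 1.0)])
            )


class TestTransport:
    def test_heat_kernel_oracle(self):
        """Zero velocity, isotropic tensor, point release: the discrete field
        approaches the continuum Gaussian once sigma > 3h."""
        n, h, d = 32, 1.0, 0.5
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), h)
        R = SymmetricTensorField.constant(d * np.eye(3), (n, n, n), h)
        phi = np.ones(mesh.n_cells)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, 0.0)])
        c0 = np.zeros(mesh.n_cells)
        c0[mesh.cell_index[n // 2, n // 2, n // 2]] = 1.0 / mesh.cell_volume
        state = SimulationState(mesh, c0, 0.0, flow=None)
        dt = 0.1
        advance_concentration(state, R, phi, src, dt, n_steps=110)
        t = state.time
        assert np.sqrt(2 * d * t) > 3 * h
        r2 = (((mesh.cells - n // 2) * h) ** 2).sum(axis=1)
        exact = (4 * np.pi * d * t) ** -1.5 * np.exp(-r2 / (4 * d * t))
        err = np.linalg.norm(state.concentration - exact) / np.linalg.norm(exact)
        assert err < 0.05

    def test_closed_domain_mass_balance(self):
        n, h = 16, 1.2
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), h)
        k = SymmetricTensorField.constant(1e-6 * np.eye(3), (n,) * 3, h)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, 0.005)])
        flow = solve_pressure(mesh, k, src)
        Rd = SymmetricTensorField.constant(1e-12 * np.eye(3), (n,) * 3, h)
        phi = np.full(mesh.n_cells, 0.2)
        state = SimulationState(mesh, np.zeros(mesh.n_cells), 0.0, flow=flow)
        advance_concentration(state, Rd, phi, src, dt=1.0, n_steps=200)
        infused = 0.005 * 200
        in_domain = state.in_domain_mass(phi)
        assert state.ledger.closure(in_domain) < 1e-6
        # plume has not reached the boundary: everything infused is inside
        assert abs(in_domain - infused) / infused < 1e-6

    def test_maximum_principle_upwind(self):
        """Implicit upwind advection keeps C within [0, C_in]."""
        n, h = 14, 1.2
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), h)
        k = SymmetricTensorField.constant(1e-6 * np.eye(3), (n,) * 3, h)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, 0.05)], c_in=1.0)
        flow = solve_pressure(mesh, k, src)
        Rd = SymmetricTensorField.constant(1e-12 * np.eye(3), (n,) * 3, h)
        phi = np.full(mesh.n_cells, 0.2)
        state = SimulationState(mesh, np.zeros(mesh.n_cells), 0.0, flow=flow)
        advance_concentration(state, Rd, phi, src, dt=5.0, n_steps=300)
        assert state.concentration.min() >= -1e-12
        assert state.concentration.max() <= 1.0 + 1e-9

    def test_van_leer_conserves_mass(self):
        n, h = 14, 1.2
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), h)
        k = SymmetricTensorField.constant(1e-6 * np.eye(3), (n,) * 3, h)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, 0.01)])
        flow = solve_pressure(mesh, k, src)
        Rd = SymmetricTensorField.constant(1e-12 * np.eye(3), (n,) * 3, h)
        phi = np.full(mesh.n_cells, 0.2)
        state = SimulationState(mesh, np.zeros(mesh.n_cells), 0.0, flow=flow)
        advance_concentration(
            state, Rd, phi, src, dt=2.0, n_steps=150, advection="van_leer"
        )
        assert state.ledger.closure(state.in_domain_mass(phi)) < 1e-6

    def test_bad_porosity_rejected(self):
        n = 8
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), 1.0)
        Rd = SymmetricTensorField.constant(1e-12 * np.eye(3), (n,) * 3, 1.0)
        src = SourceSpec(voxel=(4, 4, 4), segments=[(0.0, 0.0)])
        with pytest.raises(ValueError):
            TransportOperator(mesh, None, Rd, np.full(mesh.n_cells, 1.5), src, dt=1.0)
        with pytest.raises(ValueError):
            TransportOperator(mesh, None, Rd, np.full(mesh.n_cells, 1.5), src, dt=-1.0)


class TestDifferenceEvolution:
    """Discrete analogue of the evolution identity for dC = C_R - C_D."""

    def test_difference_equation_residual_vanishes(self):
        """phi d(dC)/dt + adv_R(dC) - diff_R(dC) = (A_R - A_D) C_D holds to
        solver precision: the two model runs and the difference identity are
        mutually consistent (the right side vanishes when R = D)."""
        n, h = 12, 1.2
        rng = np.random.default_rng(6)
        mesh = build_mesh(np.ones((n, n, n), dtype=bool), h)
        # two distinct diagonal (cross-free) tensor fields
        kr = 1e-6 * (0.5 + rng.random((n, n, n)))
        kd = 1e-6 * (0.5 + rng.random((n, n, n)))
        KR = SymmetricTensorField.from_matrices(kr[..., None, None] * np.eye(3), h)
        KD = SymmetricTensorField.from_matrices(kd[..., None, None] * np.eye(3), h)
        RR = SymmetricTensorField.constant(2e-7 * np.eye(3), (n,) * 3, h)
        DD = SymmetricTensorField.constant(1e-7 * np.eye(3), (n,) * 3, h)
        phi = np.full(mesh.n_cells, 0.2)
        src = SourceSpec(voxel=(n // 2,) * 3, segments=[(0.0, 0.01)])
        dt = 2.0

        flows = {m: solve_pressure(mesh, K, src) for m, K in (("R", KR), ("D", KD))}
        ops = {
            "R": TransportOperator(mesh, flows["R"], RR, phi, src, dt),
            "D": TransportOperator(mesh, flows["D"], DD, phi, src, dt),
        }
        cR = np.zeros(mesh.n_cells)
        cD = np.zeros(mesh.n_cells)
        for _ in range(30):
            cR_n, cD_n = cR, cD
            cR, _ = ops["R"].step(cR)
            cD, _ = ops["D"].step(cD)
        # residual of the difference identity, assembled from the operators
        dC, dC_n = cR - cD, cR_n - cD_n
        sR = ops["R"].storage
        lhs = ops["R"].A @ dC - sR * dC_n
        rhs = (ops["D"].A - ops["R"].A) @ cD  # = -(A_R - A_D) C_D
        scale = np.abs(ops["R"].A @ cR).max()
        assert np.abs(lhs - rhs).max() / scale < 1e-9

    def test_identical_tensors_give_identical_concentrations(self):
        """When the R-model is fed the D-model's tensors, dC == 0."""
        from cedsim import CalibrationConstants, build_drug_tensors, generate_labels
        from cedsim import estimate_water_tensors
        from cedsim.workflows import build_phantom, resolve_source_voxel
        from cedsim.config import RunConfig

        cfg = RunConfig(seed=2, shape=(16, 16, 16))
        data = build_phantom(cfg)
        water = estimate_water_tensors(data, "cumulant")
        # force R := D so the two models carry identical fields
        drug = build_drug_tensors(water.Dw, water.Dw, data.labels)
        mesh = build_mesh(data.labels.mask, cfg.voxel_size)
        src = SourceSpec.constant(resolve_source_voxel(data.labels, "gm_center"), 1.8)
        sim = SimulationConfig(dt=5.0, t_end=500.0)
        out = {}
        for model in ("R", "D"):
            sim_m = SimulationConfig(model=model, dt=5.0, t_end=500.0)
            out[model] = run_simulation(mesh, drug, src, sim_m).snapshots[500.0]
        assert np.abs(out["R"] - out["D"]).max() < 1e-12


class TestOrchestration:
    def _tiny_setup(self):
        from cedsim import build_drug_tensors
        from cedsim import estimate_water_tensors
        from cedsim.config import RunConfig
        from cedsim.workflows import build_phantom, resolve_source_voxel

        cfg = RunConfig(seed=4, shape=(16, 16, 16))
        data = build_phantom(cfg)
        water = estimate_water_tensors(data, "cumulant")
        drug = build_drug_tensors(water.Dw, water.Rw, data.labels)
        mesh = build_mesh(data.labels.mask, cfg.voxel_size)
        return mesh, drug, data

    def test_zero_t_end_returns_initial_state(self):
        mesh, drug, data = self._tiny_setup()
        from cedsim.workflows import resolve_source_voxel

        src = SourceSpec.constant(resolve_source_voxel(data.labels, "gm_center"), 1.8)
        res = run_simulation(mesh, drug, src, SimulationConfig(dt=1.0, t_end=0.0, snapshot_times=(0.0,)))
        assert (res.snapshots[0.0] == 0).all()

    def test_runs_are_deterministic(self):
        mesh, drug, data = self._tiny_setup()
        from cedsim.workflows import resolve_source_voxel

        src = SourceSpec.constant(resolve_source_voxel(data.labels, "gm_center"), 1.8)
        cfg = SimulationConfig(dt=5.0, t_end=250.0)
        a = run_simulation(mesh, drug, src, cfg).snapshots[250.0]
        b = run_simulation(mesh, drug, src, cfg).snapshots[250.0]
        np.testing.assert_array_equal(a, b)

    def test_schedule_switches_rate(self):
        """Two-stage schedule (slower then faster) infuses the right total."""
        mesh, drug, data = self._tiny_setup()
        from cedsim.workflows import resolve_source_voxel

        vox = resolve_source_voxel(data.labels, "gm_center")
        src = SourceSpec(
            voxel=vox,
            segments=[(0.0, ul_per_min(2.5)), (120.0, ul_per_min(5.0))],
        )
        res = run_simulation(mesh, drug, src, SimulationConfig(dt=5.0, t_end=240.0))
        expected = ul_per_min(2.5) * 120 + ul_per_min(5.0) * 120
        assert res.ledger_rows[-1]["infused"] == pytest.approx(expected, rel=1e-12)
        assert res.ledger_rows[-1]["closure"] < 1e-6
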