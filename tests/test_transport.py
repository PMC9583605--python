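"""Constitutive relations and the coupled MCPA transport solver."""

import numpy as np
import pytest

from mcpafate import (
    Mesh,
    ReactionParams,
    TransportParams,
    VanGenuchtenLayer,
    apply_initial_mcpa,
    dispersion_tensor,
    freundlich_sorbed,
    millington_quirk_Ds,
    monod_rate,
    simulate_scenario,
)
from mcpafate.hydraulics import RichardsColumn, WaterState
from mcpafate.precip import build_precip, constant_schedule
from mcpafate.transport import (
    MCPAState,
    TransportSimulator,
    equilibrium_partition,
)


@pytest.fixture(scope="module")
def tp():
    return TransportParams()


class TestFreundlich:
    def test_zero_and_linear_limits(self, tp):
        assert freundlich_sorbed(0.0, tp) == 0.0
        lin = TransportParams(n_F=1.0)
        ratio = freundlich_sorbed(np.array([1.0, 10.0, 1e4]), lin)
        assert np.allclose(ratio / np.array([1.0, 10.0, 1e4]), lin.K_F)

    def test_power_law_value(self, tp):
        # 1.79e-3 * (1e6)^0.86 evaluated independently
        assert freundlich_sorbed(1e6, tp) == pytest.approx(258.7337190,
                                                           rel=1e-8)

    def test_negative_rejected(self, tp):
        with pytest.raises(ValueError):
            freundlich_sorbed(-1.0, tp)


class TestMillingtonQuirk:
    def test_algebraic_limits(self):
        assert millington_quirk_Ds(0.49, 0.49, 6.33e-10) == pytest.approx(
            6.33e-10 * 0.49 ** (4.0 / 3.0))
        assert millington_quirk_Ds(0.0, 0.49, 6.33e-10) == 0.0

    def test_saturation_rise_83_to_98_increases_Ds_by_74_percent(self):
        """(0.98/0.83)^(10/3) = 1.7398: a > 70% diffusivity increase."""
        lo = millington_quirk_Ds(0.83 * 0.49, 0.49, 6.33e-10)
        hi = millington_quirk_Ds(0.98 * 0.49, 0.49, 6.33e-10)
        assert hi / lo == pytest.approx(1.739775769, rel=1e-8)
        assert (hi / lo - 1.0) > 0.70


class TestDispersionTensor:
    def test_zero_flow_is_isotropic_diffusion(self, tp):
        D = dispersion_tensor(np.array([0.0, 0.0]), 0.4, tp, 2e-10)
        assert np.allclose(D, 2e-10 * np.eye(2))

    def test_vertical_flow_axis_alignment(self, tp):
        q = np.array([0.0, 4e-8])  # downward
        D = dispersion_tensor(q, 0.4, tp, 0.0)
        v = 4e-8 / 0.4
        assert D[1, 1] == pytest.approx(tp.lambda_L * v)
        assert D[0, 0] == pytest.approx(tp.lambda_T * v)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-25)

    def test_eigenvalues_for_any_direction(self, tp):
        """Spectrum is (lambda_L |v| + D_s, lambda_T |v| + D_s) always."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            q = rng.normal(size=2) * 1e-7
            D = dispersion_tensor(q, 0.37, tp, 1.5e-10)
            v = np.linalg.norm(q) / 0.37
            ev = np.sort(np.linalg.eigvalsh(D))
            assert ev[0] == pytest.approx(tp.lambda_T * v + 1.5e-10)
            assert ev[1] == pytest.approx(tp.lambda_L * v + 1.5e-10)


class TestMonod:
    def test_half_saturation_and_zero_biomass(self):
        rp = ReactionParams()
        R = monod_rate(rp.K_M, 12.21, 1240.0, rp)
        assert R == pytest.approx(0.5 * rp.mu_max * 1240.0 * 12.21)
        assert monod_rate(1e5, 0.0, 1240.0, rp) == 0.0

    def test_first_order_limit(self):
        """At C = 0.01 K_M the multiplicative limit deviates < 1%."""
        rp = ReactionParams()
        C = 0.01 * rp.K_M
        exact = monod_rate(C, 12.21, 1240.0, rp)
        linear = rp.mu_max * 1240.0 * 12.21 * C / rp.K_M
        assert abs(linear - exact) / exact < 0.01


class TestPartitioning:
    def test_equilibrium_roundtrip(self, tp):
        c_tot = np.array([1e2, 1e4, 5e5])
        C_L, C_S = equilibrium_partition(c_tot, 0.4, 1240.0, tp)
        assert np.allclose(0.4 * C_L + 1240.0 * C_S, c_tot, rtol=1e-9)
        assert np.allclose(C_S, freundlich_sorbed(C_L, tp), rtol=1e-9)

    def test_dissolved_fraction_falls_with_total_concentration(self, tp):
        """n_F < 1: proportionally more MCPA sorbs as C_L decreases."""
        c_tot = np.logspace(1, 6, 12)
        C_L, C_S = equilibrium_partition(c_tot, 0.4, 1240.0, tp)
        frac = 0.4 * C_L / c_tot
        assert np.all(np.diff(frac) > 0)


class TestInitialCondition:
    def test_applied_mass_and_confinement(self, full_mesh, layers,
                                          steady_state, tp):
        theta = np.repeat(steady_state.theta[:, None], full_mesh.nx, axis=1)
        st = apply_initial_mcpa(full_mesh, layers, theta, tp)
        rho = full_mesh.layer_arrays(layers)["rho_b"]
        V = full_mesh.cell_volumes()
        mass = float(np.sum((theta * st.C_L + rho[:, None] * st.C_S) * V))
        # 2 kg/ha over 0.3 m x 0.1 m: 6 mg MCPA = 269.17 umol C
        assert mass == pytest.approx(269.1655867, rel=1e-6)
        col_mass = ((theta * st.C_L + rho[:, None] * st.C_S) * V).sum(axis=1)
        frac_top = col_mass[full_mesh.y_centers <= 0.025].sum() / mass
        assert frac_top > 0.95
        assert col_mass[full_mesh.y_centers > 0.05].max() < 1e-5 * col_mass.max()

    def test_shallow_mesh_rejected(self, layers, tp):
        shallow = [VanGenuchtenLayer(0.49, 0.0, 12.3, 1.1, 0.5, 1.85e-5,
                                     1240.0, 0.0, 0.01)]
        mesh = Mesh.build(shallow, width=0.05, graded_top=False, dy=2.5e-3)
        with pytest.raises(ValueError):
            apply_initial_mcpa(mesh, shallow, np.full((mesh.ny, mesh.nx), 0.4),
                               tp, application_depth=0.015)


@pytest.fixture(scope="module")
def sand_column():
    layer = VanGenuchtenLayer(0.43, 0.0, 3.63, 1.12, 0.5, 2.31e-5, 1460.0,
                              0.0, 1.0)
    mesh = Mesh.build([layer], width=0.05, graded_top=False).column_mesh()
    return mesh, [layer]


class TestSolver:
    def test_uniform_state_preserved_without_reaction(self, sand_column):
        """R = 0: a spatially uniform C_L is a fixed point of the scheme."""
        mesh, layers = sand_column
        col = RichardsColumn(mesh, layers)
        h = np.full(mesh.ny, -1.0)
        water = WaterState(h, col.theta(h), col.face_fluxes(h, 0.0), 0.0)
        sim = TransportSimulator(mesh, layers, np.zeros((mesh.ny, 1)),
                                 constant_schedule(0.0, 3.0), initial_water=water)
        tp = TransportParams()
        C0 = np.full((mesh.ny, 1), 500.0)
        state = MCPAState(C0.copy(), freundlich_sorbed(C0, tp), 0.0)
        res = sim.run(state, 3.0, decompose_region=False)
        assert np.allclose(res.row_CL[-1], 500.0, rtol=1e-8)

    def test_mass_ledger_closes_without_reaction(self, sand_column):
        """R = 0: storage change equals boundary export to < 1e-6."""
        mesh, layers = sand_column
        sim_res = simulate_scenario(
            mesh, layers, None, constant_schedule(10.0, 10.0), 10.0,
            reaction=ReactionParams(mu_max=1e-30, K_M=1.93e6),
            decompose_region=False)
        assert sim_res.mass_balance_error.max() < 1e-6
        assert sim_res.degraded_cum[-1] / sim_res.initial_mass < 1e-12

    def test_linear_sorption_retardation_factor(self, sand_column):
        """Centroid velocity matches v/R_f with R_f = 1 + rho K_F/theta."""
        mesh, layers = sand_column
        tp = TransportParams(n_F=1.0, lambda_L=0.01, lambda_T=0.004)
        res = simulate_scenario(
            mesh, layers, None, constant_schedule(20.0, 20.0), 20.0,
            transport=tp, reaction=ReactionParams(mu_max=1e-30, K_M=1.93e6),
            decompose_region=False)
        rho = 1460.0
        mass_prof = res.row_CT_mg_kg * (res.y_widths * rho)  # per row
        centroid = (mass_prof @ res.y_centers) / mass_prof.sum(axis=1)
        slope = np.polyfit(res.times_days[5:], centroid[5:], 1)[0]  # [m/d]
        q = 20e-3 / 86400.0
        col = RichardsColumn(mesh, layers)
        st = col.spin_up(20.0)
        i_mid = mesh.ny // 3
        v = q / st.theta[i_mid]
        R_f = 1.0 + rho * tp.K_F / st.theta[i_mid]
        expected = v / R_f * 86400.0
        assert slope == pytest.approx(expected, rel=0.08)

    def test_doubling_mu_max_speeds_removal(self, full_mesh, layers,
                                            steady_state):
        """Residual mass decreases at every time when mu_max doubles."""
        mesh = full_mesh.column_mesh()
        runs = {}
        for f in (1.0, 2.0):
            rp = ReactionParams(mu_max=f * 2.94e-4)
            runs[f] = simulate_scenario(
                mesh, layers, None, build_precip("CLR", 8.0), 8.0,
                reaction=rp, initial_water=steady_state,
                decompose_region=False)
        rem1 = runs[1.0].initial_mass - runs[1.0].degraded_cum
        rem2 = runs[2.0].initial_mass - runs[2.0].degraded_cum
        assert np.all(rem2[1:] <= rem1[1:])

    def test_sorption_equilibrium_after_every_output(self, full_mesh, layers,
                                                     steady_state, tp):
        res = simulate_scenario(
            full_mesh.column_mesh(), layers, None, build_precip("CLR", 5.0),
            5.0, initial_water=steady_state, store_snapshots=True,
            decompose_region=False)
        for snap in res.snapshots:
            assert np.allclose(snap.C_S, freundlich_sorbed(snap.C_L, tp),
                               rtol=1e-6, atol=1e-12)

    def test_mcpa_mass_balance_under_heavy_rain(self, hom_hre_column):
        """Storage + degraded + exported equals the applied mass to <0.1%."""
        assert hom_hre_column.mass_balance_error.max() < 1e-3
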