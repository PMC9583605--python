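"""Shared fixtures: reference column, steady flow, and desk-scale ensembles."""

from __future__ import annotations

import pytest

from mcpafate import (
    Mesh,
    Scenario,
    default_layers,
    rho_b_lookup,
    run_scenario,
    simulate_scenario,
    spin_up,
)
from mcpafate.precip import build_precip


@pytest.fixture(scope="session")
def layers():
    return default_layers()


@pytest.fixture(scope="session")
def topsoil(layers):
    return layers[0]


@pytest.fixture(scope="session")
def full_mesh(layers):
    return Mesh.build(layers, width=0.3)


@pytest.fixture(scope="session")
def rho_lookup(layers):
    return rho_b_lookup(layers)


@pytest.fixture(scope="session")
def steady_state(full_mesh, layers):
    """Spin-up steady flow of the reference column at 0.56 mm/d."""
    return spin_up(full_mesh, layers, 0.56)


@pytest.fixture(scope="session")
def hom_hre_column(full_mesh, layers, steady_state):
    """1-D homogeneous column under the heavy-rain-events forcing, 45 d."""
    return simulate_scenario(
        full_mesh.column_mesh(), layers, None, build_precip("HRE", 45.0),
        45.0, initial_water=steady_state, label="HOM-HRE-1D")


@pytest.fixture(scope="session")
def desk_runs():
    """Desk-preset scenario ensembles shared by the property tests.

    20-day span, n = 3 for stochastic scenarios; identical code paths to the
    full preset.
    """
    span = 20.0
    out = {
        "HOM-CLR": run_scenario(Scenario("HOM", "CLR", t_end_days=span)),
        "HOM-HRE": run_scenario(Scenario("HOM", "HRE", t_end_days=span)),
    }
    for het in ("LOW", "HIGH", "EXTR"):
        out[f"{het}-CLR"] = run_scenario(
            Scenario(het, "CLR", n_realizations=3, t_end_days=span))
    out["EXTR-HRE"] = run_scenario(
        Scenario("EXTR", "HRE", n_realizations=3, t_end_days=span))
    return out


@pytest.fixture(scope="session")
def dispersivity_runs(full_mesh, layers, steady_state):
    """1-D homogeneous CLR runs across the tested dispersivity range."""
    from mcpafate import TransportParams

    runs = {}
    for lam in (0.01, 0.03, 0.1):
        tp = TransportParams(lambda_L=lam, lambda_T=lam / 3.0)
        runs[lam] = simulate_scenario(
            full_mesh.column_mesh(), layers, None, build_precip("CLR", 30.0),
            30.0, transport=tp, initial_water=steady_state,
            label=f"HOM-CLR-lam{lam}")
    return runs
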