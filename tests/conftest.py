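"""Shared fixtures: expensive solves are session-scoped and reused."""

import numpy as np
import pytest

import vesibud as vb


@pytest.fixture(scope="session")
def config():
    return vb.SolverConfig()


@pytest.fixture(scope="session")
def flat_profile(config):
    return vb.solve_shape(vb.capsid_field(0.08, 0.0), config)


@pytest.fixture(scope="session")
def capsid_ladder(config):
    """Capsid profiles at the supplementary coat extents 25, 50, 70 nm."""
    profiles, failures = vb.solve_capsid_ladder([25.0, 50.0, 70.0], config)
    assert not failures
    return profiles


@pytest.fixture(scope="session")
def capsid25(capsid_ladder):
    return capsid_ladder[25.0]


@pytest.fixture(scope="session")
def capsid70(capsid_ladder):
    return capsid_ladder[70.0]


@pytest.fixture(scope="session")
def epsin_b83(config):
    """Single-epsin solve at the nominal range b = 8.3 nm."""
    return vb.solve_shape(vb.single_epsin_field(0.1, 8.3), config)


@pytest.fixture(scope="session")
def calibration(config):
    """Self-consistent b at kappa = 20 k_BT (E_c = 14 k_BT)."""
    return vb.calibrate_b(20.0, solver=config)


@pytest.fixture(scope="session")
def shell_sweep(calibration):
    """Shell-model area sweep at kappa = 20 with the calibrated b."""
    cfg = vb.ExperimentConfig(experiment="area_sweep", model="epsin_shells",
                              b=calibration.b)
    table, profiles, summary = vb.run_area_sweep(cfg)
    return table, profiles, summary


@pytest.fixture(scope="session")
def distribution_profiles(config):
    """Capsid ladder for the Boltzmann distribution (10-80 nm, 5-nm steps)."""
    cfg = vb.ExperimentConfig(experiment="distribution")
    profiles, _failures = vb.solve_capsid_ladder(
        [s for s in cfg.s0_grid], cfg.solver)
    return profiles


def sphere_profile(r, n=2001, s_max_frac=1.0, config=None):
    """Analytic closed-sphere profile of radius r (not solver output)."""
    s = np.linspace(0.0, s_max_frac * np.pi * r, n)
    psi = s / r
    return vb.MembraneProfile(
        s=s, psi=psi, R=r * np.sin(psi), z=r * (1.0 - np.cos(psi)),
        dpsi=np.full(n, 1.0 / r), gamma=np.zeros(n),
        H=np.full(n, 2.0 / r), s1=float(s[-1]),
        config=config or vb.SolverConfig(), field=None)
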