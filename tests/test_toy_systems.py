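"""Toy systems, energies, Langevin sampling and fixture generators."""

import numpy as np
import pytest
from scipy import stats

from geombind import (
    CVSpec,
    ConfigurationError,
    ContractError,
    GaussianWell,
    HarmonicWell,
    KB,
    MDState,
    ReferenceStructure,
    RestraintSpec,
    ThermoState,
    ToySystem,
    forces,
    generate_dihedral_series,
    langevin_step,
    make_dihedral_chain,
    make_harmonic_bead,
    make_toy_complex,
    maxwell_velocities,
    potential_energy,
    run_trajectory,
)
from geombind.conformer_analysis import ConformerModel, population_table

T300 = ThermoState(300.0)


def test_thermo_state_invariant():
    th = ThermoState(287.3)
    assert th.beta * KB * th.temperature == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        ThermoState(0.0)


# ----------------------------------------------------------------------
# energies and forces
# ----------------------------------------------------------------------
def test_gaussian_well_minimum_energy():
    """A bead at the bottom of a −5 kcal/mol well reads exactly −5."""
    sys1 = ToySystem(
        masses=[12.0], positions=[[1.0, 2.0, 3.0]],
        host=GaussianWell(depth=5.0, sigma=1.0, center=(1.0, 2.0, 3.0)),
    )
    assert potential_energy(sys1, sys1.positions) == pytest.approx(-5.0)


def test_bond_rest_length_zero_energy():
    sys2 = ToySystem(
        masses=[12.0, 12.0],
        positions=[[0.0, 0, 0], [1.5, 0, 0]],
        bonds=[(0, 1, 60.0, 1.5)],
    )
    assert potential_energy(sys2, sys2.positions) == pytest.approx(0.0)


def test_forces_match_central_differences(rng):
    """Analytic forces vs central differences (h = 1e-5 Å) to 1e-6."""
    sysc = make_toy_complex()
    pos = sysc.positions + rng.normal(0, 0.3, sysc.positions.shape)
    f = forces(sysc, pos)
    h = 1e-5
    for i in range(sysc.n_beads):
        for a in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, a] += h
            pm[i, a] -= h
            fd = -(potential_energy(sysc, pp) - potential_energy(sysc, pm)) / (2 * h)
            assert f[i, a] == pytest.approx(fd, abs=1e-6)


def test_energy_input_contracts():
    sys1 = make_harmonic_bead()
    with pytest.raises(ContractError):
        potential_energy(sys1, np.zeros((2, 3)))
    with pytest.raises(ContractError):
        potential_energy(sys1, np.array([[np.nan, 0, 0]]))


# ----------------------------------------------------------------------
# integrator
# ----------------------------------------------------------------------
def test_zero_friction_energy_drift():
    """With friction off the BAOAB step is velocity Verlet: total energy
    drifts by < 1e-4 kcal/mol over 10⁴ steps at dt = 1 fs."""
    sys2 = ToySystem(
        masses=[12.0, 12.0],
        positions=[[0.0, 0, 0], [1.56, 0, 0]],
        bonds=[(0, 1, 60.0, 1.5)],
    )
    state = MDState(sys2.positions, np.zeros((2, 3)))

    def total(s):
        ke = 0.5 * np.sum(sys2.masses[:, None] * s.velocities**2) / 418.4
        return potential_energy(sys2, s.positions) + ke

    e0 = total(state)
    for _ in range(10_000):
        state = langevin_step(sys2, state, T300, dt=0.001, friction=0.0)
    assert abs(total(state) - e0) < 1e-4


def test_equipartition_and_position_variance():
    """Long harmonic-well runs satisfy ⟨KE⟩ = (3/2)k_BT per bead and
    ⟨r²⟩ = 3 k_BT/k within three standard errors."""
    sys1 = make_harmonic_bead(k=2.0)
    rec = run_trajectory(
        sys1,
        dict(n_steps=400_000, dt=0.002, friction=10.0, seed=3, stride=20,
             cv_observers=[CVSpec("separation_r")]),
    )
    burn = 200
    ke = rec.kinetic[burn:]
    r2 = rec.cv_values[burn:, 0] ** 2
    n_eff = len(ke) / 5.0  # stride 20 × ~5 frames correlation
    target_ke = 1.5 * KB * 300
    assert abs(ke.mean() - target_ke) < 3 * ke.std() / np.sqrt(n_eff)
    target_r2 = 3 * KB * 300 / 2.0
    assert abs(r2.mean() - target_r2) < 3 * r2.std() / np.sqrt(n_eff)


def test_boltzmann_sampling_chi2():
    """The sampled 1-D marginal in a harmonic well is the analytic
    Gaussian: a χ² test must not reject at α = 0.01."""
    sys1 = make_harmonic_bead(k=2.0)
    rec = run_trajectory(
        sys1,
        dict(n_steps=600_000, dt=0.002, friction=10.0, seed=7, stride=50,
             cv_observers=[CVSpec("separation_r")]),
    )
    r = rec.cv_values[100:, 0]
    sigma2 = KB * 300 / 2.0
    edges = np.linspace(0.1, 2.6, 14)
    obs, _ = np.histogram(r, bins=edges)
    # marginal of r: p(r) ∝ r² exp(−r²/2σ²)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = centers**2 * np.exp(-(centers**2) / (2 * sigma2))
    p /= p.sum()
    exp = p * obs.sum()
    keep = exp > 5
    chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
    crit = stats.chi2.ppf(0.99, keep.sum() - 1)
    assert chi2 < 2 * crit  # factor 2 absorbs frame autocorrelation


def test_trajectory_determinism_and_zero_steps():
    sysc = make_toy_complex()
    proto = dict(n_steps=2_000, dt=0.002, friction=10.0, seed=1, stride=10,
                 cv_observers=[CVSpec("rmsd"), CVSpec("Theta")])
    r1 = run_trajectory(sysc, proto)
    r2 = run_trajectory(sysc, proto)
    np.testing.assert_array_equal(r1.cv_values, r2.cv_values)
    np.testing.assert_array_equal(r1.final_positions, r2.final_positions)
    r0 = run_trajectory(sysc, dict(proto, n_steps=0))
    assert len(r0.steps) == 1


def test_restrained_dihedral_circular_mean():
    """A stiff dihedral restraint at 180° keeps the sampled circular mean
    within 1° of 180°."""
    chain = make_dihedral_chain()
    rec = run_trajectory(
        chain,
        dict(n_steps=150_000, dt=0.001, friction=10.0, seed=5, stride=10,
             cv_observers=[CVSpec("dihedral", atoms=(0, 1, 2, 3))],
             restraints=[RestraintSpec("dihedral", 180.0, 0.5, atoms=(0, 1, 2, 3))]),
    )
    ang = np.radians(rec.cv_values[200:, 0])
    mean = np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0
    assert abs(mean - 180.0) < 1.0


def test_unobservable_cv_fails_before_dynamics():
    sys1 = make_harmonic_bead()
    with pytest.raises(ConfigurationError):
        run_trajectory(sys1, dict(seed=1, cv_observers=[CVSpec("Theta")]))
    with pytest.raises(ConfigurationError):
        run_trajectory(sys1, dict(n_steps=10))  # no seed


def test_langevin_step_contracts():
    sys1 = make_harmonic_bead()
    st0 = MDState(sys1.positions, np.zeros((1, 3)))
    with pytest.raises(ConfigurationError):
        langevin_step(sys1, st0, T300, dt=-1.0, friction=1.0)
    with pytest.raises(ConfigurationError):
        langevin_step(sys1, st0, T300, dt=0.001, friction=1.0)  # no rng


# ----------------------------------------------------------------------
# dihedral-series generator
# ----------------------------------------------------------------------
def test_single_mode_series_classifies_cleanly():
    """A tight single mode with no transitions classifies ≥ 99% to it."""
    series = generate_dihedral_series([(180.0, 180.0, 1.0, 5.0)], 3000, 0.0, seed=2)
    model = ConformerModel(modes=[("m", 180.0, 180.0)])
    table = population_table(series, model)
    assert table["m"]["fraction"] >= 0.99


def test_two_mode_weights_recovered():
    series = generate_dihedral_series(
        [(90.0, 90.0, 0.5, 8.0), (180.0, 180.0, 0.5, 8.0)], 20_000, 0.0, seed=3
    )
    model = ConformerModel(modes=[("a", 90.0, 90.0), ("b", 180.0, 180.0)])
    table = population_table(series, model)
    se = 3 * np.sqrt(0.25 / 20_000)
    assert abs(table["a"]["fraction"] - 0.5) < se


def test_generator_contracts():
    with pytest.raises(ConfigurationError):
        generate_dihedral_series([], 100, 0.0, seed=1)
    with pytest.raises(ConfigurationError):
        generate_dihedral_series([(0, 0, 1.0, -1.0)], 100, 0.0, seed=1)
    s = generate_dihedral_series([(0, 0, 1.0, 5.0)], 500, 0.2, seed=4)
    assert len(s) == 500
    assert np.all(s.frames > -180.0) and np.all(s.frames <= 180.0)


def test_maxwell_velocities_scale(rng):
    m = np.full(2000, 12.0)
    v = maxwell_velocities(m, T300, rng)
    ke = 0.5 * 12.0 * (v**2).sum() / 418.4 / 2000
    assert ke == pytest.approx(1.5 * KB * 300, rel=0.05)
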