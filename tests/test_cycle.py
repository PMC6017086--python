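"""Restraint free energies, the standard-state term and cycle composition."""

import math

import numpy as np
import pytest

from geombind import (
    CONTRIBUTION_NAMES,
    ContractError,
    CycleContribution,
    PMFProfile,
    RestraintSpec,
    ThermoState,
    analytic_bulk_orientation,
    compose_cycle,
    restraint_dg_from_pmf,
    separation_standard_term,
)

T300 = ThermoState(300.0)
kT = T300.kt

TABLE_DG = {
    "c_site": -35.2,
    "Theta_site": -0.2,
    "Phi_site": -0.1,
    "Psi_site": -0.1,
    "theta_site": -0.2,
    "phi_site": -0.1,
    "separation_term": -12.0,
    "c_bulk": 26.8,
    "o_bulk": 7.9,
}
TABLE_ERR = {"c_site": 1.6, "separation_term": 0.6, "c_bulk": 1.2}


def flat_profile(kind, lo, hi, width, temperature=300.0):
    n = int(round((hi - lo) / width))
    centers = lo + (np.arange(n) + 0.5) * width
    return PMFProfile(
        centers=centers,
        values=np.zeros(n),
        counts=np.ones(n),
        metadata={"cv": kind, "temperature": temperature, "bin_width": width,
                  "jacobian_removed": True},
    )


def quadratic_profile(kind, lo, hi, width, k_w, x0, temperature=300.0):
    prof = flat_profile(kind, lo, hi, width, temperature)
    prof.values = 0.5 * k_w * (prof.centers - x0) ** 2
    prof.values -= prof.values.min()
    return prof


# ----------------------------------------------------------------------
# restraint_dg_from_pmf
# ----------------------------------------------------------------------
def test_flat_pmf_matches_gaussian_closed_form():
    """A harmonic angular restraint on a flat azimuthal PMF reproduces
    −(1/β) ln(√(2π/βk)/L) to 1e-3."""
    k = 0.1
    prof = flat_profile("phi", -180.0, 180.0, 1.0)
    dg, _ = restraint_dg_from_pmf(prof, RestraintSpec("phi", 0.0, k), T300)
    ell = math.sqrt(2 * math.pi * kT / k)
    assert dg == pytest.approx(-kT * math.log(ell / 360.0), abs=1e-3)


def test_vanishing_restraint_costs_nothing():
    prof = flat_profile("phi", -180.0, 180.0, 1.0)
    dg, _ = restraint_dg_from_pmf(prof, RestraintSpec("phi", 0.0, 1e-12), T300)
    assert dg == pytest.approx(0.0, abs=1e-6)


def test_quadratic_pmf_two_gaussian_closed_form():
    """Harmonic PMF (a, x1) + harmonic restraint (b, x2):
    ΔG = −kT ln[√(a/(a+b)) exp(−β ab(x1−x2)²/2(a+b))]."""
    a, b, x1, x2 = 0.02, 0.05, -3.0, 4.0
    prof = quadratic_profile("Phi", -90.0, 90.0, 1.0, a, x1)
    dg, _ = restraint_dg_from_pmf(prof, RestraintSpec("Phi", x2, b), T300)
    ref = -kT * math.log(
        math.sqrt(a / (a + b))
        * math.exp(-T300.beta * a * b / (2 * (a + b)) * (x1 - x2) ** 2)
    )
    assert dg == pytest.approx(ref, abs=2e-3)


def test_impose_release_antisymmetry():
    prof = quadratic_profile("Phi", -90.0, 90.0, 1.0, 0.03, 5.0)
    r = RestraintSpec("Phi", 0.0, 0.1)
    imp, _ = restraint_dg_from_pmf(prof, r, T300, "impose")
    rel, _ = restraint_dg_from_pmf(prof, r, T300, "release")
    assert rel == -imp


def test_restraint_dg_contracts():
    prof = quadratic_profile("Phi", -20.0, 20.0, 1.0, 0.001, 0.0)
    with pytest.raises(ContractError):  # center outside domain
        restraint_dg_from_pmf(prof, RestraintSpec("Phi", 60.0, 0.1), T300)
    with pytest.raises(ContractError):  # soft PMF truncated mid-domain
        restraint_dg_from_pmf(prof, RestraintSpec("Phi", 0.0, 1e-6), T300)
    with pytest.raises(ContractError):  # temperature mismatch
        restraint_dg_from_pmf(
            quadratic_profile("Phi", -90, 90, 1.0, 0.05, 0.0, temperature=250.0),
            RestraintSpec("Phi", 0.0, 0.1),
            T300,
        )


def test_polar_profile_gets_sin_jacobian():
    """The same flat profile gives a different (and stiff-limit-correct)
    answer when the coordinate is a polar angle."""
    k = 0.1
    prof = flat_profile("theta", 0.0, 180.0, 1.0)
    dg, _ = restraint_dg_from_pmf(prof, RestraintSpec("theta", 90.0, k), T300)
    ell = math.sqrt(2 * math.pi * kT / k)
    ref = -kT * math.log(ell * math.sin(math.pi / 2) / (2.0 * 57.29577951308232))
    assert dg == pytest.approx(ref, abs=1e-2)


# ----------------------------------------------------------------------
# analytic bulk orientation
# ----------------------------------------------------------------------
def make_euler_restraints(k, theta0=90.0):
    return (
        RestraintSpec("Theta", theta0, k),
        RestraintSpec("Phi", 0.0, k),
        RestraintSpec("Psi", 0.0, k),
    )


def test_bulk_orientation_limits():
    tiny = analytic_bulk_orientation(*make_euler_restraints(1e-12), thermo=T300)
    assert tiny == pytest.approx(0.0, abs=1e-6)
    ks = [0.02, 0.1, 0.5, 2.0]
    vals = [
        analytic_bulk_orientation(*make_euler_restraints(k), thermo=T300) for k in ks
    ]
    assert all(b > a for a, b in zip(vals, vals[1:]))  # strictly increasing
    assert all(v > 0 for v in vals)


def test_bulk_orientation_stiff_closed_form():
    """k = 0.1 kcal/(mol·deg²) at Θ0 = 90°, T = 300 K matches the
    stiff-spring formula −(1/β) ln(ℓ³ sinΘ0 / 8π²) within 0.01."""
    dg = analytic_bulk_orientation(*make_euler_restraints(0.1), thermo=T300)
    ell = math.sqrt(2 * math.pi * kT / 0.1) * math.pi / 180.0  # radians
    ref = -kT * math.log(ell**3 * 1.0 / (8 * math.pi**2))
    assert dg == pytest.approx(ref, abs=0.01)


# ----------------------------------------------------------------------
# separation standard-state term
# ----------------------------------------------------------------------
def square_basin_profile(depth=8.0, basin_hi=1.0, r_star=8.0, width=0.1):
    n = int(round(r_star / width))
    centers = (np.arange(n) + 0.5) * width
    vals = np.where(centers <= basin_hi, 0.0, depth)
    vals[centers > r_star - 1.0] = depth  # plateau equals the wall top
    vals = vals - depth  # basin at -depth, plateau at 0
    return PMFProfile(
        centers=centers, values=vals - vals.min(), counts=np.ones(n),
        metadata={"cv": "separation_r", "temperature": 300.0, "bin_width": width},
    )


def test_square_basin_hand_formula():
    """A flat basin of length L with pinned angles reduces the term to
    −kT ln(r*² Ω_pin L e^{βD} / V°) (quadrature cross-check)."""
    depth, r_star = 8.0, 8.0
    prof = square_basin_profile(depth=depth, r_star=r_star)
    k_pin = 2.0
    th_r = RestraintSpec("theta", 90.0, k_pin)
    ph_r = RestraintSpec("phi", 0.0, k_pin)
    term, _ = separation_standard_term(prof, th_r, ph_r, r_star, T300, 1661.0)
    from scipy.integrate import quad

    om = quad(
        lambda t: math.exp(-T300.beta * th_r.energy(math.degrees(t))) * math.sin(t),
        0, math.pi,
    )[0] * quad(
        lambda t: math.exp(-T300.beta * ph_r.energy(math.degrees(t))), -math.pi, math.pi
    )[0]
    # I*: the basin bins at depth −D, plus the two trapezoid half-bins
    istar = math.exp(T300.beta * depth)
    ref = -kT * math.log(r_star**2 * om * istar / 1661.0)
    assert term == pytest.approx(ref, rel=0.02)


def test_v_standard_doubling_shifts_by_kT_ln2():
    prof = square_basin_profile()
    th_r = RestraintSpec("theta", 90.0, 2.0)
    ph_r = RestraintSpec("phi", 0.0, 2.0)
    t1, _ = separation_standard_term(prof, th_r, ph_r, 8.0, T300, 1661.0)
    t2, _ = separation_standard_term(prof, th_r, ph_r, 8.0, T300, 2 * 1661.0)
    assert t2 - t1 == pytest.approx(kT * math.log(2.0), abs=1e-12)


def test_r_star_extension_insensitive():
    """Extending the reference separation along the plateau barely moves
    the term: the r*² surface factor cancels against the −(2/β) ln r
    geometry carried by the spherical-radius PMF."""
    width, r_hi, depth = 0.1, 10.0, 8.0
    centers = (np.arange(int(r_hi / width)) + 0.5) * width
    w_line = np.where(centers <= 1.0, -depth, 0.0)
    vals = w_line - 2 * kT * np.log(centers / r_hi)
    prof = PMFProfile(
        centers=centers, values=vals - vals.min(), counts=np.ones_like(centers),
        metadata={"cv": "separation_r", "temperature": 300.0, "bin_width": width},
    )
    th_r = RestraintSpec("theta", 90.0, 2.0)
    ph_r = RestraintSpec("phi", 0.0, 2.0)
    t1, _ = separation_standard_term(prof, th_r, ph_r, 8.0, T300)
    t2, _ = separation_standard_term(prof, th_r, ph_r, 10.0, T300)
    assert abs(t2 - t1) < 0.2


def test_multiple_minima_need_explicit_basin():
    prof = square_basin_profile()
    prof.values[30:33] = prof.values.max() - 7.9  # second deep minimum
    th_r = RestraintSpec("theta", 90.0, 2.0)
    ph_r = RestraintSpec("phi", 0.0, 2.0)
    with pytest.raises(ContractError):
        separation_standard_term(prof, th_r, ph_r, 8.0, T300)
    term, _ = separation_standard_term(
        prof, th_r, ph_r, 8.0, T300, basin=(0.0, 1.0)
    )
    assert np.isfinite(term)


def test_pmf_must_reach_r_star():
    prof = square_basin_profile(r_star=6.0)
    with pytest.raises(ContractError):
        separation_standard_term(
            prof, RestraintSpec("theta", 90.0, 2.0), RestraintSpec("phi", 0.0, 2.0),
            8.0, T300,
        )


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------
def table_contributions():
    return [
        CycleContribution(n, TABLE_DG[n], TABLE_ERR.get(n)) for n in CONTRIBUTION_NAMES
    ]


def test_compose_table_values():
    res = compose_cycle(table_contributions(), T300)
    assert res.dg_bind == pytest.approx(-13.2, abs=1e-9)
    assert res.error == pytest.approx(math.sqrt(1.6**2 + 0.6**2 + 1.2**2), abs=1e-12)
    res.validate()


def test_compose_zero_contributions_identity():
    """All-zero contributions give ΔG = 0 and K_eq = V° (in Å³), so that
    −(1/β) ln(K_eq C°) = 0."""
    contribs = [CycleContribution(n, 0.0) for n in CONTRIBUTION_NAMES]
    res = compose_cycle(contribs, T300, v_standard=1661.0)
    assert res.dg_bind == 0.0
    assert res.keq == pytest.approx(1661.0)


def test_compose_permutation_invariant():
    import random

    contribs = table_contributions()
    random.Random(3).shuffle(contribs)
    res = compose_cycle(contribs, T300)
    assert res.dg_bind == pytest.approx(-13.2, abs=1e-9)


def test_compose_contract_errors():
    contribs = table_contributions()[:-1]
    with pytest.raises(ContractError):
        compose_cycle(contribs, T300)
    dup = table_contributions()
    dup[1] = CycleContribution("c_site", -1.0)
    with pytest.raises(ContractError):
        compose_cycle(dup, T300)


def test_eq2_consistency():
    """−(1/β) ln(K_eq C°) reproduces ΔG°bind to 1e-10."""
    res = compose_cycle(table_contributions(), T300)
    back = -kT * math.log(res.keq / res.v_standard)
    assert back == pytest.approx(res.dg_bind, abs=1e-10)
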