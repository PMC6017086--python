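"""eABF sampling, PMF estimators, windows and block errors."""

import numpy as np
import pytest

from geombind import (
    ABFHistogram,
    ConfigurationError,
    ContractError,
    CVSpec,
    ExtendedDOF,
    MDState,
    PMFProfile,
    RestraintSpec,
    ThermoState,
    block_error,
    brute_force_pmf,
    eabf_coupled_step,
    estimate_pmf,
    make_dihedral_chain,
    make_double_well_bead,
    merge_windows,
    run_eabf_window,
    stratify_windows,
)

T300 = ThermoState(300.0)
CHAIN_CV = CVSpec("dihedral", atoms=(0, 1, 2, 3))


@pytest.fixture(scope="module")
def harmonic_dihedral_run():
    """eABF along a chain torsion whose only potential is a harmonic
    restraint — the exact PMF is ½k(φ−φ0)² because the chain's torsion
    marginal is flat."""
    chain = make_dihedral_chain()
    k_test = 0.005
    rest = [RestraintSpec("dihedral", 0.0, k_test, atoms=(0, 1, 2, 3))]
    hist = ABFHistogram.for_cv(CHAIN_CV, -40.0, 40.0)
    samples, _, _ = run_eabf_window(
        chain, hist, n_steps=2_000_000, seed=7, thermo=T300, restraints=rest
    )
    return hist, samples, k_test


def test_flat_landscape_mean_force_vanishes():
    """On a flat landscape the per-bin mean force is zero within noise and
    the PMF is flat."""
    chain = make_dihedral_chain()
    hist = ABFHistogram.for_cv(CHAIN_CV, -40.0, 40.0)
    run_eabf_window(chain, hist, n_steps=600_000, seed=11, thermo=T300)
    prof = estimate_pmf(hist, estimator="naive", thermo=T300)
    inner = slice(5, -5)
    assert np.nanmax(np.abs(prof.values[inner] - prof.values[inner].mean())) < 0.25
    cnt = hist.count.sum(0)
    mf = hist.force_sum.sum(0) / np.maximum(cnt, 1)
    # magnitude check: |mean force| per bin small vs the instantaneous
    # force scale k_couple * sigma
    assert np.abs(mf[inner]).max() < 60.0


@pytest.mark.parametrize("estimator", ["naive", "czar"])
def test_harmonic_pmf_recovered(harmonic_dihedral_run, estimator):
    """Both estimators reproduce the harmonic PMF over a 2 kcal/mol range."""
    hist, _, k_test = harmonic_dihedral_run
    prof = estimate_pmf(hist, estimator=estimator, thermo=T300)
    ref = 0.5 * k_test * prof.centers**2
    ref -= ref.min()
    sel = ref <= 2.0
    tol = 0.25 if estimator == "czar" else 0.1
    assert np.nanmax(np.abs(prof.values - ref)[sel]) < tol


def test_stiff_coupling_naive_czar_agree():
    """In the stiff-coupling limit the λ–ξ convolution vanishes and the
    two estimators coincide."""
    chain = make_dihedral_chain()
    rest = [RestraintSpec("dihedral", 0.0, 0.005, atoms=(0, 1, 2, 3))]
    hist = ABFHistogram.for_cv(CHAIN_CV, -30.0, 30.0)
    ext = ExtendedDOF(lambda_mass=300.0, coupling_k=3.0)
    run_eabf_window(
        chain, hist, n_steps=2_500_000, seed=13, thermo=T300, restraints=rest,
        ext=ext, dt=0.00025,
    )
    a = estimate_pmf(hist, estimator="naive", thermo=T300)
    b = estimate_pmf(hist, estimator="czar", thermo=T300)
    sel = slice(3, -3)
    assert np.nanmax(np.abs(a.values[sel] - b.values[sel])) < 0.12


def test_double_well_matches_brute_force():
    """The eABF profile over a quartic double well agrees with exhaustive
    quadrature of the marginal."""
    sysd = make_double_well_bead()
    cv = CVSpec("separation_r")
    hist = ABFHistogram.for_cv(cv, 3.4, 6.6)
    run_eabf_window(sysd, hist, n_steps=1_500_000, seed=17, thermo=T300)
    prof = estimate_pmf(hist, estimator="czar", thermo=T300)
    oracle = brute_force_pmf(
        sysd, cv, 3.4, 6.6, hist.n_bins, T300, box_half=3.5, spacing=0.02
    )
    good = np.isfinite(prof.values) & np.isfinite(oracle.values)
    # the two outermost bins on each side carry the one-sided-difference /
    # reflecting-wall artifacts of the window edge; compare the interior
    good[:2] = good[-2:] = False
    assert good.sum() > 25
    dev = np.abs(prof.values - oracle.values)[good]
    assert dev.max() < 0.15


def test_estimator_contracts():
    hist = ABFHistogram.for_cv(CHAIN_CV, -30.0, 30.0)
    with pytest.raises(ContractError):
        estimate_pmf(hist, thermo=T300)  # zero-length accumulation
    with pytest.raises(ConfigurationError):
        estimate_pmf(hist, estimator="magic", thermo=T300)
    with pytest.raises(ConfigurationError):
        ABFHistogram.for_cv(CHAIN_CV, 0.0, 10.3, bin_width=1.0)  # not integral


def test_profile_order_independence(harmonic_dihedral_run):
    """Accumulators are plain sums, so swapping the two half-run blocks
    (time reversal at block granularity) leaves the estimate unchanged."""
    hist, _, _ = harmonic_dihedral_run
    prof = estimate_pmf(hist, thermo=T300)
    swapped = ABFHistogram(
        cv=hist.cv, lo=hist.lo, hi=hist.hi, bin_width=hist.bin_width,
        n_full=hist.n_full,
        force_sum=hist.force_sum[::-1].copy(), count=hist.count[::-1].copy(),
        xi_count=hist.xi_count[::-1].copy(), lam_sum=hist.lam_sum[::-1].copy(),
    )
    swapped._coupling_internal = hist._coupling_internal
    prof2 = estimate_pmf(swapped, thermo=T300)
    np.testing.assert_allclose(prof2.values, prof.values, atol=1e-12)


def test_eabf_coupled_step_advances(rng):
    chain = make_dihedral_chain()
    hist = ABFHistogram.for_cv(CHAIN_CV, -40.0, 40.0)
    state = MDState(chain.positions, np.zeros((4, 3)))
    ext = ExtendedDOF(lambda_mass=200.0, coupling_k=0.7, lambda_value=20.0)
    for _ in range(5):
        state, ext, hist = eabf_coupled_step(
            chain, state, ext, hist, T300, dt=0.0005, rng=rng
        )
    assert hist.total_samples == 5
    assert state.step_index == 5


# ----------------------------------------------------------------------
# windows
# ----------------------------------------------------------------------
def test_stratify_equal_split():
    ws = stratify_windows(0.0, 30.0, 5, 0.1)
    bounds = [w[1] for w in ws[:-1]]
    assert bounds == pytest.approx([6.0, 12.0, 18.0, 24.0])
    assert stratify_windows(0.0, 30.0, 1, 0.1) == [(0.0, 30.0)]


def test_stratify_snaps_to_bin_edges():
    ws = stratify_windows(0.0, 10.0, 3, 0.1)
    for lo, hi in ws:
        assert (lo / 0.1) == pytest.approx(round(lo / 0.1), abs=1e-9)
        assert (hi / 0.1) == pytest.approx(round(hi / 0.1), abs=1e-9)
    assert ws[-1][1] == 10.0


def test_stratify_contracts():
    with pytest.raises(ConfigurationError):
        stratify_windows(0.0, 0.3, 4, 0.1)  # < 2 bins per window
    with pytest.raises(ConfigurationError):
        stratify_windows(0.0, 30.0, 6, 0.1)  # protocol caps at five
    with pytest.raises(ConfigurationError):
        stratify_windows(0.0, 30.0, 0, 0.1)


def _analytic_profile(lo, hi, width, k):
    centers = lo + (np.arange(int(round((hi - lo) / width))) + 0.5) * width
    vals = 0.5 * k * centers**2
    grad = k * centers
    return PMFProfile(
        centers=centers, values=vals - vals.min(), counts=np.ones_like(centers),
        metadata={"cv": "separation_r", "temperature": 300.0, "bin_width": width},
        gradient=grad,
    )


def test_split_then_merge_reproduces_profile():
    """Splitting a harmonic profile into windows and merging reproduces it
    within 0.05 kcal/mol."""
    full = _analytic_profile(-2.0, 2.0, 0.05, 2.0)
    parts = []
    for lo, hi in stratify_windows(-2.0, 2.0, 4, 0.05):
        sel = (full.centers > lo) & (full.centers < hi)
        parts.append(
            PMFProfile(
                centers=full.centers[sel],
                values=full.values[sel] - full.values[sel].min(),
                counts=full.counts[sel],
                metadata=dict(full.metadata),
                gradient=full.gradient[sel],
            )
        )
    merged = merge_windows(parts)
    assert np.max(np.abs(merged.values - full.values)) < 0.05


def test_merge_single_window_is_anchoring():
    p = _analytic_profile(0.0, 2.0, 0.05, 2.0)
    p_shift = PMFProfile(
        centers=p.centers, values=p.values + 3.0, counts=p.counts,
        metadata=p.metadata, gradient=p.gradient,
    )
    merged = merge_windows([p_shift])
    assert merged.values.min() == pytest.approx(0.0)


def test_merge_contracts():
    a = _analytic_profile(0.0, 1.0, 0.05, 2.0)
    b = _analytic_profile(2.0, 3.0, 0.05, 2.0)  # gap
    with pytest.raises(ContractError):
        merge_windows([a, b])
    c = _analytic_profile(1.0, 2.0, 0.1, 2.0)  # different width
    with pytest.raises(ContractError):
        merge_windows([a, c])
    with pytest.raises(ContractError):
        merge_windows([])


# ----------------------------------------------------------------------
# block errors
# ----------------------------------------------------------------------
def test_block_error_definition():
    assert block_error([3.0, 3.0]) == 0.0
    assert block_error([-34.0, -36.4]) == pytest.approx(1.2)
    with pytest.raises(ContractError):
        block_error([1.0])


def test_block_error_from_samples(rng):
    """Two-block errors of a sample mean agree with the analytic standard
    error within a factor of three."""
    x = rng.normal(0.0, 2.0, 40_000)
    err = block_error(x, estimator=np.mean, n_blocks=2)
    se = 2.0 / np.sqrt(len(x))
    assert se / 3 < err + se / 10  # lower side is noise-limited
    assert err < 3 * se * 3
    with pytest.raises(ContractError):
        block_error(np.ones(1), estimator=np.mean, n_blocks=2)
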