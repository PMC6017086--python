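"""Thermodynamic-cycle composition of the standard binding free energy.

The equilibrium constant of host–guest association is written as a product
of configurational-integral ratios: restraints on the host (guest)
conformation u_c, on the guest orientation u_o = uΘ+uΦ+uΨ and on its
position u_a = uθ+uφ are imposed stepwise in the bound state (each leg a
1-D PMF), the guest is pulled to a reference separation r* along a
rectilinear path with everything else restrained, and the restraints are
released in the bulk — analytically for rotation/translation of a
quasi-rigid guest, by one more PMF for conformation.  The composition

    ΔG°bind = ΔG_c^site + ΔG_Θ^site + … + ΔG_φ^site
              − (1/β) ln(S*·I*·C°) + ΔG_o^bulk + ΔG_c^bulk

is a plain sum in the bound-state-release / bulk-impose sign convention
(site terms negative, bulk terms positive), K_eq = exp(−β ΔG°bind)/C°,
and C° = 1/V° with V° = 1661 Å³ the 1 M standard-state volume.

S* is the restrained angular surface at r*,
S* = r*² ∫∫ exp(−β u_a) sin θ dθ dφ, and I* = ∫_site exp(−β w(r)) dr over
the bound basin of the separation PMF anchored to 0 at r*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .colvars import CVSpec, POLAR_KINDS, RestraintSpec
from .eabf_sampler import (
    ABFHistogram,
    PMFProfile,
    block_error,
    default_dt,
    estimate_pmf,
    merge_windows,
    run_eabf_window,
    stratify_windows,
)
from .errors import ConfigurationError, ContractError
from .thermo import STANDARD_VOLUME_A3, ThermoState
from .toy_systems import ToySystem, make_toy_complex

#: the nine named contributions of the cycle, in presentation order
CONTRIBUTION_NAMES = (
    "c_site",
    "Theta_site",
    "Phi_site",
    "Psi_site",
    "theta_site",
    "phi_site",
    "separation_term",
    "c_bulk",
    "o_bulk",
)


@dataclass
class CycleContribution:
    """One ΔG term of the cycle with its error and sampling-time note."""

    name: str
    dg: float
    error: Optional[float] = None
    time_ns: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in CONTRIBUTION_NAMES:
            raise ConfigurationError(
                f"unknown contribution {self.name!r}; expected one of "
                f"{CONTRIBUTION_NAMES}"
            )


@dataclass
class CycleResult:
    """Composed cycle: contributions, ΔG°bind, K_eq and propagated error."""

    contributions: list
    dg_bind: float
    error: float
    keq: float
    v_standard: float
    temperature: float

    def validate(self) -> None:
        total = sum(c.dg for c in self.contributions)
        if abs(total - self.dg_bind) > 1e-12 * max(1.0, abs(total)):
            raise ContractError("ΔG°bind drifted from the sum of its terms")
        beta = ThermoState(self.temperature).beta
        back = -math.log(self.keq / self.v_standard) / beta
        if abs(back - self.dg_bind) > 1e-10:
            raise ContractError("K_eq and ΔG°bind are inconsistent")

    @property
    def total_time_ns(self) -> Optional[float]:
        times = [c.time_ns for c in self.contributions if c.time_ns is not None]
        return sum(times) if times else None


# ----------------------------------------------------------------------
# restraint free energies from PMFs
# ----------------------------------------------------------------------
def _physical_domain(kind: str):
    if kind in ("theta", "Theta"):
        return (0.0, 180.0)
    if kind in ("phi", "Phi", "Psi", "dihedral"):
        return (-180.0, 180.0)
    return (0.0, math.inf)


def _quadrature_dg(centers, w, restraint, beta, apply_jacobian):
    # midpoint rule on bin centers: covers the full binned domain (a
    # trapezoid over centers would drop half a bin at each edge)
    width = centers[1] - centers[0] if len(centers) > 1 else 1.0
    u = np.array([restraint.energy(c) for c in centers])
    jac = (
        np.sin(np.radians(centers)) if apply_jacobian else np.ones_like(centers)
    )
    f_num = np.exp(-beta * (w + u)) * jac
    f_den = np.exp(-beta * w) * jac
    num = float(f_num.sum() * width)
    den = float(f_den.sum() * width)
    return -math.log(num / den) / beta, f_num, num


def restraint_dg_from_pmf(
    pmf: PMFProfile,
    restraint: RestraintSpec,
    thermo: ThermoState,
    direction: str = "impose",
):
    """Free energy of imposing (or minus that, releasing) one harmonic
    restraint given the PMF along its coarse variable:

        ΔG_impose = −(1/β) ln [∫ e^{−β(w+u)} J dξ / ∫ e^{−βw} J dξ]

    with J = sin ξ for polar-type angles (whose profiles are stored
    Jacobian-free) and J = 1 otherwise.  Errors come from the two-block
    profile replicas when present.
    """
    if direction not in ("impose", "release"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    kind = pmf.metadata.get("cv", restraint.kind)
    if kind != restraint.kind:
        raise ContractError(
            f"PMF is along {kind!r} but the restraint acts on {restraint.kind!r}"
        )
    if pmf.temperature is not None and abs(pmf.temperature - thermo.temperature) > 1e-6:
        raise ContractError("PMF temperature differs from the composition β")
    good = np.isfinite(pmf.values)
    if pmf.metadata.get("gaps"):
        raise ContractError("PMF has interior gaps; refine sampling first")
    centers = pmf.centers[good]
    w = pmf.values[good]
    if len(centers) < 4:
        raise ContractError("too few sampled bins for quadrature")
    half = 0.5 * pmf.bin_width
    if not centers.min() - half <= restraint.center <= centers.max() + half:
        raise ContractError("restraint center lies outside the PMF domain")
    apply_jac = kind in POLAR_KINDS and pmf.metadata.get("jacobian_removed", True)
    beta = thermo.beta
    dg, f_num, num = _quadrature_dg(centers, w, restraint, beta, apply_jac)
    # tail coverage: the restrained integrand must decay at any edge that
    # is not a hard physical boundary of the coordinate
    dom = _physical_domain(kind)
    width = pmf.bin_width
    for edge, val in ((centers[0], f_num[0]), (centers[-1], f_num[-1])):
        at_phys = (
            abs(edge - dom[0]) <= width or (math.isfinite(dom[1]) and abs(edge - dom[1]) <= width)
        )
        if not at_phys and val * width / num > 1e-6:
            raise ContractError(
                f"insufficient tail coverage at ξ = {edge:.3g}: mass fraction "
                f"{val * width / num:.2e} exceeds 1e-6"
            )
    err = None
    if pmf.block_values is not None:
        reps = []
        for b in range(pmf.block_values.shape[0]):
            wb = pmf.block_values[b][good]
            ok = np.isfinite(wb)
            reps.append(
                _quadrature_dg(centers[ok], wb[ok], restraint, beta, apply_jac)[0]
            )
        err = block_error(reps)
    if direction == "release":
        dg = -dg
    return dg, err


def analytic_bulk_orientation(
    restraint_Theta: RestraintSpec,
    restraint_Phi: RestraintSpec,
    restraint_Psi: RestraintSpec,
    thermo: ThermoState,
) -> float:
    """Free-energy cost of restraining the orientation of a quasi-rigid
    guest free in solution (analytic; always ≥ 0):

        ΔG_o^bulk = −(1/β) ln [∫e^{−βuΘ} sinΘ dΘ ∫e^{−βuΦ}dΦ ∫e^{−βuΨ}dΨ / 8π²]
    """
    beta = thermo.beta
    for r, want in (
        (restraint_Theta, "Theta"),
        (restraint_Phi, "Phi"),
        (restraint_Psi, "Psi"),
    ):
        if r.kind != want:
            raise ConfigurationError(f"expected a {want} restraint, got {r.kind}")
    iTh = quad(
        lambda t: math.exp(-beta * restraint_Theta.energy(math.degrees(t)))
        * math.sin(t),
        0.0,
        math.pi,
        limit=200,
    )[0]
    iPh = quad(
        lambda t: math.exp(-beta * restraint_Phi.energy(math.degrees(t))),
        -math.pi,
        math.pi,
        limit=200,
    )[0]
    iPs = quad(
        lambda t: math.exp(-beta * restraint_Psi.energy(math.degrees(t))),
        -math.pi,
        math.pi,
        limit=200,
    )[0]
    return -math.log(iTh * iPh * iPs / (8.0 * math.pi**2)) / beta


def _find_basin(centers, w, r_star_idx):
    """Contiguous region around the global minimum below the lowest
    barrier toward r*."""
    imin = int(np.nanargmin(w))
    barrier = float(np.nanmax(w[imin : r_star_idx + 1]))
    minima = []
    for i in range(1, len(w) - 1):
        if (
            np.isfinite(w[i])
            and w[i] <= w[i - 1]
            and w[i] <= w[i + 1]
            and w[i] < barrier - 0.6
        ):
            minima.append(i)
    lo = imin
    while lo > 0 and np.isfinite(w[lo - 1]) and w[lo - 1] < barrier:
        lo -= 1
    hi = imin
    while hi + 1 <= r_star_idx and np.isfinite(w[hi + 1]) and w[hi + 1] < barrier:
        hi += 1
    return lo, hi, [m for m in minima if not lo <= m <= hi]


def separation_standard_term(
    separation_pmf: PMFProfile,
    restraint_theta: RestraintSpec,
    restraint_phi: RestraintSpec,
    r_star: float,
    thermo: ThermoState,
    v_standard: float = STANDARD_VOLUME_A3,
    basin: Optional[tuple] = None,
):
    """The −(1/β)·ln(S*·I*·C°) term of the cycle.

    The separation PMF is re-anchored to w(r*) = 0; I* integrates
    exp(−βw) over the bound basin (detected automatically unless ``basin``
    gives an explicit (lo, hi) interval — required when the profile has
    several minima, e.g. a non-native secondary well); S* is the
    restrained angular surface at r*.  Returns (term, error).
    """
    beta = thermo.beta
    centers = separation_pmf.centers
    w = separation_pmf.values
    if centers[-1] + separation_pmf.bin_width / 2 < r_star:
        raise ContractError(
            f"separation PMF ends at {centers[-1]:.2f} Å, before r* = {r_star} Å"
        )
    if restraint_theta.kind != "theta" or restraint_phi.kind != "phi":
        raise ConfigurationError("positional restraints must act on (theta, phi)")

    i_star = int(np.argmin(np.abs(centers - r_star)))
    # anchor w(r*) = 0 using the plateau next to r*
    tail = slice(max(0, i_star - 4), i_star + 1)

    def ik(values):
        anchor = np.nanmean(values[tail]) if np.isfinite(values[tail]).any() else np.nan
        if not np.isfinite(anchor):
            raise ContractError(
                f"separation PMF has no sampled bins near r* = {r_star} Å; "
                "extend the sampling"
            )
        v = values - anchor
        if basin is not None:
            sel = (centers >= basin[0]) & (centers <= basin[1])
            if not sel.any():
                raise ContractError("explicit basin contains no bins")
            lo, hi = np.where(sel)[0][[0, -1]]
        else:
            lo, hi, extra = _find_basin(centers, v, i_star)
            if extra:
                raise ContractError(
                    "separation profile has multiple minima; supply the basin "
                    f"interval explicitly (extra minima near r = "
                    f"{[round(float(centers[i]), 2) for i in extra]})"
                )
        width = separation_pmf.bin_width
        return float(np.exp(-beta * v[lo : hi + 1]).sum() * width)

    i_star_val = ik(w)
    s_star = r_star**2 * quad(
        lambda t: math.exp(-beta * restraint_theta.energy(math.degrees(t)))
        * math.sin(t),
        0.0,
        math.pi,
        limit=200,
    )[0] * quad(
        lambda t: math.exp(-beta * restraint_phi.energy(math.degrees(t))),
        -math.pi,
        math.pi,
        limit=200,
    )[0]
    term = -math.log(s_star * i_star_val / v_standard) / beta
    err = None
    if separation_pmf.block_values is not None:
        reps = []
        for b in range(separation_pmf.block_values.shape[0]):
            reps.append(
                -math.log(s_star * ik(separation_pmf.block_values[b]) / v_standard)
                / beta
            )
        err = block_error(reps)
    return term, err


def compose_cycle(
    contributions: Sequence[CycleContribution],
    thermo: ThermoState,
    v_standard: float = STANDARD_VOLUME_A3,
) -> CycleResult:
    """Sum the nine named contributions into ΔG°bind and K_eq.

    The sum is exact bookkeeping (site terms already carry their release
    sign, bulk terms their impose sign); errors add in quadrature as
    independent; K_eq = exp(−β ΔG°bind)/C°.
    """
    names = [c.name for c in contributions]
    if sorted(names) != sorted(CONTRIBUTION_NAMES):
        missing = set(CONTRIBUTION_NAMES) - set(names)
        dupes = {n for n in names if names.count(n) > 1}
        raise ContractError(
            f"cycle needs each contribution exactly once; missing={sorted(missing)} "
            f"duplicated={sorted(dupes)}"
        )
    order = {n: i for i, n in enumerate(CONTRIBUTION_NAMES)}
    contribs = sorted(contributions, key=lambda c: order[c.name])
    total = sum(c.dg for c in contribs)
    err = math.sqrt(sum(c.error**2 for c in contribs if c.error is not None))
    keq = math.exp(-thermo.beta * total) * v_standard
    result = CycleResult(
        contributions=contribs,
        dg_bind=total,
        error=err,
        keq=keq,
        v_standard=v_standard,
        temperature=thermo.temperature,
    )
    result.validate()
    return result


def angular_site_profiles(
    system: ToySystem,
    k_angular: float = 0.1,
    k_rmsd: float = 100.0,
    euler_halfwidth: float = 40.0,
    polar_halfwidth: float = 20.0,
    steps: int = 1_200_000,
    seed: int = 7,
    thermo: ThermoState = ThermoState(),
    estimator: str = "czar",
) -> dict:
    """The five sequential angular site PMFs on a bound complex, with the
    conformational restraint on and each angular restraint imposed after
    its PMF is measured.  Used to examine the shape of the orientational
    and positional legs (on a stiff complex they are quadratic)."""
    bound = _bound_cv_values(system)
    applied = [RestraintSpec("rmsd", 0.0, k_rmsd)]
    out = {}
    for i, kind in enumerate(("Theta", "Phi", "Psi", "theta", "phi")):
        center = _snap(bound[kind], 0.5)
        hw = euler_halfwidth if kind in ("Theta", "Phi", "Psi") else polar_halfwidth
        lo, hi = _snap(center - hw, 1.0), _snap(center + hw, 1.0)
        if kind in POLAR_KINDS:
            lo, hi = max(lo, 5.0), min(hi, 175.0)
        hist = ABFHistogram.for_cv(CVSpec(kind), lo, hi)
        run_eabf_window(
            system, hist, n_steps=steps, seed=seed + i, thermo=thermo,
            restraints=list(applied),
        )
        out[kind] = estimate_pmf(hist, estimator=estimator, thermo=thermo)
        applied.append(RestraintSpec(kind, center, k_angular))
    return out


def quadratic_fit_r2(profile: PMFProfile, w_max: float = 2.5) -> float:
    """R² of a quadratic least-squares fit over the thermally relevant
    region (bins with w ≤ w_max kcal/mol)."""
    m = np.isfinite(profile.values) & (profile.values <= w_max)
    x, y = profile.centers[m], profile.values[m]
    if len(x) < 6:
        raise ContractError("too few bins for a quadratic fit")
    coef = np.polyfit(x, y, 2)
    resid = y - np.polyval(coef, x)
    return 1.0 - float(np.sum(resid**2) / np.sum((y - y.mean()) ** 2))


# ----------------------------------------------------------------------
# end-to-end protocol on a toy complex
# ----------------------------------------------------------------------
@dataclass
class BindingProtocol:
    """Everything needed to replay the full geometric route on a toy
    complex: the system, restraint force constants, PMF domains and
    per-stage sampling lengths."""

    system: Optional[ToySystem] = None
    seed: int = 1
    temperature: float = 300.0
    v_standard: float = STANDARD_VOLUME_A3
    k_angular: float = 0.1  # kcal/(mol·deg²)
    k_rmsd: float = 100.0  # kcal/(mol·Å²)
    r_star: float = 8.0
    r_min: float = 1.0
    separation_windows: int = 2
    rmsd_hi: float = 0.8
    euler_halfwidth: float = 60.0
    polar_halfwidth: float = 25.0
    steps_angular: int = 2_000_000
    steps_rmsd: int = 1_500_000
    steps_separation: int = 2_000_000
    friction: float = 10.0
    estimator: str = "czar"
    n_full: int = 200

    def __post_init__(self) -> None:
        if self.system is None:
            self.system = make_toy_complex()
        if self.system.reference is None:
            raise ConfigurationError("protocol system needs a reference structure")


def _bound_cv_values(system: ToySystem) -> dict:
    """CV values at the (already minimised) stored configuration."""
    from .colvars import _eval_single

    out = {}
    for kind in ("separation_r", "theta", "phi", "Theta", "Phi", "Psi", "rmsd"):
        out[kind] = _eval_single(
            kind, system.positions, system.masses, system.frame, system.reference
        ).value
    return out


def _snap(x: float, width: float) -> float:
    return round(x / width) * width


def end_to_end_toy_binding(protocol: BindingProtocol, return_artifacts: bool = False):
    """Run the complete geometric route on a toy complex.

    Stages: bound-state conformational PMF; five sequential angular PMFs
    with restraints applied cumulatively (Θ, Φ, Ψ, θ, φ); the separation
    PMF with every restraint on, stratified into windows and merged; the
    bulk conformational PMF; the analytic bulk reorientation cost; and the
    composition into ΔG°bind.
    """
    p = protocol
    thermo = ThermoState(p.temperature)
    sysb = p.system
    bound = _bound_cv_values(sysb)
    artifacts = {"bound_cvs": bound, "profiles": {}}

    def ns_of(steps, kind):
        return steps * default_dt(kind) / 1000.0

    # restraints, centered on the bound-state geometry
    r_c = RestraintSpec("rmsd", 0.0, p.k_rmsd)
    ang_rest = {}
    for kind in ("Theta", "Phi", "Psi", "theta", "phi"):
        center = _snap(bound[kind], 0.5)
        ang_rest[kind] = RestraintSpec(kind, center, p.k_angular)
    artifacts["restraints"] = {"c": r_c, **ang_rest}

    contribs = []
    seed = p.seed

    def run_stage(system, cv, lo, hi, restr, steps, state=None, windows=1):
        nonlocal seed
        hist0 = ABFHistogram.for_cv(cv, lo, hi, n_full=p.n_full)
        profs = []
        st = state
        for wlo, whi in stratify_windows(lo, hi, windows, hist0.bin_width):
            hist = ABFHistogram.for_cv(cv, wlo, whi, n_full=p.n_full)
            seed += 1
            _, st, _ = run_eabf_window(
                system,
                hist,
                n_steps=steps // windows,
                seed=seed,
                thermo=thermo,
                restraints=restr,
                friction=p.friction,
                state=st,
            )
            profs.append(
                estimate_pmf(hist, estimator=p.estimator, thermo=thermo)
            )
        return merge_windows(profs) if len(profs) > 1 else profs[0]

    # --- bound-state conformational PMF -------------------------------
    cv = CVSpec("rmsd")
    prof = run_stage(sysb, cv, 0.0, p.rmsd_hi, [], p.steps_rmsd)
    artifacts["profiles"]["c_site"] = prof
    dg, err = restraint_dg_from_pmf(prof, r_c, thermo, direction="release")
    contribs.append(
        CycleContribution("c_site", dg, err, ns_of(p.steps_rmsd, "rmsd"))
    )

    # --- sequential angular PMFs ---------------------------------------
    applied = [r_c]
    for kind in ("Theta", "Phi", "Psi", "theta", "phi"):
        r = ang_rest[kind]
        hw = p.euler_halfwidth if kind in ("Theta", "Phi", "Psi") else p.polar_halfwidth
        lo = _snap(r.center - hw, 1.0)
        hi = _snap(r.center + hw, 1.0)
        if kind in POLAR_KINDS:
            lo, hi = max(lo, 5.0), min(hi, 175.0)
        prof = run_stage(sysb, CVSpec(kind), lo, hi, list(applied), p.steps_angular)
        artifacts["profiles"][f"{kind}_site"] = prof
        dg, err = restraint_dg_from_pmf(prof, r, thermo, direction="release")
        contribs.append(
            CycleContribution(
                f"{kind}_site", dg, err, ns_of(p.steps_angular, kind)
            )
        )
        applied.append(r)

    # --- separation PMF with all restraints on -------------------------
    prof = run_stage(
        sysb,
        CVSpec("separation_r"),
        p.r_min,
        p.r_star,
        list(applied),
        p.steps_separation,
        windows=p.separation_windows,
    )
    artifacts["profiles"]["separation"] = prof
    term, err = separation_standard_term(
        prof, ang_rest["theta"], ang_rest["phi"], p.r_star, thermo, p.v_standard
    )
    contribs.append(
        CycleContribution(
            "separation_term", term, err, ns_of(p.steps_separation, "separation_r")
        )
    )

    # --- bulk conformational PMF ---------------------------------------
    bulk = sysb.without_host()
    prof = run_stage(bulk, CVSpec("rmsd"), 0.0, p.rmsd_hi, [], p.steps_rmsd)
    artifacts["profiles"]["c_bulk"] = prof
    dg, err = restraint_dg_from_pmf(prof, r_c, thermo, direction="impose")
    contribs.append(
        CycleContribution("c_bulk", dg, err, ns_of(p.steps_rmsd, "rmsd"))
    )

    # --- analytic bulk reorientation -----------------------------------
    dg_o = analytic_bulk_orientation(
        ang_rest["Theta"], ang_rest["Phi"], ang_rest["Psi"], thermo
    )
    contribs.append(CycleContribution("o_bulk", dg_o, None, None))

    result = compose_cycle(contribs, thermo, p.v_standard)
    if return_artifacts:
        return result, artifacts
    return result
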