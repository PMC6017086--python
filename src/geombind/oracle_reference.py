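"""Sampler-independent ground truth for toy host–guest systems.

Configurational integrals are evaluated directly: exhaustive 3-D grid
quadrature for one-bead guests, and seeded importance-sampling Monte Carlo
over (COM position × orientation × internal shape) for flexible guests,
with the internal-shape ensemble drawn exactly (rejection sampling of the
bond/angle Boltzmann factors with their r² sin α measure).  Nothing here
shares code with the dynamics or the eABF machinery beyond the CV
definitions themselves.

The equilibrium constant is the ratio of the site integral to the bulk
integral with the guest centre of mass pinned far from the host,

    K_eq = ∫_site d³x₁ ⟨exp(−β U_field)⟩_free   (units Å³),

where ⟨·⟩_free averages over the free guest's internal/orientational
ensemble, and ΔG°bind = −(1/β) ln(K_eq/V°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import quad

from . import _kernels as _k
from .colvars import CVSpec, POLAR_KINDS, RestraintSpec
from .errors import ConfigurationError, ContractError
from .thermo import DEG_PER_RAD, ThermoState
from .toy_systems import ToySystem
from .eabf_sampler import PMFProfile


@dataclass
class QuadratureSpec:
    """Integration domains and resolutions for the brute-force oracle."""

    site_lo: np.ndarray = None
    site_hi: np.ndarray = None
    spacing: float = 0.1
    n_samples: int = 400_000
    seed: int = 2024
    bulk_point: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.site_lo is not None:
            self.site_lo = np.asarray(self.site_lo, float)
            self.site_hi = np.asarray(self.site_hi, float)
            if np.any(self.site_hi <= self.site_lo):
                raise ConfigurationError("site_hi must exceed site_lo")
        if self.spacing <= 0:
            raise ConfigurationError("spacing must be > 0")


# ----------------------------------------------------------------------
# vectorised host-field energy (values only; oracle never needs forces)
# ----------------------------------------------------------------------
def host_field_energy(system: ToySystem, pos: np.ndarray) -> np.ndarray:
    """U_field for a batch of configurations, shape (..., n_beads, 3) -> (...)."""
    hosts = system.host_list
    if not hosts:
        return np.zeros(pos.shape[:-2])
    total = np.zeros(pos.shape[:-2])
    for h, w in zip(hosts, system.host_weights):
        total = total + _one_field_energy(h.kind_code, h.pack(), w, pos)
    return total


def _one_field_energy(kind, par, w, pos):
    if kind == 1:
        d = pos - par[1:4]
        return 0.5 * par[0] * np.einsum("...ba,...ba,b->...", d, d, w)
    if kind == 2:
        d = pos - par[2:5]
        r2 = np.einsum("...ba,...ba->...b", d, d)
        return np.einsum("...b,b->...", -par[0] * np.exp(-r2 / (2 * par[1] ** 2)), w)
    if kind == 3:
        d = pos - par[3:6]
        s = (d[..., 0] ** 2 - par[1] ** 2) / par[1] ** 2
        u = par[0] * s * s + 0.5 * par[2] * (d[..., 1] ** 2 + d[..., 2] ** 2)
        return np.einsum("...b,b->...", u, w)
    if kind == 4:
        ax = par[4:7]
        d = pos - par[7:10]
        r = np.sqrt(np.einsum("...ba,...ba->...b", d, d))
        r = np.maximum(r, 1e-12)
        cg = np.einsum("...ba,a->...b", d, ax) / r
        cap = ((1.0 + cg) * 0.5) ** par[3]
        u = -par[0] * np.exp(-((r - par[1]) ** 2) / (2 * par[2] ** 2)) * cap
        return np.einsum("...b,b->...", u, w)
    if kind == 5:
        d = pos - par[2:5]
        r2 = np.einsum("...ba,...ba->...b", d, d)
        u = np.where(r2 < par[1] ** 2, -par[0], 0.0)
        return np.einsum("...b,b->...", u, w)
    raise ConfigurationError(f"unknown host kind {kind}")


# ----------------------------------------------------------------------
# exact free-guest ensemble
# ----------------------------------------------------------------------
def _sample_bond_length(k, r0, n, rng, beta):
    """r ~ r² exp(−βk(r−r0)²/2) by rejection from the plain Gaussian."""
    sig = 1.0 / math.sqrt(beta * k)
    rmax = r0 + 6.0 * sig
    out = np.empty(n)
    got = 0
    while got < n:
        cand = rng.normal(r0, sig, size=2 * (n - got))
        cand = cand[cand > 0]
        acc = rng.random(len(cand)) < (cand / rmax) ** 2
        take = cand[acc][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def _sample_angle(k, a0, n, rng, beta):
    """α ~ sin α exp(−βk(α−α0)²/2) on (0, π) by rejection."""
    sig = 1.0 / math.sqrt(beta * k)
    out = np.empty(n)
    got = 0
    while got < n:
        cand = rng.normal(a0, sig, size=2 * (n - got))
        cand = cand[(cand > 0) & (cand < math.pi)]
        acc = rng.random(len(cand)) < np.sin(cand)
        take = cand[acc][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def _random_rotations(n, rng):
    """Uniform (Haar) rotations via unit quaternions, shape (n, 3, 3)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _rotvec_to_matrix(v):
    """Exponential map, batched rotation vectors (n, 3) -> (n, 3, 3)."""
    t = np.linalg.norm(v, axis=1)
    t = np.maximum(t, 1e-12)
    k = v / t[:, None]
    K = np.zeros((len(v), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -k[:, 2], k[:, 1]
    K[:, 1, 0], K[:, 1, 2] = k[:, 2], -k[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -k[:, 1], k[:, 0]
    st, ct = np.sin(t), np.cos(t)
    return (
        np.eye(3)[None]
        + st[:, None, None] * K
        + (1 - ct)[:, None, None] * (K @ K)
    )


def _matrix_to_rotvec(R):
    """Inverse exponential map, batched (n, 3, 3) -> (n, 3)."""
    tr = np.clip((np.trace(R, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
    t = np.arccos(tr)
    skew = np.stack(
        [R[:, 2, 1] - R[:, 1, 2], R[:, 0, 2] - R[:, 2, 0], R[:, 1, 0] - R[:, 0, 1]],
        axis=1,
    )
    s = np.maximum(np.sin(t), 1e-12)
    axis = skew / (2.0 * s[:, None])
    return axis * t[:, None]


def _haar_density_rotvec(v):
    """Haar probability density of SO(3) in rotation-vector coordinates."""
    t = np.maximum(np.linalg.norm(v, axis=1), 1e-9)
    return (1.0 - np.cos(t)) / (4.0 * math.pi**2 * t**2)


def _mixture_rotations(n, rng, R_center, mix):
    """Orientations from a Haar/concentrated mixture around ``R_center``.

    ``mix`` is a sequence of (weight, sigma) with sigma None for the Haar
    component.  Returns (R, density) with the density taken w.r.t. the
    Haar probability measure, so plain means over the samples divided by
    the density estimate Haar expectations.
    """
    u_pick = rng.random(n)
    R = np.empty((n, 3, 3))
    acc = 0.0
    for wmix, sig in mix:
        sel_m = (u_pick >= acc) & (u_pick < acc + wmix)
        acc += wmix
        k = int(sel_m.sum())
        if sig is None:
            R[sel_m] = _random_rotations(k, rng)
        else:
            v = rng.normal(0.0, sig, size=(k, 3))
            R[sel_m] = R_center[None] @ _rotvec_to_matrix(v)
    v_all = _matrix_to_rotvec(np.einsum("ab,nbc->nac", R_center.T, R))
    h_haar = _haar_density_rotvec(v_all)
    p_rot = np.zeros(n)
    for wmix, sig in mix:
        if sig is None:
            p_rot += wmix
        else:
            g = np.exp(-0.5 * np.sum(v_all**2, axis=1) / sig**2) / (
                (2 * math.pi * sig**2) ** 1.5
            )
            p_rot += wmix * g / h_haar
    return R, p_rot


def sample_free_shapes(system: ToySystem, n: int, rng: np.random.Generator, beta: float):
    """Exact internal-shape samples of the free guest, centred on the
    mass-weighted COM and in a canonical (unrotated) frame: (n, n_beads, 3).

    Supported topologies: a single bead; two beads with one bond; three
    beads with bonds (0−1), (1−2) and a harmonic angle at bead 1.
    """
    nb = system.n_beads
    if nb == 1:
        return np.zeros((n, 1, 3))
    if nb == 2 and len(system.bonds) == 1 and not system.angles:
        i, j, k, r0 = system.bonds[0]
        r = _sample_bond_length(k, r0, n, rng, beta)
        out = np.zeros((n, 2, 3))
        out[:, int(j), 0] = r
    elif (
        nb == 3
        and len(system.bonds) == 2
        and len(system.angles) == 1
        and tuple(system.angles[0][:3]) == (0, 1, 2)
    ):
        b01, b12 = system.bonds
        r1 = _sample_bond_length(b01[2], b01[3], n, rng, beta)
        r2 = _sample_bond_length(b12[2], b12[3], n, rng, beta)
        ka, a0 = system.angles[0][3], math.radians(system.angles[0][4])
        al = _sample_angle(ka, a0, n, rng, beta)
        out = np.zeros((n, 3, 3))
        out[:, 0, 0] = r1
        out[:, 2, 0] = r2 * np.cos(al)
        out[:, 2, 1] = r2 * np.sin(al)
    else:
        raise ConfigurationError(
            "free-guest sampling supports 1 bead, 2 beads/1 bond, or "
            "3 beads with two bonds and one angle at the middle bead"
        )
    m = system.masses / system.masses.sum()
    out -= np.einsum("b,nba->na", m, out)[:, None, :]
    return out


# ----------------------------------------------------------------------
# brute-force PMF (one-bead systems, exhaustive grid)
# ----------------------------------------------------------------------
def brute_force_pmf(
    system: ToySystem,
    cv: CVSpec,
    lo: float,
    hi: float,
    n_bins: int,
    thermo: ThermoState = ThermoState(),
    box_half: float = 8.0,
    spacing: float = 0.05,
) -> PMFProfile:
    """PMF by binned high-resolution quadrature of exp(−βU) on a 3-D grid.

    Only one-bead systems are integrated exhaustively; the CV must be a
    function of the bead position (separation or polar angles).  Polar
    angles are returned Jacobian-free, matching the sampler's convention.
    """
    if system.n_beads != 1:
        raise ContractError("exhaustive PMF quadrature supports one-bead systems")
    if cv.kind not in ("separation_r", "theta", "phi"):
        raise ContractError(f"CV {cv.kind!r} is not position-only")
    if system.host is None:
        raise ContractError("unbounded integrand: no host field")
    ax = np.arange(-box_half, box_half + spacing / 2, spacing)
    edges = np.linspace(lo, hi, n_bins + 1)
    hist = np.zeros(n_bins)
    # z-slab chunks keep the grid memory bounded at any resolution
    Y, Z = np.meshgrid(ax, ax, indexing="ij")
    for x in ax:
        pts = np.stack([np.full_like(Y, x), Y, Z], axis=-1).reshape(-1, 1, 3)
        u = host_field_energy(system, pts)
        wgt = np.exp(-thermo.beta * u)
        rel = (pts[:, 0, :] - system.frame.origin) @ system.frame.axes
        if cv.kind == "separation_r":
            vals = np.linalg.norm(rel, axis=1)
        elif cv.kind == "theta":
            r = np.maximum(np.linalg.norm(rel, axis=1), 1e-12)
            vals = np.degrees(np.arccos(np.clip(rel[:, 2] / r, -1, 1)))
        else:
            vals = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
        h, _ = np.histogram(vals, bins=edges, weights=wgt)
        hist += h
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore"):
        a = -thermo.kt * np.log(hist)
    a[hist == 0] = np.nan
    if cv.kind in POLAR_KINDS:
        a = a + thermo.kt * np.log(np.sin(np.radians(centers)))
    good = np.isfinite(a)
    a -= a[good].min()
    return PMFProfile(
        centers=centers,
        values=a,
        counts=hist,
        metadata={
            "cv": cv.kind,
            "bin_width": edges[1] - edges[0],
            "temperature": thermo.temperature,
            "estimator": "quadrature",
            "jacobian_removed": cv.kind in POLAR_KINDS,
        },
    )


# ----------------------------------------------------------------------
# equilibrium constant
# ----------------------------------------------------------------------
def _bound_pose(system: ToySystem):
    """Energy-minimised bound configuration (positions, COM, rotation)."""
    from scipy.optimize import minimize
    from .toy_systems import potential_energy, forces as _forces

    def fun(x):
        return potential_energy(system, x.reshape(-1, 3))

    def jac(x):
        return -_forces(system, x.reshape(-1, 3)).ravel()

    res = minimize(fun, system.positions.ravel(), jac=jac, method="L-BFGS-B")
    pos = res.x.reshape(-1, 3)
    m = system.masses / system.masses.sum()
    com = m @ pos
    Rb = np.eye(3)
    if system.reference is not None and system.n_beads >= 3:
        q, Rb, *_ = _k.best_fit(
            pos, system.masses, system.reference.centered, system.reference.selection
        )
    return pos, com, Rb


def brute_force_keq(
    system: ToySystem,
    spec: QuadratureSpec,
    thermo: ThermoState = ThermoState(),
    return_details: bool = False,
):
    """K_eq (Å³) with its standard error.

    One-bead guests integrate exp(−β U_field) on an exhaustive grid over
    the site box.  Flexible guests use importance-sampled Monte Carlo:
    exact free-guest shapes, orientations from a Haar/bound-pose mixture,
    COM positions from a uniform/Gaussian mixture over the site box.
    """
    if spec.site_lo is None:
        raise ConfigurationError("QuadratureSpec needs a site box")
    beta = thermo.beta
    if system.n_beads == 1:
        h = spec.spacing
        axes = [np.arange(lo + h / 2, hi, h) for lo, hi in zip(spec.site_lo, spec.site_hi)]
        Y, Z = np.meshgrid(axes[1], axes[2], indexing="ij")
        total = 0.0
        for ix, x in enumerate(axes[0]):
            pts = np.stack([np.full_like(Y, x), Y, Z], axis=-1).reshape(-1, 1, 3)
            u = host_field_energy(system, pts)
            # the bound well must be interior to the site box
            face = np.zeros(len(pts), bool)
            if ix <= 1 or ix >= len(axes[0]) - 2:
                face[:] = True
            for d in (1, 2):
                face |= (pts[:, 0, d] < spec.site_lo[d] + 2 * h) | (
                    pts[:, 0, d] > spec.site_hi[d] - 2 * h
                )
            if np.any(u[face] < -0.5 * thermo.kt):
                raise ContractError("site region touches the integration boundary")
            total += float(np.sum(np.exp(-beta * u)))
        keq = total * h**3
        return (keq, 0.0) if not return_details else (keq, 0.0, {})
    if system.n_beads > 3:
        raise ContractError("exhaustive/MC oracle supports at most 3 beads")

    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_samples)
    _pos_b, com_b, R_b = _bound_pose(system)
    lo, hi = spec.site_lo, spec.site_hi
    vol = float(np.prod(hi - lo))
    # layered mixture proposals: broad components cover the whole site and
    # orientation space, tight components resolve the bound basin and the
    # strongly restrained core the cycle ratios integrate over
    x_mix = ((0.35, None), (0.40, 0.45), (0.25, 1.1))
    r_mix = ((0.30, None), (0.45, 0.25), (0.25, 0.055))

    shapes = sample_free_shapes(system.without_host(), n, rng, beta)
    R, p_rot = _mixture_rotations(n, rng, R_b, r_mix)
    # COM proposal
    u_pick = rng.random(n)
    x1 = np.empty((n, 3))
    acc = 0.0
    for wmix, sig in x_mix:
        sel_m = (u_pick >= acc) & (u_pick < acc + wmix)
        acc += wmix
        k = int(sel_m.sum())
        if sig is None:
            x1[sel_m] = rng.uniform(lo, hi, size=(k, 3))
        else:
            x1[sel_m] = rng.normal(com_b, sig, size=(k, 3))
    inside = np.all((x1 >= lo) & (x1 <= hi), axis=1)
    p_x = np.zeros(n)
    for wmix, sig in x_mix:
        if sig is None:
            p_x += np.where(inside, wmix / vol, 0.0)
        else:
            p_x += wmix * np.exp(
                -0.5 * np.sum((x1 - com_b) ** 2, axis=1) / sig**2
            ) / ((2 * math.pi * sig**2) ** 1.5)

    pos = x1[:, None, :] + np.einsum("nab,nkb->nka", R, shapes)
    u = host_field_energy(system, pos)
    w = np.where(inside, np.exp(-beta * u), 0.0) / (p_x * p_rot)
    keq = float(w.mean())
    se = float(w.std(ddof=1) / math.sqrt(n))
    if return_details:
        details = {
            "x1": x1,
            "pos": pos,
            "weights_unrestrained": w,
            "inside": inside,
            "com_b": com_b,
            "R_b": R_b,
        }
        return keq, se, details
    return keq, se


def keq_to_dg(keq: float, thermo: ThermoState, v_standard: float) -> float:
    """ΔG°bind = −(1/β) ln(K_eq·C°) with C° = 1/V°."""
    if keq <= 0:
        raise ContractError("K_eq must be positive")
    return -thermo.kt * math.log(keq / v_standard)


# ----------------------------------------------------------------------
# analytic single-restraint free energies
# ----------------------------------------------------------------------
def analytic_harmonic_dg(
    k: float,
    center: float,
    domain: tuple,
    jacobian: bool = False,
    thermo: ThermoState = ThermoState(),
) -> float:
    """Free energy of imposing ½k(ξ−ξ0)² on a flat landscape over a
    bounded domain (degrees for angles; ``jacobian`` adds the sin ξ
    measure of polar angles)."""
    lo, hi = domain
    if not lo < center < hi:
        raise ContractError("restraint center outside the domain")
    if k < 0:
        raise ContractError("force constant must be >= 0")
    beta = thermo.beta

    if jacobian:
        meas = lambda x: math.sin(math.radians(x))
    else:
        meas = lambda x: 1.0
    num = quad(lambda x: math.exp(-beta * 0.5 * k * (x - center) ** 2) * meas(x), lo, hi, limit=200)[0]
    den = quad(meas, lo, hi, limit=200)[0]
    return -math.log(num / den) / beta


# ----------------------------------------------------------------------
# product-of-ratios reconstruction (internal identity of the cycle)
# ----------------------------------------------------------------------
def _batch_restraint_energy(
    system: ToySystem, pos_batch: np.ndarray, restraints
) -> np.ndarray:
    """Σ_j u_j evaluated on each configuration of a batch via the same CV
    kernels the sampler uses."""
    (m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel) = system.pack()
    nr = len(restraints)
    codes = np.array([CVSpec(r.kind, r.atoms).code for r in restraints], dtype=np.int64)
    atoms = (
        np.stack([CVSpec(r.kind, r.atoms).atoms_array() for r in restraints])
        if nr
        else np.zeros((0, 4), dtype=np.int64)
    )
    centers = np.array([r.internal_center for r in restraints])
    ks = np.array([r.internal_k for r in restraints])
    return _k.batch_restraint_energy(
        codes, atoms, centers, ks, np.ascontiguousarray(pos_batch), m, org, axes,
        rc, rdm, sel,
    )


def cycle_integrals(
    system: ToySystem,
    restraints: dict,
    spec: QuadratureSpec,
    thermo: ThermoState = ThermoState(),
    v_standard: float = 1661.0,
) -> dict:
    """Every term of the thermodynamic cycle from shared Monte Carlo
    integrals, plus the direct K_eq.

    ``restraints`` maps {"c", "Theta", "Phi", "Psi", "theta", "phi"} to
    RestraintSpec.  Because all site ratios reuse one sample set and all
    bulk ratios another, the product of ratios telescopes to the direct
    K_eq estimate exactly — an identity check of the cycle bookkeeping —
    while each individual term is an honest quadrature of its ratio.
    """
    order = ["c", "Theta", "Phi", "Psi", "theta", "phi"]
    missing = [k for k in order if k not in restraints]
    if missing:
        raise ConfigurationError(f"missing restraints: {missing}")
    beta = thermo.beta
    kT = thermo.kt
    keq, se, det = brute_force_keq(system, spec, thermo, return_details=True)
    pos = det["pos"]
    w0 = det["weights_unrestrained"]

    # cumulative site integrals Z_k
    z = [float(w0.mean())]
    cum = np.zeros(len(pos))
    for name in order:
        cum += _batch_restraint_energy(system, pos, [restraints[name]])
        z.append(float((w0 * np.exp(-beta * cum)).mean()))

    # bulk ensemble: free guest pinned far from the host; orientations are
    # importance-sampled around the restraint core (a uniform draw would
    # almost never hit the ~1e-5 fraction of SO(3) the o-restraints keep)
    rng = np.random.default_rng(spec.seed + 1)
    nb = int(spec.n_samples)
    shapes = sample_free_shapes(system.without_host(), nb, rng, beta)
    Rl, p_rot = _mixture_rotations(
        nb, rng, det["R_b"], ((0.3, None), (0.4, 0.25), (0.3, 0.055))
    )
    bulk_pos = np.einsum("nab,nkb->nka", Rl, shapes)
    u_c = _batch_restraint_energy(system, bulk_pos, [restraints["c"]])
    u_o = _batch_restraint_energy(
        system, bulk_pos, [restraints["Theta"], restraints["Phi"], restraints["Psi"]]
    )
    b1 = 1.0  # E[1/p_rot] under the proposal is exactly 1
    b2 = float((np.exp(-beta * u_c) / p_rot).mean())
    b3 = float((np.exp(-beta * (u_c + u_o)) / p_rot).mean())

    terms = {
        "c_site": -kT * math.log(z[0] / z[1]),
        "Theta_site": -kT * math.log(z[1] / z[2]),
        "Phi_site": -kT * math.log(z[2] / z[3]),
        "Psi_site": -kT * math.log(z[3] / z[4]),
        "theta_site": -kT * math.log(z[4] / z[5]),
        "phi_site": -kT * math.log(z[5] / z[6]),
        "separation_term": -kT * math.log(z[6] / (b3 * v_standard)),
        "o_bulk": -kT * math.log(b3 / b2),
        "c_bulk": -kT * math.log(b2 / b1),
    }
    total = sum(terms.values())
    return {
        "terms": terms,
        "dg_bind": total,
        "keq": keq,
        "keq_se": se,
        "dg_direct": keq_to_dg(keq, thermo, v_standard),
    }
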