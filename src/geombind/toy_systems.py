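"""Analytic toy host–guest systems and a Langevin-dynamics sampler.

The host is an infinitely heavy, fixed external field (a choice of analytic
potentials below); the guest is a small bead-and-spring molecule with
harmonic bonds and angles and cosine dihedrals.  A BAOAB splitting-scheme
Langevin integrator samples the canonical ensemble.  Because the host
cannot deform, the conformational restraint leg of the binding cycle is
exercised on the guest's internal coordinates instead.

Units: Å, ps, amu, kcal/mol; angles in degrees at this interface.
No solvent, periodic boundaries or electrostatics: the machinery under
test — restraint bookkeeping and PMF composition — is agnostic to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels as _k
from .colvars import CVSpec, HostFrame, ReferenceStructure, RestraintSpec, _unit_scale
from .conformer_analysis import ConformerModel, DihedralSeries, classify_frame
from .errors import ConfigurationError, ContractError, NumericalError
from .thermo import DEG_PER_RAD, KB, KCAL_PER_MOL_ACCEL, ThermoState


# ----------------------------------------------------------------------
# host potentials
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class HarmonicWell:
    """U(r) = ½ k |r − c|² acting on each coupled bead."""

    k: float
    center: tuple = (0.0, 0.0, 0.0)
    kind_code: int = 1

    def pack(self) -> np.ndarray:
        p = np.zeros(12)
        p[0] = self.k
        p[1:4] = self.center
        return p


@dataclass(frozen=True)
class GaussianWell:
    """Attractive pocket U(r) = −depth · exp(−|r − c|²/2σ²)."""

    depth: float
    sigma: float
    center: tuple = (0.0, 0.0, 0.0)
    kind_code: int = 2

    def pack(self) -> np.ndarray:
        p = np.zeros(12)
        p[0], p[1] = self.depth, self.sigma
        p[2:5] = self.center
        return p


@dataclass(frozen=True)
class DoubleWell:
    """Quartic double well along x with harmonic transverse confinement.

    U = h·((x−cx)² − x0²)²/x0⁴ + ½ k_t ((y−cy)² + (z−cz)²)
    """

    barrier: float
    x0: float
    k_transverse: float
    center: tuple = (0.0, 0.0, 0.0)
    kind_code: int = 3

    def pack(self) -> np.ndarray:
        p = np.zeros(12)
        p[0], p[1], p[2] = self.barrier, self.x0, self.k_transverse
        p[3:6] = self.center
        return p


@dataclass(frozen=True)
class AngularPocket:
    """Gaussian radial shell at r0 modulated by a directional cap:
    U = −depth · exp(−(r−r0)²/2σ²) · ((1+cos γ)/2)^p with γ the angle from
    ``axis``."""

    depth: float
    r0: float
    sigma_r: float
    power: float
    axis: tuple = (1.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)
    kind_code: int = 4

    def pack(self) -> np.ndarray:
        a = np.asarray(self.axis, float)
        a = a / np.linalg.norm(a)
        p = np.zeros(12)
        p[0], p[1], p[2], p[3] = self.depth, self.r0, self.sigma_r, self.power
        p[4:7] = a
        p[7:10] = self.center
        return p


@dataclass(frozen=True)
class SquareWell:
    """Spherical square well (−depth inside radius).  Discontinuous: used
    by quadrature oracles only, never for dynamics (its force is zero)."""

    depth: float
    radius: float
    center: tuple = (0.0, 0.0, 0.0)
    kind_code: int = 5

    def pack(self) -> np.ndarray:
        p = np.zeros(12)
        p[0], p[1] = self.depth, self.radius
        p[2:5] = self.center
        return p


HostPotential = (HarmonicWell, GaussianWell, DoubleWell, AngularPocket, SquareWell)


# ----------------------------------------------------------------------
# system definition
# ----------------------------------------------------------------------
@dataclass
class ToySystem:
    """A bead-and-spring guest in a fixed analytic host field.

    Parameters
    ----------
    masses : (n,) amu, all positive.
    positions : (n, 3) Å, an initial configuration.
    bonds : sequence of (i, j, k, r0) harmonic bonds, k in kcal/(mol·Å²).
    angles : sequence of (i, j, k, k_a, a0_deg) harmonic angles at bead j,
        k_a in kcal/(mol·rad²).
    dihedrals : sequence of (i, j, k, l, k_d, n, delta_deg) cosine terms
        U = k_d (1 + cos(n φ − δ)).
    host : one of the analytic host potentials, or None (bulk).
    host_weights : per-bead coupling strengths to the host field.
    frame : the host reference frame (origin + triad).
    reference : reference structure for orientation/RMSD coordinates.
    """

    masses: np.ndarray
    positions: np.ndarray
    bonds: Sequence[tuple] = ()
    angles: Sequence[tuple] = ()
    dihedrals: Sequence[tuple] = ()
    host: Optional[object] = None
    host_weights: Optional[np.ndarray] = None
    frame: HostFrame = field(default_factory=HostFrame)
    reference: Optional[ReferenceStructure] = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, float)
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.masses.ndim != 1 or len(self.masses) != len(self.positions):
            raise ConfigurationError("masses and positions must agree in length")
        if len(self.masses) < 1:
            raise ConfigurationError("guest needs at least one bead")
        if np.any(self.masses <= 0):
            raise ConfigurationError("all masses must be positive")
        # the host may be a single potential or a sum of potentials, each
        # coupling to the beads with its own weight vector
        hosts = self.host
        if hosts is None:
            hosts = []
        elif isinstance(hosts, HostPotential):
            hosts = [hosts]
        else:
            hosts = list(hosts)
        for h in hosts:
            if not isinstance(h, HostPotential):
                raise ConfigurationError(f"unknown host potential {type(h)}")
        if not hosts:
            self.host = None
        elif len(hosts) == 1:
            self.host = hosts[0]
        else:
            self.host = hosts
        n = len(self.masses)
        w = self.host_weights
        if w is None:
            w = np.ones((len(hosts), n))
        else:
            w = np.atleast_2d(np.asarray(w, float))
            if w.shape == (1, n) and len(hosts) > 1:
                w = np.repeat(w, len(hosts), axis=0)
        if len(hosts) and w.shape != (len(hosts), n):
            raise ConfigurationError(
                f"host_weights shape {w.shape} incompatible with "
                f"{len(hosts)} potentials × {n} beads"
            )
        self.host_weights = w

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def host_list(self) -> list:
        if self.host is None:
            return []
        return self.host if isinstance(self.host, list) else [self.host]

    def without_host(self) -> "ToySystem":
        """The same guest in bulk (host field removed)."""
        return replace(self, host=None, host_weights=None)

    def pack(self) -> tuple:
        """Flatten to the array tuple the numba kernels consume."""
        nb = len(self.bonds)
        bond_idx = np.array([b[:2] for b in self.bonds], dtype=np.int64).reshape(nb, 2)
        bond_par = np.array([b[2:4] for b in self.bonds], float).reshape(nb, 2)
        na = len(self.angles)
        ang_idx = np.array([a[:3] for a in self.angles], dtype=np.int64).reshape(na, 3)
        ang_par = np.array(
            [(a[3], math.radians(a[4])) for a in self.angles], float
        ).reshape(na, 2)
        nd = len(self.dihedrals)
        dih_idx = np.array([d[:4] for d in self.dihedrals], dtype=np.int64).reshape(nd, 4)
        dih_par = np.array(
            [(d[4], d[5], math.radians(d[6])) for d in self.dihedrals], float
        ).reshape(nd, 3)
        hosts = self.host_list
        hk = np.array([h.kind_code for h in hosts], dtype=np.int64)
        hp = (
            np.stack([h.pack() for h in hosts])
            if hosts
            else np.zeros((0, 12))
        )
        hw = (
            self.host_weights.reshape(len(hosts), self.n_beads)
            if hosts
            else np.zeros((0, self.n_beads))
        )
        if self.reference is not None:
            ref_c = self.reference.centered
            ref_dm = self.reference.pair_distances
            sel = self.reference.selection
        else:
            ref_c = np.zeros((1, 3))
            ref_dm = np.zeros(1)
            sel = np.zeros(1, dtype=np.int64)
        return (
            self.masses,
            bond_idx,
            bond_par,
            ang_idx,
            ang_par,
            dih_idx,
            dih_par,
            hk,
            hp,
            hw,
            self.frame.origin,
            self.frame.axes,
            ref_c,
            ref_dm,
            sel,
        )

    def validate_cv(self, spec: CVSpec) -> None:
        """Fail fast when a CV cannot be observed on this system."""
        if spec.kind in ("Theta", "Phi", "Psi", "rmsd"):
            if self.reference is None:
                raise ConfigurationError(
                    f"CV {spec.kind!r} needs a reference structure"
                )
            if spec.kind != "rmsd":
                self.reference.require_orientable()
        if spec.kind == "rmsd_dm":
            if self.reference is None or len(self.reference.selection) < 2:
                raise ConfigurationError("rmsd_dm needs a reference with >= 2 atoms")
        if spec.kind == "dihedral":
            if max(spec.atoms) >= self.n_beads:
                raise ConfigurationError("dihedral atom index out of range")


def _restraint_arrays(restraints: Sequence[RestraintSpec]):
    nr = len(restraints)
    codes = np.array([CVSpec(r.kind, r.atoms).code for r in restraints], dtype=np.int64).reshape(nr)
    atoms = np.stack(
        [CVSpec(r.kind, r.atoms).atoms_array() for r in restraints]
    ).reshape(nr, 4) if nr else np.zeros((0, 4), dtype=np.int64)
    centers = np.array([r.internal_center for r in restraints], float).reshape(nr)
    ks = np.array([r.internal_k for r in restraints], float).reshape(nr)
    return codes, atoms, centers, ks


# ----------------------------------------------------------------------
# energies and forces
# ----------------------------------------------------------------------
def potential_energy(system: ToySystem, positions: np.ndarray) -> float:
    """Total potential (host field + bonded guest terms), kcal/mol."""
    positions = np.atleast_2d(np.asarray(positions, float))
    if positions.shape != system.positions.shape:
        raise ContractError(
            f"positions shape {positions.shape} != {system.positions.shape}"
        )
    if not np.all(np.isfinite(positions)):
        raise ContractError("non-finite positions")
    u, _ = _energy_forces(system, positions)
    return u


def forces(system: ToySystem, positions: np.ndarray) -> np.ndarray:
    """Analytic forces −∇U, kcal/(mol·Å); matches central differences."""
    positions = np.atleast_2d(np.asarray(positions, float))
    if positions.shape != system.positions.shape:
        raise ContractError("positions shape mismatch")
    if not np.all(np.isfinite(positions)):
        raise ContractError("non-finite positions")
    return _energy_forces(system, positions)[1]


def _energy_forces(system: ToySystem, positions: np.ndarray):
    (m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel) = system.pack()
    f = np.zeros_like(positions)
    u = _k.host_energy_force(hk, hp, hw, positions, f)
    u += _k.bonded_energy_force(bi, bp, ai, ap, di, dp, positions, f)
    return u, f


# ----------------------------------------------------------------------
# Langevin dynamics
# ----------------------------------------------------------------------
@dataclass
class MDState:
    """Instantaneous dynamical state of the guest."""

    positions: np.ndarray
    velocities: np.ndarray
    step_index: int = 0
    rng_state: Optional[np.random.Generator] = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, float))
        if self.positions.shape != self.velocities.shape:
            raise ContractError("positions/velocities shape mismatch")
        if not (
            np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))
        ):
            raise ContractError("non-finite state")


def maxwell_velocities(
    masses: np.ndarray, thermo: ThermoState, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell–Boltzmann velocities, Å/ps."""
    sig = np.sqrt(KB * thermo.temperature * KCAL_PER_MOL_ACCEL / masses)
    return rng.normal(size=(len(masses), 3)) * sig[:, None]


def langevin_step(
    system: ToySystem,
    state: MDState,
    thermo: ThermoState,
    dt: float,
    friction: float,
    extra_forces: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> MDState:
    """One BAOAB step.  ``extra_forces(positions) -> (n, 3)`` lets callers
    couple restraints or an extended degree of freedom.

    friction = 0 with a null RNG reduces to velocity Verlet (the symplectic
    limit used by the energy-drift check).  Time-step-too-large detection is
    not attempted; NaN propagation raises with the step index.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    if friction < 0:
        raise ConfigurationError("friction must be >= 0")
    pos = state.positions.copy()
    vel = state.velocities.copy()
    m = system.masses[:, None]

    def total_force(p):
        f = _energy_forces(system, p)[1]
        if extra_forces is not None:
            f = f + extra_forces(p)
        return f

    f = total_force(pos)
    vel += 0.5 * dt * f * KCAL_PER_MOL_ACCEL / m
    pos += 0.5 * dt * vel
    if friction > 0:
        c1 = math.exp(-friction * dt)
        c2 = math.sqrt(1.0 - c1 * c1)
        rng = state.rng_state
        if rng is None:
            raise ConfigurationError("friction > 0 requires an rng_state")
        sig = np.sqrt(KB * thermo.temperature * KCAL_PER_MOL_ACCEL / system.masses)
        vel = c1 * vel + c2 * sig[:, None] * rng.normal(size=vel.shape)
    pos += 0.5 * dt * vel
    f = total_force(pos)
    vel += 0.5 * dt * f * KCAL_PER_MOL_ACCEL / m
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
        raise NumericalError(f"non-finite state after step {state.step_index + 1}")
    return MDState(pos, vel, state.step_index + 1, state.rng_state)


@dataclass
class TrajectoryRecord:
    """Strided record of a trajectory: CV values and energies per frame."""

    steps: np.ndarray
    time_ps: np.ndarray
    cv_names: list
    cv_values: np.ndarray  # (n_frames, n_cvs), public units
    potential: np.ndarray
    kinetic: np.ndarray
    final_positions: np.ndarray
    final_velocities: np.ndarray
    seed: int


def run_trajectory(
    system: ToySystem,
    protocol: dict,
) -> TrajectoryRecord:
    """Sample a trajectory under an optional set of harmonic restraints.

    ``protocol`` keys: n_steps, dt (ps), friction (1/ps), seed (required),
    temperature (K, default 300), stride (default 10), cv_observers
    (list of CVSpec), restraints (list of RestraintSpec).  The same seed
    always reproduces the identical record bit for bit.
    """
    if "seed" not in protocol:
        raise ConfigurationError("protocol must set an explicit seed")
    n_steps = int(protocol.get("n_steps", 1000))
    dt = float(protocol.get("dt", 0.002))
    friction = float(protocol.get("friction", 10.0))
    stride = int(protocol.get("stride", 10))
    seed = int(protocol["seed"])
    thermo = ThermoState(float(protocol.get("temperature", 300.0)))
    observers = list(protocol.get("cv_observers", []))
    restraints = list(protocol.get("restraints", []))
    for spec in observers:
        system.validate_cv(spec)
    for r in restraints:
        system.validate_cv(CVSpec(r.kind, r.atoms))

    rng = np.random.default_rng(seed)
    pos = system.positions.copy()
    vel = maxwell_velocities(system.masses, thermo, rng)
    (m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel) = system.pack()
    r_codes, r_atoms, r_centers, r_ks = _restraint_arrays(restraints)
    nobs = len(observers)
    obs_codes = np.array([o.code for o in observers], dtype=np.int64).reshape(nobs)
    obs_atoms = (
        np.stack([o.atoms_array() for o in observers]).reshape(nobs, 4)
        if nobs
        else np.zeros((0, 4), dtype=np.int64)
    )
    cv_rec, pot, kin, status, bad = _k.run_md(
        pos, vel, m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel,
        r_codes, r_atoms, r_centers, r_ks, obs_codes, obs_atoms,
        dt, friction, thermo.temperature, n_steps, stride, seed % (2**31),
    )
    if status != 0:
        raise NumericalError(f"non-finite dynamics at step {bad}")
    scale = np.array([_unit_scale(o.kind) for o in observers]) if nobs else np.ones(0)
    steps = np.arange(0, n_steps + 1, stride)[: len(pot)]
    return TrajectoryRecord(
        steps=steps,
        time_ps=steps * dt,
        cv_names=[o.kind for o in observers],
        cv_values=cv_rec * scale,
        potential=pot,
        kinetic=kin,
        final_positions=pos,
        final_velocities=vel,
        seed=seed,
    )


# ----------------------------------------------------------------------
# dihedral-series fixture generator
# ----------------------------------------------------------------------
def generate_dihedral_series(
    modes: Sequence[tuple],
    n_frames: int,
    transition_fraction: float = 0.0,
    seed: int = 0,
    time_stride_ps: Optional[float] = None,
    exclusion_threshold: float = 45.0,
) -> DihedralSeries:
    """Sample a (ϕ1, ϕ2) series from a wrapped-Gaussian mixture on the torus.

    ``modes`` is a sequence of (center1_deg, center2_deg, weight,
    spread_deg).  A ``transition_fraction`` of frames is drawn uniformly
    over the part of the torus that lies *outside* every mode's
    ±``exclusion_threshold`` box (including the ± sign images), i.e. from
    genuinely non-conformer geometries, so that classified populations
    reproduce the generator weights.

    Frames are shuffled so transitions interleave with mode visits; the
    whole series is reproducible from the seed.
    """
    modes = list(modes)
    if not modes:
        raise ConfigurationError("at least one mode is required")
    w = np.array([m[2] for m in modes], float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ConfigurationError("mode weights must be nonnegative, not all zero")
    w = w / w.sum()
    if not 0.0 <= transition_fraction < 1.0:
        raise ConfigurationError("transition_fraction must be in [0, 1)")
    for m in modes:
        if m[3] <= 0:
            raise ConfigurationError("angular spreads must be > 0")
    rng = np.random.default_rng(seed)
    n_trans = int(round(transition_fraction * n_frames))
    n_modes = n_frames - n_trans
    counts = rng.multinomial(n_modes, w)
    frames = []
    for (c1, c2, _w, s), k in zip(modes, counts):
        pts = rng.normal([c1, c2], s, size=(k, 2))
        frames.append(pts)
    model = ConformerModel(
        modes=[(f"m{i}", m[0], m[1]) for i, m in enumerate(modes)],
        threshold=exclusion_threshold,
    )
    out = np.empty((0, 2))
    while len(out) < n_trans:
        cand = rng.uniform(-180.0, 180.0, size=(max(64, 2 * n_trans), 2))
        keep = np.array(
            [classify_frame(c[0], c[1], model) == "transition" for c in cand]
        )
        out = np.vstack([out, cand[keep]])
    frames.append(out[:n_trans])
    allf = np.vstack(frames)
    allf = ((allf + 180.0) % 360.0) - 180.0
    allf[allf == -180.0] = 180.0
    rng.shuffle(allf)
    return DihedralSeries(frames=allf, time_stride_ps=time_stride_ps)


# ----------------------------------------------------------------------
# fixture factories (the package's standard study systems)
# ----------------------------------------------------------------------
def make_harmonic_bead(k: float = 2.0, mass: float = 12.0) -> ToySystem:
    """One bead in an isotropic harmonic well at the origin."""
    return ToySystem(
        masses=[mass], positions=[[0.0, 0.0, 0.0]], host=HarmonicWell(k=k)
    )


def make_double_well_bead(
    barrier: float = 2.5,
    x0: float = 1.2,
    k_transverse: float = 50.0,
    mass: float = 12.0,
    frame_origin: tuple = (-5.0, 0.0, 0.0),
) -> ToySystem:
    """One bead in a quartic double well along x; the host-frame origin is
    displaced so the separation CV r = |x − o| is smooth and monotone in x
    across both minima."""
    return ToySystem(
        masses=[mass],
        positions=[[x0, 0.0, 0.0]],
        host=DoubleWell(barrier=barrier, x0=x0, k_transverse=k_transverse),
        frame=HostFrame(origin=np.asarray(frame_origin, float)),
    )


def make_dihedral_chain(k_dihedral: float = 0.0) -> ToySystem:
    """Four-bead chain whose torsion marginal is flat (bonds and angles do
    not couple to φ), optionally with a cosine dihedral term."""
    dih = [(0, 1, 2, 3, k_dihedral, 1.0, 0.0)] if k_dihedral else []
    return ToySystem(
        masses=[14.0, 12.0, 12.0, 14.0],
        positions=[[-1.2, 0.9, 0.3], [-0.75, 0.0, 0.0], [0.75, 0.0, 0.0], [1.2, 0.9, -0.3]],
        bonds=[(0, 1, 80.0, 1.2), (1, 2, 80.0, 1.5), (2, 3, 80.0, 1.2)],
        angles=[(0, 1, 2, 40.0, 110.0), (1, 2, 3, 40.0, 110.0)],
        dihedrals=dih,
    )


def _ry(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array(
        [[math.cos(a), 0, math.sin(a)], [0, 1, 0], [-math.sin(a), 0, math.cos(a)]]
    )


def make_toy_complex(
    depths: tuple = (7.0, 5.0, 3.5),
    sigmas: tuple = (1.0, 0.9, 0.9),
    bond_k: float = 60.0,
    bond_r0: float = 1.5,
    angle_k: float = 30.0,
    angle0_deg: float = 110.0,
) -> ToySystem:
    """The standard three-bead host–guest complex used throughout.

    The host pocket is a sum of three Gaussian wells, one anchoring each
    bead at the pose of a realizable guest conformation.  Distinct anchor
    points break every rotational symmetry of the field (a single
    spherical well would leave the bound guest free to pivot about the
    well center), and the anchor geometry is chiral (bead 2 sits out of
    the plane of the other two), so the bound state has one well-defined
    position, orientation and conformation.  The stored reference
    structure is the energy-minimised bound conformer rotated by −90°
    about y, which puts the bound-state Euler angles near (90, 0, 0) —
    far from gimbal lock — while the bound polar angles sit near
    (θ, φ) ≈ (85, 22).
    """
    from scipy.optimize import minimize

    masses = np.array([14.0, 12.0, 14.0])
    a0 = math.radians(angle0_deg)
    # anchor pose: bead 0 at the pocket mouth, bead 1 straight above it,
    # bead 2 bent by the equilibrium angle and twisted out of plane
    anchors = np.array(
        [
            [2.5, 0.0, 0.0],
            [2.5, bond_r0, 0.0],
            [
                2.5 + bond_r0 * math.sin(a0) * math.cos(math.radians(35.0)),
                bond_r0 - bond_r0 * math.cos(a0),
                bond_r0 * math.sin(a0) * math.sin(math.radians(35.0)),
            ],
        ]
    )
    wells = [
        GaussianWell(depth=d, sigma=s, center=tuple(c))
        for d, s, c in zip(depths, sigmas, anchors)
    ]
    weights = np.eye(3)
    sys0 = ToySystem(
        masses=masses,
        positions=anchors.copy(),
        bonds=[(0, 1, bond_k, bond_r0), (1, 2, bond_k, bond_r0)],
        angles=[(0, 1, 2, angle_k, angle0_deg)],
        host=wells,
        host_weights=weights,
    )

    def fun(x):
        return potential_energy(sys0, x.reshape(-1, 3))

    def jac(x):
        return -forces(sys0, x.reshape(-1, 3)).ravel()

    res = minimize(fun, sys0.positions.ravel(), jac=jac, method="L-BFGS-B")
    bound = res.x.reshape(-1, 3)
    centered = bound - bound.mean(axis=0)
    ref_coords = (_ry(-90.0) @ centered.T).T
    sys0.positions = bound
    sys0.reference = ReferenceStructure(coordinates=ref_coords)
    return sys0
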