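"""Coarse variables of the geometric route, with analytic gradients.

The relative position of a guest in the frame of its host is described by a
separation distance and two polar angles (θ, φ); its orientation by three
ZYZ Euler angles (Θ, Φ, Ψ) extracted from the least-squares rotation onto a
reference structure; conformational deviation by an RMSD coordinate (either
after optimal superposition or on the intramolecular distance matrix); and
local geometry by signed dihedrals.  Each variable exposes its per-atom
gradient so it can be biased or restrained during sampling.

All angles are degrees externally (so force constants carry the
conventional kcal/(mol·degree²) units) and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as _k
from .errors import ConfigurationError, ContractError
from .thermo import DEG_PER_RAD

#: CV kinds and their integer kernel codes
CV_KINDS = {
    "separation_r": 0,
    "theta": 1,
    "phi": 2,
    "Theta": 3,
    "Phi": 4,
    "Psi": 5,
    "rmsd": 6,
    "rmsd_dm": 7,
    "dihedral": 8,
}

ANGULAR_KINDS = frozenset({"theta", "phi", "Theta", "Phi", "Psi", "dihedral"})
#: polar-type angles whose configurational measure carries a sin Jacobian
POLAR_KINDS = frozenset({"theta", "Theta"})
#: angles with a branch cut at ±180°
PERIODIC_KINDS = frozenset({"phi", "Phi", "Psi", "dihedral"})


def _unit_scale(kind: str) -> float:
    """Multiplier taking internal (rad/Å) values to public (deg/Å) units."""
    return DEG_PER_RAD if kind in ANGULAR_KINDS else 1.0


@dataclass(frozen=True)
class HostFrame:
    """Fixed host reference frame: an origin and an orthonormal triad.

    ``axes`` holds the host x, y, z unit vectors as columns.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise ConfigurationError("host frame needs a 3-vector origin and 3x3 axes")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-10):
            raise ConfigurationError("host frame axes must be orthonormal")


@dataclass
class ReferenceStructure:
    """Reference coordinates for orientation and RMSD coordinates.

    Parameters
    ----------
    coordinates : (n, 3) array, Å
    selection : indices of the atoms the fit uses; default all.
    """

    coordinates: np.ndarray
    selection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, float))
        if self.selection is None:
            self.selection = np.arange(len(self.coordinates), dtype=np.int64)
        else:
            self.selection = np.asarray(self.selection, dtype=np.int64)

    @property
    def barycenter(self) -> np.ndarray:
        """Unweighted centroid of the selected atoms (always recomputed)."""
        return self.coordinates[self.selection].mean(axis=0)

    @property
    def centered(self) -> np.ndarray:
        """Selected coordinates with the centroid removed."""
        sel = self.coordinates[self.selection]
        return sel - sel.mean(axis=0)

    @property
    def pair_distances(self) -> np.ndarray:
        """Condensed upper-triangle intramolecular distance matrix."""
        c = self.coordinates[self.selection]
        d = []
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                d.append(np.linalg.norm(c[i] - c[j]))
        return np.asarray(d)

    def require_orientable(self) -> None:
        """Raise unless the selection supports a best-fit rotation."""
        c = self.centered
        if len(c) < 3:
            raise ContractError(
                f"orientation CVs need >= 3 atoms; selection has {len(c)}"
            )
        # collinearity: rank of the centered coordinates
        if np.linalg.matrix_rank(c, tol=1e-8) < 2:
            raise ContractError("orientation CVs need non-collinear reference atoms")


@dataclass
class CVValue:
    """A collective-variable evaluation: value, gradient, degeneracy flag.

    ``value`` is degrees for angular kinds, Å otherwise; ``gradient`` rows
    are per-atom derivatives in (deg or Å) per Å.
    """

    kind: str
    value: float
    gradient: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class RestraintSpec:
    """One harmonic restraint u(ξ) = ½ k (ξ − ξ0)² on a coarse variable.

    ``force_constant`` is kcal/(mol·degree²) for angular kinds and
    kcal/(mol·Å²) otherwise; ``center`` is degrees or Å accordingly.
    """

    kind: str
    center: float
    force_constant: float
    atoms: Optional[tuple] = None  # dihedral atom indices

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ConfigurationError(f"unknown CV kind {self.kind!r}")
        if not self.force_constant > 0:
            raise ConfigurationError("restraint force constant must be > 0")

    def energy(self, value: float) -> float:
        """Restraint energy at a CV value given in public units."""
        dv = value - self.center
        if self.kind in PERIODIC_KINDS:
            dv = (dv + 180.0) % 360.0 - 180.0
        return 0.5 * self.force_constant * dv * dv

    @property
    def internal_k(self) -> float:
        """Force constant in internal units (rad for angles)."""
        if self.kind in ANGULAR_KINDS:
            return self.force_constant * DEG_PER_RAD**2
        return self.force_constant

    @property
    def internal_center(self) -> float:
        if self.kind in ANGULAR_KINDS:
            return self.center / DEG_PER_RAD
        return self.center


@dataclass(frozen=True)
class CVSpec:
    """Identifies a coarse variable to observe or bias."""

    kind: str
    atoms: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in CV_KINDS:
            raise ConfigurationError(f"unknown CV kind {self.kind!r}")
        if self.kind == "dihedral" and (self.atoms is None or len(self.atoms) != 4):
            raise ConfigurationError("dihedral CV needs exactly 4 atom indices")

    @property
    def code(self) -> int:
        return CV_KINDS[self.kind]

    def atoms_array(self) -> np.ndarray:
        a = np.full(4, -1, dtype=np.int64)
        if self.atoms is not None:
            a[: len(self.atoms)] = self.atoms
        return a


# ----------------------------------------------------------------------
# public single-CV operations
# ----------------------------------------------------------------------
def _eval_single(
    kind: str,
    positions: np.ndarray,
    masses: np.ndarray,
    frame: HostFrame,
    reference: Optional[ReferenceStructure],
    atoms: Optional[tuple] = None,
) -> CVValue:
    positions = np.atleast_2d(np.asarray(positions, float))
    if not np.all(np.isfinite(positions)):
        raise ContractError("non-finite coordinates")
    n = len(positions)
    if reference is not None:
        ref_c = reference.centered
        ref_dm = reference.pair_distances
        sel = reference.selection
    else:
        ref_c = np.zeros((1, 3))
        ref_dm = np.zeros(1)
        sel = np.zeros(1, dtype=np.int64)
    spec = CVSpec(kind, atoms)
    codes = np.array([spec.code], dtype=np.int64)
    at = spec.atoms_array()[None, :]
    vals = np.zeros(1)
    grads = np.zeros((1, n, 3))
    flags = _k.eval_cvs(
        codes, at, positions, np.asarray(masses, float), frame.origin, frame.axes,
        ref_c, ref_dm, sel, vals, grads,
    )
    s = _unit_scale(kind)
    return CVValue(kind, vals[0] * s, grads[0] * s, degenerate=bool(flags & 1))


def separation_distance(
    guest_coords: np.ndarray, masses: np.ndarray, host_frame: HostFrame
) -> CVValue:
    """Distance between the guest centre of mass and the host origin.

    The gradient distributes the radial unit vector over the beads by mass
    fraction.  A coincident COM and origin gives value 0 with the gradient
    flagged undefined.
    """
    guest_coords = np.atleast_2d(np.asarray(guest_coords, float))
    if guest_coords.size == 0:
        raise ContractError("guest must have at least one bead")
    return _eval_single("separation_r", guest_coords, masses, host_frame, None)


def polar_angles(
    guest_coords: np.ndarray, masses: np.ndarray, host_frame: HostFrame
) -> tuple[CVValue, CVValue]:
    """Polar angle θ from the host z-axis and azimuth φ in the x–y plane.

    On-axis configurations (sin θ = 0) leave φ undefined; it is returned as
    0 with the degeneracy flag set.
    """
    th = _eval_single("theta", guest_coords, masses, host_frame, None)
    ph = _eval_single("phi", guest_coords, masses, host_frame, None)
    return th, ph


def best_fit_rotation(
    moving_coords: np.ndarray, reference: ReferenceStructure
) -> np.ndarray:
    """Least-squares proper rotation mapping the centered reference onto the
    centered moving selection (quaternion construction; det = +1 always)."""
    reference.require_orientable()
    moving_coords = np.atleast_2d(np.asarray(moving_coords, float))
    masses = np.ones(len(moving_coords))
    q, R, _xb, _xt, _dq, ok = _k.best_fit(
        moving_coords, masses, reference.centered, reference.selection
    )
    if not ok:
        raise ContractError(
            "degenerate best-fit problem (collinear or symmetric selection)"
        )
    return R


def euler_angles(rotation: np.ndarray) -> tuple[float, float, float, bool]:
    """ZYZ Euler angles (Θ, Φ, Ψ) in degrees of a proper rotation matrix.

    Returns (Θ, Φ, Ψ, gimbal_flag).  At gimbal lock (Θ = 0 or 180°) only
    Φ+Ψ (resp. Φ−Ψ) is defined; the convention Φ = 0 is returned with the
    flag set.
    """
    R = np.asarray(rotation, float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-8 or not np.allclose(
        R.T @ R, np.eye(3), atol=1e-8
    ):
        raise ContractError("input is not a proper rotation matrix (to 1e-8)")
    th, ph, ps, lock = _k.euler_zyz(R)
    return th * DEG_PER_RAD, ph * DEG_PER_RAD, ps * DEG_PER_RAD, bool(lock)


def euler_to_matrix(Theta: float, Phi: float, Psi: float) -> np.ndarray:
    """Compose R = Rz(Φ) Ry(Θ) Rz(Ψ) from angles in degrees."""
    a, b, c = np.deg2rad([Phi, Theta, Psi])

    def rz(x):
        return np.array([[np.cos(x), -np.sin(x), 0], [np.sin(x), np.cos(x), 0], [0, 0, 1]])

    ry = np.array(
        [[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]]
    )
    return rz(a) @ ry @ rz(c)


def rmsd_cv(
    moving_coords: np.ndarray,
    reference: ReferenceStructure,
    mode: str = "fitted",
) -> CVValue:
    """Conformational RMSD coordinate.

    ``fitted``: RMSD after optimal superposition (invariant under any
    rigid-body motion of the moving set).  ``distance_matrix``: RMS
    difference of all intramolecular pair distances.
    """
    moving_coords = np.atleast_2d(np.asarray(moving_coords, float))
    if len(reference.selection) != 0 and reference.selection.max() >= len(moving_coords):
        raise ContractError("selection exceeds moving coordinate count")
    if mode == "fitted":
        reference.require_orientable()
        masses = np.ones(len(moving_coords))
        return _eval_single("rmsd", moving_coords, masses, HostFrame(), reference)
    if mode == "distance_matrix":
        if len(reference.selection) < 2:
            raise ContractError("distance_matrix RMSD needs >= 2 atoms")
        masses = np.ones(len(moving_coords))
        return _eval_single("rmsd_dm", moving_coords, masses, HostFrame(), reference)
    raise ConfigurationError(f"unknown rmsd mode {mode!r}")


def dihedral(p1, p2, p3, p4) -> CVValue:
    """Signed IUPAC torsion in (−180, 180]: cis = 0, trans = 180."""
    pts = np.asarray([p1, p2, p3, p4], float)
    for a, b in ((0, 1), (1, 2), (2, 3)):
        if np.linalg.norm(pts[a] - pts[b]) < 1e-10:
            raise ContractError("consecutive dihedral points coincide")
    b2 = pts[2] - pts[1]
    n1 = np.cross(pts[1] - pts[0], b2)
    n2 = np.cross(b2, pts[3] - pts[2])
    degenerate = min(np.linalg.norm(n1), np.linalg.norm(n2)) < 1e-10
    phi, g1, g2, g3, g4 = _k.dihedral_val_grad(pts[0], pts[1], pts[2], pts[3])
    grad = np.stack([g1, g2, g3, g4]) * DEG_PER_RAD
    val = phi * DEG_PER_RAD
    if val <= -180.0:
        val += 360.0
    return CVValue("dihedral", val, grad, degenerate=degenerate)
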