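"""Extended-system adaptive biasing force (eABF) sampling of 1-D PMFs.

A fictitious particle λ is coupled harmonically to the collective variable
ξ; the adaptive bias — the negated running mean of the instantaneous force
k(ξ−λ) accrued in bins of λ — acts on λ only, so the physical beads never
feel the CV's inverse-gradient machinery.  The bias is ramped in linearly
until a bin has seen ``n_full`` samples.  Free-energy profiles are
recovered either from the λ histogram directly ("naive": the estimate is
the true PMF convolved with the k_BT/k coupling Gaussian) or corrected for
the coupling convolution with the CZAR estimator, which combines the
logarithmic derivative of the sampled ξ distribution with the mean
displacement of λ conditioned on ξ.

Domains are stratified into up to five consecutive, non-overlapping
windows whose λ is confined by reflecting walls; adjacent windows merge by
mean-force continuity.  Statistical errors come from recomputing profiles
on the two halves of the sampling ("two blocks of equal size").

Histogram accumulators are kept in internal units (radians); profiles and
window bounds are in public units (degrees/Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels as _k
from .colvars import (
    ANGULAR_KINDS,
    CVSpec,
    POLAR_KINDS,
    RestraintSpec,
)
from .errors import ConfigurationError, ContractError, NumericalError
from .thermo import DEG_PER_RAD, ThermoState
from .toy_systems import (
    MDState,
    ToySystem,
    _restraint_arrays,
    maxwell_velocities,
)

#: default bin widths in public units: 1° angular, 0.05 Å RMSD, 0.1 Å separation
DEFAULT_BIN_WIDTH = {
    "theta": 1.0,
    "phi": 1.0,
    "Theta": 1.0,
    "Phi": 1.0,
    "Psi": 1.0,
    "dihedral": 1.0,
    "rmsd": 0.05,
    "rmsd_dm": 0.05,
    "separation_r": 0.1,
}

MAX_WINDOWS = 5


@dataclass
class ExtendedDOF:
    """The fictitious particle carrying the adaptive bias.

    ``coupling_k`` is kcal/(mol·deg²) for angular CVs, kcal/(mol·Å²)
    otherwise; the default choices keep the RMS λ−ξ mismatch
    √(k_BT/k) below one bin width.
    """

    lambda_value: float = 0.0
    lambda_mass: float = 50.0
    coupling_k: float = 100.0
    friction: float = 10.0
    lambda_velocity: float = 0.0

    def __post_init__(self) -> None:
        if self.coupling_k <= 0 or self.lambda_mass <= 0:
            raise ConfigurationError("coupling_k and lambda_mass must be > 0")


def default_extended_dof(kind: str) -> ExtendedDOF:
    """Coupling defaults keep √(k_BT/k) below one default bin width:
    0.92° for angles (1° bins), 0.049 Å for RMSD (0.05 Å bins), 0.077 Å
    for separation (0.1 Å bins)."""
    if kind in ANGULAR_KINDS:
        return ExtendedDOF(lambda_mass=200.0, coupling_k=0.7)
    if kind in ("rmsd", "rmsd_dm"):
        return ExtendedDOF(lambda_mass=50.0, coupling_k=250.0)
    return ExtendedDOF(lambda_mass=50.0, coupling_k=100.0)


def default_dt(kind: str) -> float:
    """Time step keeping the stiff ξ–λ mode at ω·dt ≲ 0.3.

    Angular couplings in kcal/(mol·deg²) translate to several thousand
    kcal/(mol·rad²), so angular windows integrate at 0.5 fs; distance-like
    CVs are soft enough for 2 fs.
    """
    return 0.0005 if kind in ANGULAR_KINDS else 0.002


@dataclass
class ABFHistogram:
    """Binned eABF accumulators over one window [lo, hi] (public units).

    Accumulator arrays have shape (2, n_bins): the two rows are the first
    and second halves of sampling, for two-block error estimation.
    Internally (rows of ``force_sum``) forces are kcal/mol per radian for
    angular CVs.
    """

    cv: CVSpec
    lo: float
    hi: float
    bin_width: float
    n_full: int = 200
    force_sum: np.ndarray = None
    count: np.ndarray = None
    xi_count: np.ndarray = None
    lam_sum: np.ndarray = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        ratio = (self.hi - self.lo) / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigurationError(
                f"window [{self.lo}, {self.hi}] is not an integral number of "
                f"bins of width {self.bin_width}"
            )
        nb = self.n_bins
        for name in ("force_sum", "count", "xi_count", "lam_sum"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((2, nb)))

    @classmethod
    def for_cv(
        cls,
        cv: CVSpec,
        lo: float,
        hi: float,
        bin_width: Optional[float] = None,
        n_full: int = 200,
    ) -> "ABFHistogram":
        if bin_width is None:
            bin_width = DEFAULT_BIN_WIDTH[cv.kind]
        return cls(cv=cv, lo=lo, hi=hi, bin_width=bin_width, n_full=n_full)

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.bin_width))

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def unit_scale(self) -> float:
        """Internal-to-public unit factor for the CV axis."""
        return DEG_PER_RAD if self.cv.kind in ANGULAR_KINDS else 1.0

    @property
    def total_samples(self) -> float:
        return float(self.count.sum())


@dataclass
class PMFProfile:
    """A binned free-energy profile w(ξ), anchored so min w = 0.

    ``gradient`` holds dA/dξ per bin (public units) when the profile came
    from an ABF estimator — window merging uses it for mean-force
    continuity.  ``block_values`` holds the two half-sampling replicas.
    Polar-type angles (θ, Θ) are stored Jacobian-free: the sin ξ measure is
    divided out of the marginal and re-applied during restraint quadrature.
    """

    centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)
    gradient: Optional[np.ndarray] = None
    block_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.values = np.asarray(self.values, float)
        if self.counts is None:
            self.counts = np.ones_like(self.values)
        self.counts = np.asarray(self.counts, float)
        if len(self.centers) != len(self.values):
            raise ContractError("centers/values length mismatch")
        if len(self.centers) > 1 and np.any(np.diff(self.centers) <= 0):
            raise ContractError("bin centers must increase strictly")

    @property
    def bin_width(self) -> float:
        if len(self.centers) < 2:
            return float(self.metadata.get("bin_width", 1.0))
        return float(self.centers[1] - self.centers[0])

    @property
    def temperature(self) -> Optional[float]:
        t = self.metadata.get("temperature")
        return None if t is None else float(t)

    def anchored(self) -> "PMFProfile":
        """Copy shifted so the minimum over sampled bins is zero."""
        good = np.isfinite(self.values)
        shift = self.values[good].min() if good.any() else 0.0
        out = replace(self, values=self.values - shift)
        if self.block_values is not None:
            bv = self.block_values.copy()
            for b in range(bv.shape[0]):
                g = np.isfinite(bv[b])
                if g.any():
                    bv[b] -= bv[b][g].min()
            out.block_values = bv
        return out


# ----------------------------------------------------------------------
# sampling drivers
# ----------------------------------------------------------------------
def _steer_into_window(
    system, pos, vel, cv, xi0, target, k_pub, restraints, thermo, dt, friction, seed,
    n_segments=80, steps_per_segment=400,
):
    """Drag the CV from xi0 to target with a moving harmonic center.

    The center moves in small increments so the pulling force never exceeds
    ~k·(increment + thermal width); pos/vel are updated in place.
    """
    (m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel) = system.pack()
    from .colvars import PERIODIC_KINDS

    if cv.kind in PERIODIC_KINDS:
        # take the short way around the branch cut
        if target - xi0 > 180.0:
            target -= 360.0
        elif target - xi0 < -180.0:
            target += 360.0
    path = np.linspace(xi0, target, n_segments + 1)[1:]
    no_obs = np.zeros(0, dtype=np.int64)
    no_obs_at = np.zeros((0, 4), dtype=np.int64)
    for i, c in enumerate(path):
        rs = list(restraints) + [RestraintSpec(cv.kind, c, k_pub, atoms=cv.atoms)]
        r_codes, r_atoms, r_centers, r_ks = _restraint_arrays(rs)
        _, _, _, status, bad = _k.run_md(
            pos, vel, m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel,
            r_codes, r_atoms, r_centers, r_ks, no_obs, no_obs_at,
            dt, friction, thermo.temperature, steps_per_segment,
            steps_per_segment, (seed + 7919 * i) % (2**31),
        )
        if status != 0:
            raise NumericalError(f"steering diverged at segment {i}, step {bad}")


def run_eabf_window(
    system: ToySystem,
    hist: ABFHistogram,
    n_steps: int,
    seed: int,
    thermo: ThermoState = ThermoState(),
    restraints: Sequence[RestraintSpec] = (),
    ext: Optional[ExtendedDOF] = None,
    dt: Optional[float] = None,
    friction: float = 10.0,
    state: Optional[MDState] = None,
    sample_stride: int = 10,
):
    """Run eABF in one window, accumulating into ``hist`` in place.

    Returns (samples, final_state, ext) where ``samples`` are strided
    (ξ, λ) pairs in public units.  Passing the previous window's final
    state chains stratified windows.
    """
    system.validate_cv(hist.cv)
    for r in restraints:
        system.validate_cv(CVSpec(r.kind, r.atoms))
    if ext is None:
        ext = default_extended_dof(hist.cv.kind)
    if dt is None:
        dt = default_dt(hist.cv.kind)
    rng = np.random.default_rng(seed)
    if state is None:
        pos = system.positions.copy()
        vel = maxwell_velocities(system.masses, thermo, rng)
    else:
        pos = state.positions.copy()
        vel = state.velocities.copy()
    (m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel) = system.pack()
    r_codes, r_atoms, r_centers, r_ks = _restraint_arrays(restraints)
    s = hist.unit_scale
    lo_i, hi_i = hist.lo / s, hist.hi / s
    k_i = ext.coupling_k * s * s
    hist._coupling_internal = k_i  # CZAR needs the actual coupling later

    def cv_value():
        vals = np.zeros(1)
        grads = np.zeros((1, len(m), 3))
        _k.eval_cvs(
            np.array([hist.cv.code], dtype=np.int64),
            hist.cv.atoms_array()[None, :],
            pos, m, org, axes, rc, rdm, sel, vals, grads,
        )
        return vals[0]

    xi0 = cv_value()
    margin = 0.5 * (hi_i - lo_i) / hist.n_bins
    if not (lo_i + margin <= xi0 <= hi_i - margin):
        # drag the system inside the window before coupling lambda to it:
        # a clamped lambda plus a stiff spring to a far-outside CV would
        # blow the dynamics up
        _steer_into_window(
            system, pos, vel, hist.cv, xi0 * s, 0.5 * (hist.lo + hist.hi),
            ext.coupling_k, restraints, thermo, dt, friction, seed + 1,
        )
        xi0 = cv_value()
    lam = ext.lambda_value / s
    if not lo_i <= lam <= hi_i:
        lam = min(max(xi0, lo_i), hi_i)
    samples, lam, lamv, status, bad = _k.run_eabf(
        pos, vel, m, bi, bp, ai, ap, di, dp, hk, hp, hw, org, axes, rc, rdm, sel,
        r_codes, r_atoms, r_centers, r_ks,
        hist.cv.code, hist.cv.atoms_array(),
        lo_i, hi_i, hist.n_bins, k_i, ext.lambda_mass, ext.friction, hist.n_full,
        lam, ext.lambda_velocity / s,
        dt, friction, thermo.temperature, n_steps, seed % (2**31), sample_stride,
        hist.force_sum, hist.count, hist.xi_count, hist.lam_sum, 1,
    )
    if status != 0:
        raise NumericalError(
            f"eABF diverged at step {bad} (cv={hist.cv.kind}, lambda={lam})"
        )
    new_ext = replace(ext, lambda_value=lam * s, lambda_velocity=lamv * s)
    return samples * s, MDState(pos, vel), new_ext


def eabf_coupled_step(
    system: ToySystem,
    state: MDState,
    ext: ExtendedDOF,
    hist: ABFHistogram,
    thermo: ThermoState,
    dt: float,
    rng: np.random.Generator,
    restraints: Sequence[RestraintSpec] = (),
    friction: float = 10.0,
):
    """A single eABF step (pedagogical per-step interface).

    The driver :func:`run_eabf_window` is the efficient path; this wrapper
    advances the same kernel by one step, reseeding from ``rng``, and
    returns the updated (state, ext, hist) triple.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    _, new_state, new_ext = run_eabf_window(
        system,
        hist,
        n_steps=1,
        seed=seed,
        thermo=thermo,
        restraints=restraints,
        ext=ext,
        dt=dt,
        friction=friction,
        state=state,
        sample_stride=1,
    )
    new_state.step_index = state.step_index + 1
    return new_state, new_ext, hist


# ----------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------
def _integrate_segments(grad: np.ndarray, width: float, mask: np.ndarray) -> np.ndarray:
    """Trapezoid-integrate dA/dξ over bin centers, per contiguous segment."""
    a = np.full_like(grad, np.nan)
    i = 0
    n = len(grad)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        a[i] = 0.0
        while j + 1 < n and mask[j + 1]:
            a[j + 1] = a[j] + 0.5 * (grad[j] + grad[j + 1]) * width
            j += 1
        i = j + 1
    return a


def estimate_pmf(
    hist: ABFHistogram,
    samples: Optional[np.ndarray] = None,
    estimator: str = "czar",
    thermo: ThermoState = ThermoState(),
    window_id: int = 0,
) -> PMFProfile:
    """Free-energy profile from eABF accumulators.

    ``naive`` integrates the binned mean force on λ (a k_BT/k-broadened
    estimate of the PMF); ``czar`` removes the λ–ξ coupling convolution
    using the sampled ξ distribution.  Empty bins inside the sampled
    region are flagged as gaps and each contiguous segment is integrated
    separately.  Polar-type angles are returned Jacobian-free.
    """
    if estimator not in ("naive", "czar"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    if hist.total_samples == 0:
        raise ContractError("no samples accumulated: cannot estimate a PMF")
    kT = thermo.kt
    s = hist.unit_scale
    width_i = hist.bin_width / s

    def one_block(fsum, cnt, xcnt, lsum):
        if estimator == "naive":
            mask = cnt > 0
            mean_f = np.where(mask, fsum / np.maximum(cnt, 1), 0.0)
            grad = -mean_f  # dA/dlambda = -<F_sys>
            used = cnt
        else:
            mask = xcnt > 0
            # CZAR: dA/dxi = -kT dln rho/dxi + k <lambda - xi_center>
            logc = np.where(mask, np.log(np.maximum(xcnt, 1e-300)), np.nan)
            dlog = np.full(len(logc), np.nan)
            for i in range(len(logc)):
                if not mask[i]:
                    continue
                if 0 < i < len(logc) - 1 and mask[i - 1] and mask[i + 1]:
                    dlog[i] = (logc[i + 1] - logc[i - 1]) / (2 * width_i)
                elif i + 1 < len(logc) and mask[i + 1]:
                    dlog[i] = (logc[i + 1] - logc[i]) / width_i
                elif i - 1 >= 0 and mask[i - 1]:
                    dlog[i] = (logc[i] - logc[i - 1]) / width_i
                else:
                    dlog[i] = 0.0
            disp = np.where(mask, lsum / np.maximum(xcnt, 1), 0.0)
            grad = np.where(mask, -kT * dlog + k_couple_i * disp, 0.0)
            used = xcnt
        a = _integrate_segments(grad, width_i, mask)
        return a, grad, used, mask

    # coupling constant in internal units: recover from defaults is wrong if
    # a custom ext was used; callers may stash it in the histogram metadata.
    k_couple_i = getattr(hist, "_coupling_internal", None)
    if k_couple_i is None:
        k_couple_i = default_extended_dof(hist.cv.kind).coupling_k * s * s

    tot = one_block(
        hist.force_sum.sum(0), hist.count.sum(0), hist.xi_count.sum(0), hist.lam_sum.sum(0)
    )
    a, grad, used, mask = tot
    blocks = []
    for b in range(2):
        ab, _, _, _ = one_block(
            hist.force_sum[b], hist.count[b], hist.xi_count[b], hist.lam_sum[b]
        )
        blocks.append(ab)
    centers_i = hist.lo / s + (np.arange(hist.n_bins) + 0.5) * width_i
    if hist.cv.kind in POLAR_KINDS:
        jac = kT * np.log(np.clip(np.sin(centers_i), 1e-12, None))
        a = a + jac
        blocks = [b + jac for b in blocks]
    interior = mask.nonzero()[0]
    gaps = False
    if len(interior) > 1:
        gaps = bool((~mask[interior[0] : interior[-1] + 1]).any())
    prof = PMFProfile(
        centers=hist.centers,
        values=a,
        counts=used,
        gradient=grad / s,
        block_values=np.stack(blocks),
        metadata={
            "cv": hist.cv.kind,
            "units": "deg" if hist.cv.kind in ANGULAR_KINDS else "A",
            "bin_width": hist.bin_width,
            "temperature": thermo.temperature,
            "estimator": estimator,
            "window_id": window_id,
            "jacobian_removed": hist.cv.kind in POLAR_KINDS,
            "gaps": gaps,
        },
    )
    return prof.anchored()


# ----------------------------------------------------------------------
# window stratification and merging
# ----------------------------------------------------------------------
def stratify_windows(
    lo: float, hi: float, n_windows: int, bin_width: float
) -> list:
    """Split [lo, hi] into up to five consecutive, non-overlapping windows
    of near-equal width, with boundaries snapped to bin edges."""
    if n_windows < 1:
        raise ConfigurationError("n_windows must be >= 1")
    if n_windows > MAX_WINDOWS:
        raise ConfigurationError(f"at most {MAX_WINDOWS} windows are supported")
    total = (hi - lo) / bin_width
    if abs(total - round(total)) > 1e-9:
        raise ConfigurationError("[lo, hi] must span a whole number of bins")
    total = int(round(total))
    base, rem = divmod(total, n_windows)
    sizes = [base + (1 if i < rem else 0) for i in range(n_windows)]
    if min(sizes) < 2:
        raise ConfigurationError("window narrower than 2 bins")
    out = []
    a = lo
    for sz in sizes:
        b = lo + round((a - lo) / bin_width + sz) * bin_width
        b = min(b, hi)
        out.append((a, b))
        a = b
    out[-1] = (out[-1][0], hi)
    return out


def merge_windows(profiles: Sequence[PMFProfile]) -> PMFProfile:
    """Join contiguous window profiles into one by mean-force continuity.

    When per-bin gradients are available (any ABF estimate), the gradients
    are concatenated and re-integrated — continuity of the mean force at
    each seam is then automatic.  Otherwise successive profiles are offset
    so values extrapolate smoothly across the seam.
    """
    if not profiles:
        raise ContractError("no profiles to merge")
    profs = sorted(profiles, key=lambda p: p.centers[0])
    if len(profs) == 1:
        return profs[0].anchored()
    w = profs[0].bin_width
    for p in profs[1:]:
        if abs(p.bin_width - w) > 1e-9:
            raise ContractError("windows have mismatched bin widths")
    for a, b in zip(profs[:-1], profs[1:]):
        gap = b.centers[0] - a.centers[-1]
        if abs(gap - w) > 1e-6 * w:
            raise ContractError(
                f"windows are not contiguous: gap of {gap} between "
                f"{a.centers[-1]} and {b.centers[0]}"
            )
    centers = np.concatenate([p.centers for p in profs])
    counts = np.concatenate([p.counts for p in profs])
    meta = dict(profs[0].metadata)
    meta["window_id"] = "merged"
    if all(p.gradient is not None for p in profs):
        grad = np.concatenate([p.gradient for p in profs])
        mask = np.isfinite(grad) & (counts > 0)
        vals = _integrate_segments(grad, w, mask)
        bv = None
        if all(p.block_values is not None for p in profs):
            bv = np.stack(
                [_merge_by_value([p.block_values[b] for p in profs], w) for b in range(2)]
            )
        out = PMFProfile(
            centers=centers, values=vals, counts=counts, metadata=meta,
            gradient=grad, block_values=bv,
        )
        return out.anchored()
    # value-matching fallback
    out = PMFProfile(
        centers=centers,
        values=_merge_by_value([p.values for p in profs], w),
        counts=counts,
        metadata=meta,
    )
    return out.anchored()


def _merge_by_value(segments, w: float) -> np.ndarray:
    """Offset successive segments so values extrapolate smoothly across
    each seam (average of the two boundary slopes)."""
    vals = [np.asarray(segments[0], float).copy()]
    for seg in segments[1:]:
        pa = vals[-1]
        seg = np.asarray(seg, float)
        slope_a = (pa[-1] - pa[-2]) / w if len(pa) > 1 else 0.0
        slope_b = (seg[1] - seg[0]) / w if len(seg) > 1 else 0.0
        target = pa[-1] + 0.5 * (slope_a + slope_b) * w
        vals.append(seg + (target - seg[0]))
    return np.concatenate(vals)


# ----------------------------------------------------------------------
# two-block error estimation
# ----------------------------------------------------------------------
def block_error(data, estimator=None, n_blocks: int = 2) -> float:
    """Statistical error from equal data blocks.

    With ``estimator`` None, ``data`` are the per-block estimates of the
    target quantity themselves: for two blocks the error is half their
    absolute difference; for more, the standard error over blocks.  With a
    callable ``estimator``, ``data`` is a sample array that is split into
    ``n_blocks`` equal blocks (trailing remainder truncated) and the
    estimator is applied to each.
    """
    if estimator is not None:
        data = np.asarray(data)
        if len(data) < n_blocks:
            raise ContractError(
                f"{len(data)} samples cannot fill {n_blocks} blocks"
            )
        size = len(data) // n_blocks
        data = [estimator(data[i * size : (i + 1) * size]) for i in range(n_blocks)]
    vals = np.asarray(data, float)
    if len(vals) < 2:
        raise ContractError("need at least two block values")
    if len(vals) == 2:
        return 0.5 * abs(vals[1] - vals[0])
    return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
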