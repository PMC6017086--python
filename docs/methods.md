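# Methods

This note records the models, conventions and numerical choices behind
`geombind`, in the spirit of a methods section: what is computed, under
which assumptions, and what the toy validations do and do not demonstrate.

## The geometric route

Host–guest association is decomposed into a thermodynamic cycle.  In the
bound state, harmonic restraints are imposed stepwise on a conformational
RMSD coordinate (u_c), on the three ZYZ Euler angles of the guest's
best-fit rotation relative to a reference structure (u_o = u_Θ+u_Φ+u_Ψ),
and on the two polar angles of its centre of mass in the host frame
(u_a = u_θ+u_φ).  Each imposition's free energy is obtained from a 1-D PMF
w(ξ) along the restrained variable,

ΔG_impose = −(1/β) ln[∫e^(−β(w+u)) J dξ / ∫e^(−βw) J dξ],

which is an exact identity because u depends on ξ alone.  J = sin ξ for
θ and Θ: profiles of polar-type angles are stored *Jacobian-free* (the
sin ξ of the configurational measure is divided out by the estimator and
re-applied during quadrature), so that a stiffly bound angular leg looks
harmonic rather than sine-skewed.  The guest is then pulled to a reference
separation r* along the ray through the bound centre of mass, with all six
restraints active; the spherical-radius PMF along this leg, anchored to 0
at r*, *includes* the −(2/β) ln r geometric term, which is exactly what
the factorisation of the standard-state term needs:

−(1/β) ln(S*·I*·C°),   I* = ∫_basin e^(−βw(r)) dr,
S* = r*² ∫∫ e^(−βu_a) sin θ dθ dφ,   C° = 1/V°.

The factorisation assumes the interior free energy varies negligibly over
the angular width of u_a (≈2.4° at the default stiffness) — sub-0.05
kcal/mol on the shipped systems.  In the bulk the orientational release is
analytic (Haar measure over SO(3); exact for a rigid guest), and the
conformational release is one more PMF on the free guest.  Composition is
a plain sum in the site-release / bulk-impose sign convention; K_eq =
exp(−βΔG°)·V°.  The printed standard-state volume for 1 M is taken as
V° = 1661 Å³ (C° = 1/1661 Å⁻³); it is configurable everywhere.

## Coarse variables

* Separation and polar angles use the mass-weighted guest COM in the host
  frame (orthonormal triad + origin).  On-axis and zero-distance
  degeneracies return deterministic values with explicit flags instead of
  raising mid-trajectory.
* The best-fit rotation is the quaternion (Horn) construction, which can
  only produce proper rotations; its analytic gradient comes from
  first-order perturbation of the top eigenvector of the 4×4 quaternion
  matrix.  Euler angles use the ZYZ convention (matching the
  polar/azimuth pairing of the positional angles); at gimbal lock
  (Θ = 0, 180°) only Φ±Ψ is defined and the Φ = 0 convention is returned
  flagged.  The convention is fixed by round-trip tests rather than by
  any external reference.
* Conformational RMSD supports both the best-fit ("fitted", default) and
  the intramolecular distance-matrix interpretation.  The fitted form is
  the default restraint coordinate because rigid-body motion is already
  handled by the five angles; both are available since the two readings
  of "distance RMSD" differ only for non-rigid deformations.
* Every gradient is validated against central finite differences at 1e-6.

## Sampling

Dynamics is BAOAB Langevin (velocity Verlet with an interleaved
Ornstein–Uhlenbeck step) in Å/ps/amu/kcal·mol⁻¹ units, k_B =
0.0019872041 kcal/(mol·K), default temperature 300 K (configurable; the
toy systems fix no particular temperature scale).  No solvent, cutoffs or
barostats: the machinery under test — restraints and PMF composition — is
agnostic to them.  The host is an infinitely heavy analytic field, so the
"host conformational restraint" leg of the cycle is exercised on the
guest's internal coordinates instead; the cycle algebra is identical.

eABF couples a fictitious particle λ (mass m_λ, same thermostat) to the
CV with ½k(ξ−λ)²; the adaptive bias on λ is the negated running mean of
the instantaneous coupling force k(ξ−λ) accrued in 1° / 0.05 Å / 0.1 Å
bins (angles / RMSD / separation), ramped linearly until a bin holds
N_full = 200 samples.  λ reflects at window walls.  Both BAOAB half-kicks
use the same force field evaluation — applying the bias in only one
half-kick is an O(dt) inconsistency that measurably corrupts the
conditional λ|ξ statistics.  Coupling defaults keep √(k_BT/k) under one
bin width (0.7 kcal/(mol·deg²), 250 and 100 kcal/(mol·Å²)); because the
angular couplings are stiff in radian units, angular windows integrate at
0.5 fs and distance-like windows at 2 fs (ω·dt ≲ 0.3 for the coupled
mode).  When a window starts with the CV outside it, the system is first
dragged in with a moving harmonic centre (a clamped λ coupled to a distant
ξ would explode).

The default estimator is CZAR, which removes the λ–ξ convolution:
dA/dξ = −(1/β)·d ln ρ̃/dξ + k(⟨λ⟩_ξ − ξ), with the logarithmic derivative
from centred differences of binned counts and the conditional mean from a
wrapped-displacement accumulator.  The naive estimator (integrated mean
force on λ) is retained for the stiff-coupling regime and pedagogy.
Empty interior bins are flagged as gaps and each contiguous segment is
integrated separately; a PMF with gaps is rejected by the restraint
quadrature rather than silently bridged.  Domains are stratified into at
most five equal, non-overlapping windows snapped to bin edges; merging
concatenates per-bin mean forces and re-integrates, so mean-force
continuity at seams is automatic.  Statistical errors recompute each
target from the two halves of sampling (error = half the absolute
difference for two blocks; standard error over blocks beyond that).
Two-block errors on strongly autocorrelated ABF histories are rough — the
force-constant-invariance check uses twice the propagated error as its
band for exactly this reason.

## Toy systems and the oracle

The standard complex binds a bent three-bead guest (bonds k = 60
kcal/(mol·Å²), r0 = 1.5 Å; angle k = 30 kcal/(mol·rad²), 110°) in a
pocket made of three Gaussian wells, one anchoring each bead (depths
7/5/3.5 kcal/mol, widths 1.0/0.9/0.9 Å).  Distinct anchor points are
essential: a single spherical well commutes with rotations about its
centre, leaving the bound orientation free and the angular legs
ill-defined.  The anchor pose is chiral (the third bead sits out of
plane), so there is no mirror-degenerate bound state.  The reference
structure is the minimised bound conformer pre-rotated by −90° about y,
placing the bound Euler angles near (90, 0, 0) — far from gimbal lock.
Default protocol: restraints 0.1 kcal/(mol·deg²) and 100 kcal/(mol·Å²)
(the values used consistently across the cycle; the composed ΔG°bind must
not depend on them), r* = 8 Å where the field is < 1e-5 kcal/mol,
separation stratified into two windows, Euler windows ±60°, polar windows
±25° around the bound values (3–5 σ of the respective bound
distributions), RMSD domain [0, 0.8] Å.  Sampling lengths (2·10⁶ steps
per angular leg, 1.2·10⁶ per conformational leg, 4.8·10⁶ for the
separation) were chosen so the propagated two-block error sits near 0.1
kcal/mol; the acceptance script uses the same sizes.

The oracle evaluates K_eq = ∫_site d³x₁ ⟨e^(−βU_field)⟩_free directly:
exhaustively on a 3-D grid for one-bead guests (slab-chunked, so memory
stays bounded), and by importance-sampling Monte Carlo for flexible
guests — internal shapes drawn exactly from the bond/angle Boltzmann
measure (rejection sampling with the r² sin α volume element),
orientations from a Haar/concentrated mixture around the minimised bound
pose, COM positions from a uniform/Gaussian mixture over the site box.
Tight mixture components are required: the strongly restrained cores the
cycle ratios integrate over occupy ~1e-5 of orientation space, and a
plain uniform proposal would never resolve them.  The product-of-ratios
reconstruction shares one sample set per ensemble, so it telescopes to
the direct K_eq estimate exactly — an identity test of the cycle
bookkeeping, not an accuracy statement.  The site box (half-widths 4 Å
around the pocket) contributes its unbound volume (~500 Å³) to K_eq;
with the shipped well depths the bound core is ~2·10⁴ larger, so the
box-definition ambiguity is ≲0.02 kcal/mol.

Known approximations in route-vs-oracle comparisons: the analytic bulk
reorientation assumes a rigid guest, while the toy guest's internal
fluctuations jitter the measured Euler angles by a few degrees —
comparable to the 2.4° restraint width — contributing on the order of
0.1 kcal/mol; angular window truncation adds a few hundredths.  The
observed agreement (~0.1 kcal/mol, versus the 0.3 kcal/mol acceptance
band) is consistent with these terms plus statistics.

## Conformer analysis

Frames of a (ϕ1, ϕ2) torsion series are assigned to a conformer when both
periodic coordinate distances to a centre are within the threshold
(default 45°; an axis-aligned box on the torus, with a Euclidean-ball
option).  The ± sign symmetry applies to each torsion independently — a
centre written ϕ ∼ ±90° matches either sign in that coordinate — because
the flat and perpendicular scaffold geometries are the same conformer
regardless of the individual torsion signs.  Among multiple qualifying modes the nearest by
max-coordinate distance wins, ties by declaration order.  Mode detection
finds periodic local maxima of the 2-D histogram above a prominence and
merges peaks within a minimum separation.

The synthetic generator draws mode frames from wrapped Gaussians and
"transition" frames uniformly over the torus *excluding* every conformer
acceptance box: transition frames are, by definition, non-conformer
geometries.  Without the exclusion, uniform frames would land inside the
boxes ~31% of the time and bias recovered mode populations by ~1–2
percentage points — far beyond binomial error at n = 5000 — making exact
round-trip recovery impossible.  The generator therefore takes the
classification threshold as a parameter (default 45°).

What the toy validations show: that the cycle algebra, the estimators and
the classification logic are correct against independent ground truth.
What they do not show: force-field accuracy, solvent effects, sampling
adequacy for real flexible hosts (where the conformational legs dominate
the error budget), or the behaviour of multi-dimensional reaction
coordinates.

## Degenerate inputs and failure modes

Non-finite coordinates, mismatched shapes and unobservable CVs fail fast
with configuration errors before any dynamics.  NaN propagation during
dynamics raises with the step index.  Restraint quadrature refuses
profiles whose restrained integrand has >1e-6 of its mass in a
non-physical edge bin (insufficient tail coverage), profiles with interior
gaps, and temperature mismatches.  The separation term requires the
profile to reach r* and a unique basin; profiles with several deep minima
(e.g. a non-native secondary well along the pull path) require an
explicit basin interval.  Time-step-too-large detection is not attempted.
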