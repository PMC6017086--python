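"""Numba-compiled numerical core.

Everything in this module works in internal units: Å, ps, amu, kcal/mol and
*radians*.  Public modules convert to degrees at the interface.  The kernels
are deliberately free of Python objects: a "model" is a flat tuple of arrays
(see :func:`geombind.toy_systems.ToySystem.pack`).

Collective-variable codes
-------------------------
0 separation_r   COM distance from the host origin
1 theta          polar angle of the COM in the host frame
2 phi            azimuth of the COM in the host frame
3 Theta          ZYZ Euler angle of the best-fit rotation (reference→moving)
4 Phi            ZYZ Euler angle
5 Psi            ZYZ Euler angle
6 rmsd_fit       RMSD after optimal superposition (uniform weights)
7 rmsd_dm        root-mean-square deviation of intramolecular pair distances
8 dihedral       signed torsion of four beads

Host-potential codes
--------------------
0 none, 1 harmonic, 2 gaussian_well, 3 double_well (x axis, transverse
harmonic), 4 angular_pocket, 5 square_well (quadrature only; zero force).
"""

import numpy as np
from numba import njit

KB = 0.0019872041
ACC = 418.4  # kcal/mol -> amu Å²/ps²

TWO_PI = 2.0 * np.pi


# ----------------------------------------------------------------------
# small utilities
# ----------------------------------------------------------------------
@njit(cache=True, inline="always")
def wrap_pi(x):
    """Wrap an angle into (-pi, pi]."""
    y = (x + np.pi) % TWO_PI
    if y <= 0.0:
        y += TWO_PI
    return y - np.pi


@njit(cache=True)
def com_of(pos, masses):
    M = 0.0
    c = np.zeros(3)
    for i in range(pos.shape[0]):
        M += masses[i]
        for a in range(3):
            c[a] += masses[i] * pos[i, a]
    return c / M, M


# ----------------------------------------------------------------------
# host potentials (energy returned; force accumulated into f)
# ----------------------------------------------------------------------
@njit(cache=True)
def host_energy_force(kinds, pars, ws, pos, f):
    """Sum of analytic host fields; kinds (np,), pars (np, 12), ws (np, n)."""
    u = 0.0
    for p in range(kinds.shape[0]):
        u += _one_host_energy_force(kinds[p], pars[p], ws[p], pos, f)
    return u


@njit(cache=True)
def _one_host_energy_force(kind, par, w, pos, f):
    u = 0.0
    n = pos.shape[0]
    if kind == 0:
        return 0.0
    for i in range(n):
        wi = w[i]
        if wi == 0.0:
            continue
        if kind == 1:  # harmonic: ½ k |r-c|²
            k = par[0]
            dx = pos[i, 0] - par[1]
            dy = pos[i, 1] - par[2]
            dz = pos[i, 2] - par[3]
            u += wi * 0.5 * k * (dx * dx + dy * dy + dz * dz)
            f[i, 0] -= wi * k * dx
            f[i, 1] -= wi * k * dy
            f[i, 2] -= wi * k * dz
        elif kind == 2:  # gaussian well: -eps exp(-|r-c|²/2σ²)
            eps, sig = par[0], par[1]
            dx = pos[i, 0] - par[2]
            dy = pos[i, 1] - par[3]
            dz = pos[i, 2] - par[4]
            r2 = dx * dx + dy * dy + dz * dz
            e = -eps * np.exp(-r2 / (2.0 * sig * sig))
            u += wi * e
            g = -e / (sig * sig)  # dU/dr = g * r_vec
            f[i, 0] -= wi * g * dx
            f[i, 1] -= wi * g * dy
            f[i, 2] -= wi * g * dz
        elif kind == 3:  # double well along x + transverse harmonic
            h, x0, kt = par[0], par[1], par[2]
            dx = pos[i, 0] - par[3]
            dy = pos[i, 1] - par[4]
            dz = pos[i, 2] - par[5]
            s = (dx * dx - x0 * x0) / (x0 * x0)
            u += wi * (h * s * s + 0.5 * kt * (dy * dy + dz * dz))
            f[i, 0] -= wi * h * 4.0 * s * dx / (x0 * x0)
            f[i, 1] -= wi * kt * dy
            f[i, 2] -= wi * kt * dz
        elif kind == 4:  # angular pocket: radial gaussian shell × cap
            eps, r0, sr, p = par[0], par[1], par[2], par[3]
            ax, ay, az = par[4], par[5], par[6]
            dx = pos[i, 0] - par[7]
            dy = pos[i, 1] - par[8]
            dz = pos[i, 2] - par[9]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-10:
                continue
            cg = (dx * ax + dy * ay + dz * az) / r
            cap = ((1.0 + cg) * 0.5) ** p
            dr = r - r0
            rad = np.exp(-dr * dr / (2.0 * sr * sr))
            u += wi * (-eps * rad * cap)
            # dU/dr (radial) and dU/dcg (angular)
            dU_dr = -eps * cap * rad * (-dr / (sr * sr))
            dU_dc = -eps * rad * p * ((1.0 + cg) * 0.5) ** (p - 1.0) * 0.5
            # dcg/dx = (a - cg*rhat)/r
            for a in range(3):
                rb = (dx, dy, dz)[a] / r
                av = (ax, ay, az)[a]
                grad = dU_dr * rb + dU_dc * (av - cg * rb) / r
                f[i, a] -= wi * grad
        elif kind == 5:  # square well: quadrature only, zero force
            eps, rw = par[0], par[1]
            dx = pos[i, 0] - par[2]
            dy = pos[i, 1] - par[3]
            dz = pos[i, 2] - par[4]
            if dx * dx + dy * dy + dz * dz < rw * rw:
                u += wi * (-eps)
    return u


@njit(cache=True)
def bonded_energy_force(bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par, pos, f):
    u = 0.0
    # harmonic bonds ½k(r-r0)²
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        k, r0 = bond_par[b, 0], bond_par[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        u += 0.5 * k * dr * dr
        if r > 1e-12:
            g = k * dr / r
            f[i, 0] -= g * dx
            f[i, 1] -= g * dy
            f[i, 2] -= g * dz
            f[j, 0] += g * dx
            f[j, 1] += g * dy
            f[j, 2] += g * dz
    # harmonic angles ½k(a-a0)²
    for b in range(ang_idx.shape[0]):
        i, j, k3 = ang_idx[b, 0], ang_idx[b, 1], ang_idx[b, 2]
        ka, a0 = ang_par[b, 0], ang_par[b, 1]
        v1 = pos[i] - pos[j]
        v2 = pos[k3] - pos[j]
        n1 = np.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
        n2 = np.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
        ct = (v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]) / (n1 * n2)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        th = np.arccos(ct)
        st = np.sqrt(max(1.0 - ct * ct, 1e-16))
        u += 0.5 * ka * (th - a0) ** 2
        dU = ka * (th - a0)
        for a in range(3):
            dth_di = (ct * v1[a] / n1 - v2[a] / n2) / (n1 * st)
            dth_dk = (ct * v2[a] / n2 - v1[a] / n1) / (n2 * st)
            f[i, a] -= dU * dth_di
            f[k3, a] -= dU * dth_dk
            f[j, a] += dU * (dth_di + dth_dk)
    # cosine dihedrals k(1+cos(n φ - δ))
    for b in range(dih_idx.shape[0]):
        kd, mult, delta = dih_par[b, 0], dih_par[b, 1], dih_par[b, 2]
        phi, g1, g2, g3, g4 = dihedral_val_grad(
            pos[dih_idx[b, 0]], pos[dih_idx[b, 1]], pos[dih_idx[b, 2]], pos[dih_idx[b, 3]]
        )
        u += kd * (1.0 + np.cos(mult * phi - delta))
        dU = -kd * mult * np.sin(mult * phi - delta)
        for a in range(3):
            f[dih_idx[b, 0], a] -= dU * g1[a]
            f[dih_idx[b, 1], a] -= dU * g2[a]
            f[dih_idx[b, 2], a] -= dU * g3[a]
            f[dih_idx[b, 3], a] -= dU * g4[a]
    return u


@njit(cache=True)
def dihedral_val_grad(p1, p2, p3, p4):
    """Signed torsion in (-pi, pi] and its four position gradients."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.array(
        [b1[1] * b2[2] - b1[2] * b2[1], b1[2] * b2[0] - b1[0] * b2[2], b1[0] * b2[1] - b1[1] * b2[0]]
    )
    n2 = np.array(
        [b2[1] * b3[2] - b2[2] * b3[1], b2[2] * b3[0] - b2[0] * b3[2], b2[0] * b3[1] - b2[1] * b3[0]]
    )
    nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    m1 = np.array(
        [n1[1] * b2[2] - n1[2] * b2[1], n1[2] * b2[0] - n1[0] * b2[2], n1[0] * b2[1] - n1[1] * b2[0]]
    )
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = (m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]) / max(nb2, 1e-12)
    phi = np.arctan2(y, x)
    nn1 = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
    nn2 = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
    g1 = (nb2 / max(nn1, 1e-14)) * n1
    g4 = -(nb2 / max(nn2, 1e-14)) * n2
    s1 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / max(nb2 * nb2, 1e-14)
    s2 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / max(nb2 * nb2, 1e-14)
    g2 = -(1.0 + s1) * g1 + s2 * g4
    g3 = s1 * g1 - (1.0 + s2) * g4
    return phi, g1, g2, g3, g4


# ----------------------------------------------------------------------
# best-fit rotation (quaternion / Horn) and its analytic gradient
# ----------------------------------------------------------------------
@njit(cache=True)
def _kmat(M):
    K = np.empty((4, 4))
    K[0, 0] = M[0, 0] + M[1, 1] + M[2, 2]
    K[0, 1] = M[1, 2] - M[2, 1]
    K[0, 2] = M[2, 0] - M[0, 2]
    K[0, 3] = M[0, 1] - M[1, 0]
    K[1, 1] = M[0, 0] - M[1, 1] - M[2, 2]
    K[1, 2] = M[0, 1] + M[1, 0]
    K[1, 3] = M[0, 2] + M[2, 0]
    K[2, 2] = -M[0, 0] + M[1, 1] - M[2, 2]
    K[2, 3] = M[1, 2] + M[2, 1]
    K[3, 3] = -M[0, 0] - M[1, 1] + M[2, 2]
    for a in range(4):
        for b in range(a):
            K[a, b] = K[b, a]
    return K


@njit(cache=True)
def rot_from_q(q):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R = np.empty((3, 3))
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return R


@njit(cache=True)
def best_fit(pos, masses, ref_c, sel):
    """Optimal rotation mapping the centered reference onto the centered
    moving selection, with the quaternion derivative machinery.

    Returns (q, R, xbar, xt, dqdx, ok) where xt is the centered moving set
    and dqdx[i, c, :] = ∂q/∂pos[sel[i], c].
    """
    ns = sel.shape[0]
    xbar = np.zeros(3)
    for i in range(ns):
        xbar += pos[sel[i]]
    xbar /= ns
    xt = np.empty((ns, 3))
    for i in range(ns):
        xt[i] = pos[sel[i]] - xbar
    # correlation M[a, b] = sum_i ref[i, a] * xt[i, b]
    M = np.zeros((3, 3))
    for i in range(ns):
        for a in range(3):
            for b in range(3):
                M[a, b] += ref_c[i, a] * xt[i, b]
    K = _kmat(M)
    w, V = np.linalg.eigh(K)
    q = V[:, 3].copy()
    ok = (w[3] - w[2]) > 1e-9
    # pseudo-inverse projector P = sum_{m<3} v_m v_m^T / (λ0 - λ_m)
    P = np.zeros((4, 4))
    for m in range(3):
        inv = 1.0 / (w[3] - w[m])
        for a in range(4):
            for b in range(4):
                P[a, b] += V[a, m] * V[b, m] * inv
    # dq/dx: K is linear in xt; dM/dxt[i, c] has row a = ref[i, a] at col c
    dqdx = np.zeros((ns, 3, 4))
    for i in range(ns):
        for c in range(3):
            dM = np.zeros((3, 3))
            for a in range(3):
                dM[a, c] = ref_c[i, a]
            dK = _kmat(dM)
            tmp = dK @ q
            dqdx[i, c, :] = P @ tmp
    return q, rot_from_q(q), xbar, xt, dqdx, ok


@njit(cache=True)
def euler_zyz(R):
    """ZYZ Euler angles (Theta, Phi, Psi) of R = Rz(Phi) Ry(Theta) Rz(Psi)."""
    c = R[2, 2]
    if c > 1.0:
        c = 1.0
    if c < -1.0:
        c = -1.0
    Th = np.arccos(c)
    st = np.sin(Th)
    if st < 1e-7:
        # gimbal lock: only Phi+Psi (Th=0) or Phi-Psi (Th=pi) defined
        if c > 0.0:
            return Th, 0.0, np.arctan2(R[1, 0], R[0, 0]), 1
        return Th, 0.0, -np.arctan2(R[1, 0], R[0, 0]), 1
    Ph = np.arctan2(R[1, 2], R[0, 2])
    Ps = np.arctan2(R[2, 1], -R[2, 0])
    return Th, Ph, Ps, 0


@njit(cache=True)
def _euler_dq(q, which):
    """d(angle)/dq for the ZYZ angles of R(q). which: 0=Theta, 1=Phi, 2=Psi."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    out = np.zeros(4)
    if which == 0:
        r33 = 1.0 - 2.0 * (x * x + y * y)
        c = min(max(r33, -1.0), 1.0)
        st = np.sqrt(max(1.0 - c * c, 1e-14))
        # dTheta/dq = -(dR33/dq)/sin(Theta)
        out[1] = 4.0 * x / st
        out[2] = 4.0 * y / st
    elif which == 1:
        a = 2.0 * (x * z + w * y)   # R13
        b = 2.0 * (y * z - w * x)   # R23
        da = np.array([2.0 * y, 2.0 * z, 2.0 * w, 2.0 * x])
        db = np.array([-2.0 * x, -2.0 * w, 2.0 * z, 2.0 * y])
        den = max(a * a + b * b, 1e-14)
        for m in range(4):
            out[m] = (a * db[m] - b * da[m]) / den
    else:
        a = -2.0 * (x * z - w * y)  # -R31
        b = 2.0 * (y * z + w * x)   # R32
        da = np.array([2.0 * y, -2.0 * z, 2.0 * w, -2.0 * x])
        db = np.array([2.0 * x, 2.0 * w, 2.0 * z, 2.0 * y])
        den = max(a * a + b * b, 1e-14)
        for m in range(4):
            out[m] = (a * db[m] - b * da[m]) / den
    return out


# ----------------------------------------------------------------------
# grouped CV evaluation
# ----------------------------------------------------------------------
@njit(cache=True)
def eval_cvs(codes, atoms, pos, masses, origin, axes, ref_c, ref_dm, sel, values, grads):
    """Evaluate all requested CVs; Kabsch machinery is shared.

    values[j] and grads[j] (n, 3 arrays) are filled in place.  Returns a
    bitmask of degeneracy flags (bit j set when CV j hit a singular
    configuration).
    """
    n = pos.shape[0]
    ncv = codes.shape[0]
    flags = 0
    need_fit = False
    for j in range(ncv):
        if 3 <= codes[j] <= 6:
            need_fit = True
    have_fit = False
    q = np.zeros(4)
    R = np.eye(3)
    xt = np.zeros((sel.shape[0], 3))
    dqdx = np.zeros((sel.shape[0], 3, 4))
    if need_fit:
        q, R, _xb, xt, dqdx, ok = best_fit(pos, masses, ref_c, sel)
        have_fit = True
        if not ok:
            flags |= 1 << 30
    com, M = com_of(pos, masses)
    for j in range(ncv):
        c = codes[j]
        grads[j][:, :] = 0.0
        if c == 0:  # separation
            v = com - origin
            r = np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            values[j] = r
            if r < 1e-10:
                flags |= 1 << j
            else:
                for i in range(n):
                    fac = masses[i] / (M * r)
                    for a in range(3):
                        grads[j][i, a] = fac * v[a]
        elif c == 1 or c == 2:  # polar angles in the host frame
            v = com - origin
            u = axes.T @ v
            rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
            rxy2 = u[0] ** 2 + u[1] ** 2
            if rho < 1e-10:
                values[j] = 0.0
                flags |= 1 << j
                continue
            if c == 1:
                ct = min(max(u[2] / rho, -1.0), 1.0)
                th = np.arccos(ct)
                values[j] = th
                st = np.sqrt(max(1.0 - ct * ct, 0.0))
                if st < 1e-8:
                    flags |= 1 << j
                    continue
                du = np.empty(3)
                for a in range(3):
                    ez = 1.0 if a == 2 else 0.0
                    du[a] = -(ez / rho - u[2] * u[a] / rho ** 3) / st
                g = axes @ du
                for i in range(n):
                    fac = masses[i] / M
                    for a in range(3):
                        grads[j][i, a] = fac * g[a]
            else:
                if rxy2 < 1e-16:
                    values[j] = 0.0
                    flags |= 1 << j
                    continue
                values[j] = np.arctan2(u[1], u[0])
                du = np.array([-u[1] / rxy2, u[0] / rxy2, 0.0])
                g = axes @ du
                for i in range(n):
                    fac = masses[i] / M
                    for a in range(3):
                        grads[j][i, a] = fac * g[a]
        elif 3 <= c <= 5:  # Euler angles
            Th, Ph, Ps, lock = euler_zyz(R)
            if lock == 1:
                flags |= 1 << j
            if c == 3:
                values[j] = Th
            elif c == 4:
                values[j] = Ph
            else:
                values[j] = Ps
            dAdq = _euler_dq(q, c - 3)
            for i in range(sel.shape[0]):
                for a in range(3):
                    s = 0.0
                    for m in range(4):
                        s += dAdq[m] * dqdx[i, a, m]
                    grads[j][sel[i], a] = s
        elif c == 6:  # fitted RMSD
            ns = sel.shape[0]
            s2 = 0.0
            dev = np.empty((ns, 3))
            for i in range(ns):
                ry = R @ ref_c[i]
                for a in range(3):
                    dev[i, a] = xt[i, a] - ry[a]
                    s2 += dev[i, a] ** 2
            val = np.sqrt(s2 / ns)
            values[j] = val
            if val < 1e-10:
                flags |= 1 << j
            else:
                for i in range(ns):
                    for a in range(3):
                        grads[j][sel[i], a] = dev[i, a] / (ns * val)
        elif c == 7:  # distance-matrix RMSD
            ns = sel.shape[0]
            npair = ns * (ns - 1) // 2
            s2 = 0.0
            p = 0
            for i in range(ns):
                for k in range(i + 1, ns):
                    d = pos[sel[i]] - pos[sel[k]]
                    dij = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
                    s2 += (dij - ref_dm[p]) ** 2
                    p += 1
            val = np.sqrt(s2 / npair)
            values[j] = val
            if val < 1e-10:
                flags |= 1 << j
            else:
                p = 0
                for i in range(ns):
                    for k in range(i + 1, ns):
                        d = pos[sel[i]] - pos[sel[k]]
                        dij = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
                        fac = (dij - ref_dm[p]) / (npair * val * max(dij, 1e-12))
                        for a in range(3):
                            grads[j][sel[i], a] += fac * d[a]
                            grads[j][sel[k], a] -= fac * d[a]
                        p += 1
        elif c == 8:  # dihedral
            phi, g1, g2, g3, g4 = dihedral_val_grad(
                pos[atoms[j, 0]], pos[atoms[j, 1]], pos[atoms[j, 2]], pos[atoms[j, 3]]
            )
            values[j] = phi
            for a in range(3):
                grads[j][atoms[j, 0], a] = g1[a]
                grads[j][atoms[j, 1], a] = g2[a]
                grads[j][atoms[j, 2], a] = g3[a]
                grads[j][atoms[j, 3], a] = g4[a]
    return flags


@njit(cache=True, inline="always")
def _cv_periodic(code):
    """Angles with a branch cut: azimuth, Euler Phi/Psi, dihedral."""
    return code == 2 or code == 4 or code == 5 or code == 8


@njit(cache=True)
def batch_restraint_energy(
    codes, atoms, centers, ks, pos_batch, masses, origin, axes, ref_c, ref_dm, sel
):
    """Total harmonic restraint energy for each configuration of a batch;
    centers and ks are in internal units (radians for angles)."""
    nconf = pos_batch.shape[0]
    ncv = codes.shape[0]
    n = pos_batch.shape[1]
    out = np.zeros(nconf)
    vals = np.zeros(ncv)
    grads = np.zeros((ncv, n, 3))
    for i in range(nconf):
        eval_cvs(
            codes, atoms, pos_batch[i], masses, origin, axes, ref_c, ref_dm, sel,
            vals, grads,
        )
        e = 0.0
        for j in range(ncv):
            dv = vals[j] - centers[j]
            if _cv_periodic(codes[j]):
                dv = wrap_pi(dv)
            e += 0.5 * ks[j] * dv * dv
        out[i] = e
    return out


# ----------------------------------------------------------------------
# total force: potential + restraints (+ optional eABF coupling)
# ----------------------------------------------------------------------
@njit(cache=True)
def compute_forces(
    pos,
    masses,
    bond_idx,
    bond_par,
    ang_idx,
    ang_par,
    dih_idx,
    dih_par,
    host_kind,
    host_par,
    host_w,
    origin,
    axes,
    ref_c,
    ref_dm,
    sel,
    r_codes,
    r_atoms,
    r_centers,
    r_ks,
    b_code,
    b_atoms,
    k_couple,
    lam,
    f,
    cvbuf_v,
    cvbuf_g,
):
    """Fill f with forces; return (U_total, xi).

    The last entry of cvbuf corresponds to the biased CV when b_code >= 0.
    Restraint energies are included in U_total; the coupling energy is not.
    """
    f[:, :] = 0.0
    u = host_energy_force(host_kind, host_par, host_w, pos, f)
    u += bonded_energy_force(bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par, pos, f)
    nr = r_codes.shape[0]
    ncv = cvbuf_v.shape[0]
    codes = np.empty(ncv, dtype=np.int64)
    atoms = np.empty((ncv, 4), dtype=np.int64)
    for j in range(nr):
        codes[j] = r_codes[j]
        atoms[j] = r_atoms[j]
    if b_code >= 0:
        codes[ncv - 1] = b_code
        atoms[ncv - 1] = b_atoms
    eval_cvs(codes, atoms, pos, masses, origin, axes, ref_c, ref_dm, sel, cvbuf_v, cvbuf_g)
    n = pos.shape[0]
    for j in range(nr):
        dv = cvbuf_v[j] - r_centers[j]
        if _cv_periodic(r_codes[j]):
            dv = wrap_pi(dv)
        if r_codes[j] == 6 or r_codes[j] == 7:
            # stable product form: k (v - c) * dev/(ns v) stays finite at v→0
            v = max(cvbuf_v[j], 1e-12)
            scale = r_ks[j] * (1.0 - r_centers[j] / v)
            u += 0.5 * r_ks[j] * dv * dv
            for i in range(n):
                for a in range(3):
                    f[i, a] -= scale * v * cvbuf_g[j][i, a]
        else:
            u += 0.5 * r_ks[j] * dv * dv
            g = r_ks[j] * dv
            for i in range(n):
                for a in range(3):
                    f[i, a] -= g * cvbuf_g[j][i, a]
    xi = 0.0
    if b_code >= 0:
        xi = cvbuf_v[ncv - 1]
        dv = xi - lam
        if _cv_periodic(b_code):
            dv = wrap_pi(dv)
        g = k_couple * dv
        for i in range(n):
            for a in range(3):
                f[i, a] -= g * cvbuf_g[ncv - 1][i, a]
    return u, xi


# ----------------------------------------------------------------------
# BAOAB Langevin dynamics
# ----------------------------------------------------------------------
@njit(cache=True)
def run_md(
    pos,
    vel,
    masses,
    bond_idx,
    bond_par,
    ang_idx,
    ang_par,
    dih_idx,
    dih_par,
    host_kind,
    host_par,
    host_w,
    origin,
    axes,
    ref_c,
    ref_dm,
    sel,
    r_codes,
    r_atoms,
    r_centers,
    r_ks,
    obs_codes,
    obs_atoms,
    dt,
    friction,
    temperature,
    n_steps,
    stride,
    seed,
):
    """BAOAB Langevin trajectory with harmonic restraints.

    Returns (cv_rec, pot_rec, kin_rec, status, bad_step).  status 0 = ok,
    1 = non-finite coordinates encountered at step bad_step.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nr = r_codes.shape[0]
    nobs = obs_codes.shape[0]
    kT = KB * temperature
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sig = np.empty(n)
    for i in range(n):
        sig[i] = np.sqrt(kT * ACC / masses[i])
    nrec = n_steps // stride + 1
    cv_rec = np.zeros((nrec, nobs))
    pot_rec = np.zeros(nrec)
    kin_rec = np.zeros(nrec)
    f = np.zeros((n, 3))
    ncv = nr + 1
    cvv = np.zeros(ncv)
    cvg = np.zeros((ncv, n, 3))
    dummy_atoms = np.full(4, -1, dtype=np.int64)
    u, _ = compute_forces(
        pos, masses, bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par,
        host_kind, host_par, host_w, origin, axes, ref_c, ref_dm, sel,
        r_codes, r_atoms, r_centers, r_ks, -1, dummy_atoms, 0.0, 0.0, f, cvv, cvg,
    )
    obs_v = np.zeros(max(nobs, 1))
    obs_g = np.zeros((max(nobs, 1), n, 3))
    rec = 0
    if nobs > 0:
        eval_cvs(obs_codes, obs_atoms, pos, masses, origin, axes, ref_c, ref_dm, sel, obs_v, obs_g)
        for j in range(nobs):
            cv_rec[rec, j] = obs_v[j]
    pot_rec[rec] = u
    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2) / ACC
    kin_rec[rec] = ke
    rec += 1
    half = 0.5 * dt
    for step in range(n_steps):
        # B
        for i in range(n):
            fac = half * ACC / masses[i]
            for a in range(3):
                vel[i, a] += fac * f[i, a]
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += half * vel[i, a]
        # O
        for i in range(n):
            for a in range(3):
                vel[i, a] = c1 * vel[i, a] + c2 * sig[i] * np.random.normal()
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += half * vel[i, a]
        # B
        u, _ = compute_forces(
            pos, masses, bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par,
            host_kind, host_par, host_w, origin, axes, ref_c, ref_dm, sel,
            r_codes, r_atoms, r_centers, r_ks, -1, dummy_atoms, 0.0, 0.0, f, cvv, cvg,
        )
        for i in range(n):
            fac = half * ACC / masses[i]
            for a in range(3):
                vel[i, a] += fac * f[i, a]
        if not np.isfinite(u):
            return cv_rec, pot_rec, kin_rec, 1, step
        if (step + 1) % stride == 0:
            if nobs > 0:
                eval_cvs(
                    obs_codes, obs_atoms, pos, masses, origin, axes, ref_c, ref_dm, sel, obs_v, obs_g
                )
                for j in range(nobs):
                    cv_rec[rec, j] = obs_v[j]
            pot_rec[rec] = u
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2) / ACC
            kin_rec[rec] = ke
            rec += 1
    return cv_rec, pot_rec, kin_rec, 0, -1


# ----------------------------------------------------------------------
# eABF driver
# ----------------------------------------------------------------------
@njit(cache=True)
def run_eabf(
    pos,
    vel,
    masses,
    bond_idx,
    bond_par,
    ang_idx,
    ang_par,
    dih_idx,
    dih_par,
    host_kind,
    host_par,
    host_w,
    origin,
    axes,
    ref_c,
    ref_dm,
    sel,
    r_codes,
    r_atoms,
    r_centers,
    r_ks,
    b_code,
    b_atoms,
    lo,
    hi,
    nbins,
    k_couple,
    m_lambda,
    friction_lambda,
    n_full,
    lam,
    lamv,
    dt,
    friction,
    temperature,
    n_steps,
    seed,
    sample_stride,
    force_sum,
    count,
    xi_count,
    lam_sum,
    reseed,
):
    """Extended-system ABF along one CV with reflecting λ walls.

    Accumulators (shape (2, nbins); axis 0 = halves of the run for two-block
    error estimation) are updated in place so the driver can be called
    repeatedly to continue a window.  Returns (samples, lam, lamv, status,
    bad_step) where samples[s] = (ξ, λ) at the sampling stride.
    """
    if reseed != 0:
        np.random.seed(seed)
    n = pos.shape[0]
    nr = r_codes.shape[0]
    kT = KB * temperature
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    c1l = np.exp(-friction_lambda * dt)
    c2l = np.sqrt(max(1.0 - c1l * c1l, 0.0))
    sig = np.empty(n)
    for i in range(n):
        sig[i] = np.sqrt(kT * ACC / masses[i])
    sigl = np.sqrt(kT * ACC / m_lambda)
    dx = (hi - lo) / nbins
    f = np.zeros((n, 3))
    ncv = nr + 1
    cvv = np.zeros(ncv)
    cvg = np.zeros((ncv, n, 3))
    u, xi = compute_forces(
        pos, masses, bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par,
        host_kind, host_par, host_w, origin, axes, ref_c, ref_dm, sel,
        r_codes, r_atoms, r_centers, r_ks, b_code, b_atoms, k_couple, lam, f, cvv, cvg,
    )
    nsamp = n_steps // sample_stride
    samples = np.zeros((nsamp, 2))
    srec = 0
    half = 0.5 * dt

    # full force on lambda (coupling + adaptive bias) at the current state;
    # cached so both BAOAB half-kicks use the same force field
    dvl = xi - lam
    if _cv_periodic(b_code):
        dvl = wrap_pi(dvl)
    flam = k_couple * dvl
    ib = int((lam - lo) / dx)
    ib = min(max(ib, 0), nbins - 1)
    ctot = count[0, ib] + count[1, ib]
    if ctot > 0:
        ramp = min(1.0, ctot / n_full)
        flam -= ramp * (force_sum[0, ib] + force_sum[1, ib]) / ctot

    for step in range(n_steps):
        block = 0 if step < n_steps // 2 else 1
        # B
        for i in range(n):
            fac = half * ACC / masses[i]
            for a in range(3):
                vel[i, a] += fac * f[i, a]
        lamv += half * ACC / m_lambda * flam
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += half * vel[i, a]
        lam += half * lamv
        # O
        for i in range(n):
            for a in range(3):
                vel[i, a] = c1 * vel[i, a] + c2 * sig[i] * np.random.normal()
        lamv = c1l * lamv + c2l * sigl * np.random.normal()
        # A
        for i in range(n):
            for a in range(3):
                pos[i, a] += half * vel[i, a]
        lam += half * lamv
        # reflecting walls for lambda
        if lam < lo:
            lam = 2.0 * lo - lam
            lamv = -lamv
        elif lam > hi:
            lam = 2.0 * hi - lam
            lamv = -lamv
        # fresh forces at the new state
        u, xi = compute_forces(
            pos, masses, bond_idx, bond_par, ang_idx, ang_par, dih_idx, dih_par,
            host_kind, host_par, host_w, origin, axes, ref_c, ref_dm, sel,
            r_codes, r_atoms, r_centers, r_ks, b_code, b_atoms, k_couple, lam, f, cvv, cvg,
        )
        if not np.isfinite(u) or not np.isfinite(lam):
            return samples, lam, lamv, 1, step
        dvl = xi - lam
        if _cv_periodic(b_code):
            dvl = wrap_pi(dvl)
        ib = int((lam - lo) / dx)
        ib = min(max(ib, 0), nbins - 1)
        # accrue the instantaneous system force on lambda in lambda's bin
        force_sum[block, ib] += k_couple * dvl
        count[block, ib] += 1.0
        # CZAR accumulators on the physical CV: displacement of lambda from
        # the xi-bin center (wrapped), for k (<lambda>_xi - xi_center)
        ixi = int((xi - lo) / dx)
        if 0 <= ixi < nbins:
            xi_count[block, ixi] += 1.0
            xic = lo + (ixi + 0.5) * dx
            lam_sum[block, ixi] += -dvl + (xi - xic)
        # updated lambda force for B2 (and B1 of the next step)
        flam = k_couple * dvl
        ctot = count[0, ib] + count[1, ib]
        if ctot > 0:
            ramp = min(1.0, ctot / n_full)
            flam -= ramp * (force_sum[0, ib] + force_sum[1, ib]) / ctot
        # B
        for i in range(n):
            fac = half * ACC / masses[i]
            for a in range(3):
                vel[i, a] += fac * f[i, a]
        lamv += half * ACC / m_lambda * flam
        if (step + 1) % sample_stride == 0 and srec < nsamp:
            samples[srec, 0] = xi
            samples[srec, 1] = lam
            srec += 1
    return samples, lam, lamv, 0, -1
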