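"""Numba force/energy kernels for the patchy-particle simulator.

Everything here works in reduced units: sigma = 1 (centre-centre contact
distance), k_BT = 1, mass = 1.  The lateral box (x, y) is periodic, z is
bounded below by a WCA wall at z = 0 and open above.

Pair energy between particles i and j at centre distance r:

    U_ij = U_wca(r; eps_core) + f_i f_j U_lj(r; eps_patch)
           + U_lj(r / body_sigma; eps_body)

with U_lj(r; eps) = 4 eps [r^-2n - r^-n] (n = 24), truncated and shifted at
r_cut, the WCA core cut at 2^{1/n}, and f_i = g(theta_i) the alignment of
particle i's best patch with the centre line:
g(theta) = exp(-theta^2 / 2 delta^2) * w(theta), where w is a C^1
cosine-squared switch that is 1 below 2 delta and exactly 0 above 3 delta,
so misalignments of >= 3 delta feel no patch attraction at all.  At the
default body_sigma = 0.5 (the sphere-radius length scale) the body term is
negligible at contact and non-patch contacts are purely repulsive.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _lj(r, eps, n, shift):
    x = r ** (-n)
    return 4.0 * eps * (x * x - x) - shift


@njit(cache=True, inline="always")
def _lj_dudr(r, eps, n):
    x = r ** (-n)
    return 4.0 * eps * (-2.0 * n * x * x + n * x) / r


@njit(cache=True, inline="always")
def _align(c, inv2d2, th1, th2):
    """g(theta), g'(theta)/sin(theta) for c = cos(theta).

    Returns (g, h) with h = g'(theta)/sin(theta); h stays finite at
    theta -> 0.  th1 = 2 delta, th2 = 3 delta bound the switching window.
    """
    if c >= 1.0:
        c = 1.0
    elif c <= -1.0:
        c = -1.0
    th = np.arccos(c)
    if th >= th2:
        return 0.0, 0.0
    ga = np.exp(-th * th * inv2d2)
    dga = -2.0 * th * inv2d2 * ga          # d/d theta
    if th > th1:
        u = 0.5 * np.pi * (th - th1) / (th2 - th1)
        w = np.cos(u) ** 2
        dw = -np.pi / (th2 - th1) * np.cos(u) * np.sin(u)
        g = ga * w
        dg = dga * w + ga * dw
    else:
        g = ga
        dg = dga
    s = np.sin(th)
    if s < 1e-8:
        h = -2.0 * inv2d2 * g              # limit of dg/sin at theta->0
    else:
        h = dg / s
    return g, h


@njit(cache=True)
def _quat_to_mat(q, out):
    w, x, y, z = q[0], q[1], q[2], q[3]
    out[0, 0] = 1 - 2 * (y * y + z * z)
    out[0, 1] = 2 * (x * y - w * z)
    out[0, 2] = 2 * (x * z + w * y)
    out[1, 0] = 2 * (x * y + w * z)
    out[1, 1] = 1 - 2 * (x * x + z * z)
    out[1, 2] = 2 * (y * z - w * x)
    out[2, 0] = 2 * (x * z - w * y)
    out[2, 1] = 2 * (y * z + w * x)
    out[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True)
def rotate_patches(quat, patch_body, out):
    """Rotate the body-frame patch axes into the lab frame for all particles."""
    n = quat.shape[0]
    npatch = patch_body.shape[0]
    mat = np.empty((3, 3))
    for i in range(n):
        _quat_to_mat(quat[i], mat)
        for k in range(npatch):
            for a in range(3):
                out[i, k, a] = (mat[a, 0] * patch_body[k, 0]
                                + mat[a, 1] * patch_body[k, 1]
                                + mat[a, 2] * patch_body[k, 2])


@njit(cache=True)
def compute_forces(pos, patches, pairs, lx, ly,
                   eps_patch, eps_body, body_sigma, eps_core, n_exp, r_cut,
                   inv2d2, th1, th2,
                   gravity, eps_wall, n_wall, wall_sigma,
                   forces, torques):
    """Fill forces/torques; return total potential energy.

    Pair energy: WCA core (eps_core, contact length 1) + alignment-
    modulated patch LJ (eps_patch) + body-body LJ at its own length scale
    ``body_sigma`` (the sphere-radius default makes this negligible at
    contact; body_sigma = 1 recovers a composite attractive contact).
    ``patches`` is the (N, 4, 3) lab-frame patch-axis array; ``pairs`` the
    candidate pair list (may include pairs beyond r_cut, which are
    skipped).
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0 - gravity
        torques[i, 0] = 0.0
        torques[i, 1] = 0.0
        torques[i, 2] = 0.0
    bsn = body_sigma ** n_exp
    xb_cut = bsn * r_cut ** (-n_exp)
    shift_b = 4.0 * eps_body * (xb_cut * xb_cut - xb_cut)
    shift_p = 4.0 * eps_patch * (r_cut ** (-2.0 * n_exp) - r_cut ** (-n_exp))
    core_cut = 2.0 ** (1.0 / n_exp)
    cth2 = np.cos(min(th2, np.pi))
    energy = 0.0
    for i in range(n):
        energy += gravity * pos[i, 2]

    # bottom wall (WCA): acts on the gap z
    wall_cut = wall_sigma * 2.0 ** (1.0 / n_wall)
    for i in range(n):
        z = pos[i, 2]
        if z < wall_cut:
            x = (wall_sigma / z) ** n_wall
            energy += 4.0 * eps_wall * (x * x - x) + eps_wall
            forces[i, 2] += 4.0 * eps_wall * (2.0 * n_wall * x * x
                                              - n_wall * x) / z

    npairs = pairs.shape[0]
    for e in range(npairs):
        i = pairs[e, 0]
        j = pairs[e, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= lx * np.rint(dx / lx)
        dy -= ly * np.rint(dy / ly)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r_cut * r_cut:
            continue
        r = np.sqrt(r2)
        ux = dx / r
        uy = dy / r
        uz = dz / r

        # one pow per pair: x = r^-n serves core, body and patch terms
        x = r ** (-n_exp)
        x2 = x * x
        # body-body LJ at its own length scale (xb = (body_sigma/r)^n)
        xb = bsn * x
        ub = 4.0 * eps_body * (xb * xb - xb) - shift_b
        dub = 4.0 * eps_body * n_exp * (xb - 2.0 * xb * xb) / r
        # WCA repulsive core at the contact length
        if r < core_cut:
            ub += 4.0 * eps_core * (x2 - x) + eps_core
            dub += 4.0 * eps_core * n_exp * (x - 2.0 * x2) / r

        # best-aligned patch of i towards j, and of j towards i
        ci = -2.0
        ki = 0
        cj = -2.0
        kj = 0
        for k in range(4):
            c = patches[i, k, 0] * ux + patches[i, k, 1] * uy + patches[i, k, 2] * uz
            if c > ci:
                ci = c
                ki = k
            c = -(patches[j, k, 0] * ux + patches[j, k, 1] * uy + patches[j, k, 2] * uz)
            if c > cj:
                cj = c
                kj = k
        # either patch beyond the angular cutoff: no patch interaction at
        # all — skip the arccos/exp entirely
        if ci <= cth2 or cj <= cth2:
            gi = 0.0
            hi = 0.0
            gj = 0.0
            hj = 0.0
        else:
            gi, hi = _align(ci, inv2d2, th1, th2)
            gj, hj = _align(cj, inv2d2, th1, th2)

        up = 4.0 * eps_patch * (x2 - x) - shift_p
        dup = 4.0 * eps_patch * n_exp * (x - 2.0 * x2) / r

        energy += ub + gi * gj * up

        # radial force
        frad = dub + gi * gj * dup
        fx = -frad * ux
        fy = -frad * uy
        fz = -frad * uz

        # angular contributions: dU/dc_i = up * gj * hi * (dtheta/dc = -1/sin)
        # combined: dU/d(p_i . u) along u direction via projector
        if gi > 0.0 and gj > 0.0:
            # a_i = dU/dc_i (c_i = p_i.u),  a_j = dU/dc_j (c_j = -p_j.u)
            a_i = up * gj * (-hi)
            a_j = up * gi * (-hj)
            pi0 = patches[i, ki, 0]
            pi1 = patches[i, ki, 1]
            pi2 = patches[i, ki, 2]
            pj0 = patches[j, kj, 0]
            pj1 = patches[j, kj, 1]
            pj2 = patches[j, kj, 2]
            # w = dU/du = a_i * p_i - a_j * p_j
            wx = a_i * pi0 - a_j * pj0
            wy = a_i * pi1 - a_j * pj1
            wz = a_i * pi2 - a_j * pj2
            # project out the radial component, divide by r
            wdotu = wx * ux + wy * uy + wz * uz
            tx = (wx - wdotu * ux) / r
            ty = (wy - wdotu * uy) / r
            tz = (wz - wdotu * uz) / r
            fx -= tx
            fy -= ty
            fz -= tz
            # torques: tau_i = a_i * (u x p_i); tau_j = a_j * ((-u) x p_j)
            torques[i, 0] += a_i * (uy * pi2 - uz * pi1)
            torques[i, 1] += a_i * (uz * pi0 - ux * pi2)
            torques[i, 2] += a_i * (ux * pi1 - uy * pi0)
            torques[j, 0] += a_j * (-(uy * pj2 - uz * pj1))
            torques[j, 1] += a_j * (-(uz * pj0 - ux * pj2))
            torques[j, 2] += a_j * (-(ux * pj1 - uy * pj0))

        forces[j, 0] += fx
        forces[j, 1] += fy
        forces[j, 2] += fz
        forces[i, 0] -= fx
        forces[i, 1] -= fy
        forces[i, 2] -= fz
    return energy


@njit(cache=True)
def build_cell_pairs(pos, lx, ly, cutoff, pairs):
    """Laterally periodic cell-list candidate pairs within cutoff.

    z is treated as open (no wrap).  Returns the number of pairs written
    into ``pairs``; -1 if the buffer is too small.
    """
    n = pos.shape[0]
    nx = max(int(lx / cutoff), 1)
    ny = max(int(ly / cutoff), 1)
    zmin = pos[0, 2]
    zmax = pos[0, 2]
    for i in range(n):
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        if pos[i, 2] > zmax:
            zmax = pos[i, 2]
    nz = max(int((zmax - zmin) / cutoff) + 1, 1)
    ncell = nx * ny * nz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] % lx) / lx * nx)
        cy = int((pos[i, 1] % ly) / ly * ny)
        cz = int((pos[i, 2] - zmin) / cutoff)
        if cx >= nx:
            cx = nx - 1
        if cy >= ny:
            cy = ny - 1
        if cz >= nz:
            cz = nz - 1
        c = (cz * ny + cy) * nx + cx
        cell[i] = c
        nxt[i] = head[c]
        head[c] = i
    cut2 = cutoff * cutoff
    cap = pairs.shape[0]
    m = 0
    small_lateral = nx < 3 or ny < 3
    for cz in range(nz):
        for cy in range(ny):
            for cx in range(nx):
                c = (cz * ny + cy) * nx + cx
                i = head[c]
                while i >= 0:
                    # same cell: j after i in the linked list
                    j = nxt[i]
                    while j >= 0:
                        m = _try_pair(pos, i, j, lx, ly, cut2, pairs, m, cap)
                        j = nxt[j]
                    # half stencil of neighbouring cells
                    for dz in range(-1, 2):
                        czn = cz + dz
                        if czn < 0 or czn >= nz:
                            continue
                        for dy in range(-1, 2):
                            for dx in range(-1, 2):
                                if dz < 0:
                                    continue
                                if dz == 0 and (dy < 0 or (dy == 0 and dx <= 0)):
                                    continue
                                cxn = cx + dx
                                cyn = cy + dy
                                if small_lateral:
                                    # tiny lateral boxes handled by the
                                    # caller via the k-d tree path
                                    pass
                                cxn = cxn % nx
                                cyn = cyn % ny
                                cn = (czn * ny + cyn) * nx + cxn
                                if cn == c:
                                    continue
                                j = head[cn]
                                while j >= 0:
                                    m = _try_pair(pos, i, j, lx, ly, cut2,
                                                  pairs, m, cap)
                                    j = nxt[j]
                    i = nxt[i]
    return m


@njit(cache=True, inline="always")
def _try_pair(pos, i, j, lx, ly, cut2, pairs, m, cap):
    dx = pos[j, 0] - pos[i, 0]
    dy = pos[j, 1] - pos[i, 1]
    dz = pos[j, 2] - pos[i, 2]
    dx -= lx * np.rint(dx / lx)
    dy -= ly * np.rint(dy / ly)
    if dx * dx + dy * dy + dz * dz < cut2:
        if m < cap:
            pairs[m, 0] = i
            pairs[m, 1] = j
        m += 1
    return m


@njit(cache=True)
def integrate_chunk(pos, quat, vel, angvel, patch_body, nsteps, dt,
                    c1, c2, c1r, c2r, noise_t, noise_r,
                    lx, ly, eps_patch, eps_body, body_sigma, eps_core,
                    n_exp, r_cut,
                    inv2d2, th1, th2, gravity, eps_wall, n_wall, wall_sigma,
                    skin, pairs_buf, patches, forces, torques,
                    mass, inertia):
    """One neighbour-list interval of BAOAB Langevin steps.

    The candidate pair list is built once at chunk start; ``skin`` must
    cover the per-chunk drift.  Returns (potential energy, pair count) at
    the final configuration; pair count -1 signals a pair-buffer overflow.
    """
    npairs = build_cell_pairs(pos, lx, ly, r_cut + skin, pairs_buf)
    if npairs > pairs_buf.shape[0]:
        return 0.0, -1
    pairs = pairs_buf[:npairs]
    n = pos.shape[0]
    rotate_patches(quat, patch_body, patches)
    e = compute_forces(pos, patches, pairs, lx, ly, eps_patch, eps_body,
                       body_sigma, eps_core, n_exp, r_cut, inv2d2, th1, th2,
                       gravity, eps_wall, n_wall, wall_sigma, forces, torques)
    half_dt_m = dt / (2.0 * mass)
    half_dt_i = dt / (2.0 * inertia)
    half_dt = dt / 2.0
    for s in range(nsteps):
        for i in range(n):
            for a in range(3):
                vel[i, a] += forces[i, a] * half_dt_m
                angvel[i, a] += torques[i, a] * half_dt_i
                pos[i, a] += vel[i, a] * half_dt
        rotate_quats(quat, angvel, half_dt)
        if c2 > 0.0:
            for i in range(n):
                for a in range(3):
                    vel[i, a] = c1 * vel[i, a] + c2 * noise_t[s, i, a]
        if c2r > 0.0:
            for i in range(n):
                for a in range(3):
                    angvel[i, a] = c1r * angvel[i, a] + c2r * noise_r[s, i, a]
        for i in range(n):
            for a in range(3):
                pos[i, a] += vel[i, a] * half_dt
        rotate_quats(quat, angvel, half_dt)
        rotate_patches(quat, patch_body, patches)
        e = compute_forces(pos, patches, pairs, lx, ly, eps_patch, eps_body,
                           body_sigma, eps_core, n_exp, r_cut, inv2d2, th1,
                           th2, gravity, eps_wall, n_wall, wall_sigma,
                           forces, torques)
        for i in range(n):
            for a in range(3):
                vel[i, a] += forces[i, a] * half_dt_m
                angvel[i, a] += torques[i, a] * half_dt_i
    return e, npairs


@njit(cache=True)
def rotate_quats(quat, angvel, dt):
    """Advance unit quaternions by space-frame angular velocities over dt."""
    n = quat.shape[0]
    dq = np.empty(4)
    out = np.empty(4)
    for i in range(n):
        wx = angvel[i, 0]
        wy = angvel[i, 1]
        wz = angvel[i, 2]
        wnorm = np.sqrt(wx * wx + wy * wy + wz * wz)
        if wnorm < 1e-14:
            continue
        half = 0.5 * wnorm * dt
        s = np.sin(half) / wnorm
        dq[0] = np.cos(half)
        dq[1] = wx * s
        dq[2] = wy * s
        dq[3] = wz * s
        # out = dq * q  (space-frame rotation)
        a, b = dq, quat[i]
        out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
        out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
        out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
        out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
        norm = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
        quat[i, 0] = out[0] / norm
        quat[i, 1] = out[1] / norm
        quat[i, 2] = out[2] / norm
        quat[i, 3] = out[3] / norm
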