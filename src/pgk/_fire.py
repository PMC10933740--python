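"""Numba FIRE minimiser for harmonic soft spheres in the unit periodic box.

Contact energy V = sum_pairs 0.5 (1 - d/sigma_ij)^2 for d < sigma_ij
(sigma_ij = r_i + r_j).  The integration state (dt, alpha, steps since the
last downhill reset) persists across chunks in a small float array so the
Python driver can rebuild neighbour lists between chunks.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def energy_forces(pos, radii, pairs, forces):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    e = 0.0
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= np.rint(dx)
        dy -= np.rint(dy)
        dz -= np.rint(dz)
        sig = radii[i] + radii[j]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= sig * sig:
            continue
        d = np.sqrt(d2)
        ov = 1.0 - d / sig
        e += 0.5 * ov * ov
        mag = ov / (sig * d)
        fx = mag * dx
        fy = mag * dy
        fz = mag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e


@njit(cache=True)
def fire_chunk(pos, vel, forces, radii, pairs, state, n_steps,
               dt_max, force_tol, e_floor):
    """Run up to n_steps of FIRE; returns (energy, converged_flag).

    state = [dt, alpha, since_neg]; converged when the rms force falls
    below force_tol or the energy per particle below e_floor.
    """
    n = pos.shape[0]
    alpha0 = 0.1
    f_inc = 1.1
    f_dec = 0.5
    f_alpha = 0.99
    n_min = 5.0
    dt = state[0]
    alpha = state[1]
    since_neg = state[2]
    e = energy_forces(pos, radii, pairs, forces)
    for s in range(n_steps):
        fsq = 0.0
        vsq = 0.0
        p = 0.0
        for i in range(n):
            for a in range(3):
                fsq += forces[i, a] * forces[i, a]
                vsq += vel[i, a] * vel[i, a]
                p += forces[i, a] * vel[i, a]
        if np.sqrt(fsq / n) < force_tol or e / n < e_floor:
            state[0] = dt
            state[1] = alpha
            state[2] = since_neg
            return e, 1
        if p > 0.0:
            fac = alpha * np.sqrt(vsq / fsq) if fsq > 0 else 0.0
            for i in range(n):
                for a in range(3):
                    vel[i, a] = (1.0 - alpha) * vel[i, a] + fac * forces[i, a]
            since_neg += 1.0
            if since_neg > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            for i in range(n):
                for a in range(3):
                    vel[i, a] = 0.0
            dt *= f_dec
            alpha = alpha0
            since_neg = 0.0
        for i in range(n):
            for a in range(3):
                vel[i, a] += forces[i, a] * dt
                pos[i, a] += vel[i, a] * dt
                pos[i, a] -= np.floor(pos[i, a])
        e = energy_forces(pos, radii, pairs, forces)
    state[0] = dt
    state[1] = alpha
    state[2] = since_neg
    return e, 0
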