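"""Numba-compiled inner loops for the event-driven and particle simulators.

Everything here is deliberately free of Python objects: plain scalars and
preallocated arrays in, filled arrays plus status codes out.  The public
wrappers live in :mod:`schlogl.cme` and :mod:`schlogl.particles`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# geometry kinds
GEOM_PERIODIC_BOX = 0
GEOM_REFLECTIVE_BOX = 1
GEOM_SPHERE = 2


@njit(cache=True)
def ssa_core(k1AV, km1, km2B, k2, k3, km3, V, generalized,
             X0, X20, t_max, seed, record_dt,
             times, Xs, X2s):
    """Direct-method Gillespie simulation of the conventional (4-channel) or
    generalized dimer-mediated (6-channel) scheme.

    record_dt > 0: sample on a uniform grid; record_dt <= 0: record every
    event.  Returns (n_records, overflow_flag, t_final).
    """
    np.random.seed(seed)
    cap = times.shape[0]
    t = 0.0
    X = X0
    X2 = X20
    n = 0
    times[n] = 0.0
    Xs[n] = X
    X2s[n] = X2
    n += 1
    next_rec = record_dt
    overflow = 0
    while t < t_max:
        if generalized:
            a1 = k1AV
            a2 = km1 * X
            a3 = k3 * X * (X - 1) / V
            a4 = km3 * X2
            a5 = km2B * X2
            a6 = k2 * X2 * X / V
            a0 = a1 + a2 + a3 + a4 + a5 + a6
        else:
            a1 = k1AV
            a2 = km2B * X * (X - 1) / V
            a3 = km1 * X
            a4 = k2 * X * (X - 1) * (X - 2) / (V * V)
            a0 = a1 + a2 + a3 + a4
        if a0 <= 0.0:
            break
        tau = -np.log(np.random.random()) / a0
        t_new = t + tau
        if record_dt > 0.0:
            while next_rec <= t_new and next_rec <= t_max:
                if n >= cap:
                    overflow = 1
                    return n, overflow, t
                times[n] = next_rec
                Xs[n] = X
                X2s[n] = X2
                n += 1
                next_rec += record_dt
        if t_new >= t_max:
            t = t_max
            break
        t = t_new
        r = np.random.random() * a0
        if generalized:
            if r < a1:
                X += 1
            elif r < a1 + a2:
                X -= 1
            elif r < a1 + a2 + a3:
                X -= 2
                X2 += 1
            elif r < a1 + a2 + a3 + a4:
                X += 2
                X2 -= 1
            elif r < a1 + a2 + a3 + a4 + a5:
                X += 1
            else:
                X -= 1
        else:
            if r < a1 + a2:
                X += 1
            else:
                X -= 1
        if record_dt <= 0.0:
            if n >= cap:
                overflow = 1
                return n, overflow, t
            times[n] = t
            Xs[n] = X
            X2s[n] = X2
            n += 1
    return n, overflow, t


# --------------------------------------------------------------------------
# particle-based Smoluchowski dynamics


@njit(cache=True, inline="always")
def _wrap(u, L):
    return u - L * np.floor(u / L)


@njit(cache=True)
def _apply_boundary(pos, i, geom, Lx, Ly, Lz, R):
    if geom == GEOM_PERIODIC_BOX:
        pos[i, 0] = _wrap(pos[i, 0], Lx)
        pos[i, 1] = _wrap(pos[i, 1], Ly)
        pos[i, 2] = _wrap(pos[i, 2], Lz)
    elif geom == GEOM_REFLECTIVE_BOX:
        L = (Lx, Ly, Lz)
        for d in range(3):
            u = pos[i, d]
            for _ in range(4):
                if u < 0.0:
                    u = -u
                elif u > L[d]:
                    u = 2.0 * L[d] - u
                else:
                    break
            if u < 0.0:
                u = 0.0
            elif u > L[d]:
                u = L[d]
            pos[i, d] = u
    else:  # sphere, centered at origin, reflective
        rr = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if rr > R:
            rnew = 2.0 * R - rr
            if rnew < 0.0:
                rnew = 0.999 * R
            f = rnew / rr
            pos[i, 0] *= f
            pos[i, 1] *= f
            pos[i, 2] *= f


@njit(cache=True, inline="always")
def _delta(a, b, geom, Lx, Ly, Lz, out):
    """Displacement b - a with minimum-image convention in periodic boxes."""
    out[0] = b[0] - a[0]
    out[1] = b[1] - a[1]
    out[2] = b[2] - a[2]
    if geom == GEOM_PERIODIC_BOX:
        out[0] -= Lx * np.rint(out[0] / Lx)
        out[1] -= Ly * np.rint(out[1] / Ly)
        out[2] -= Lz * np.rint(out[2] / Lz)


@njit(cache=True)
def _random_unit(vec):
    n = 0.0
    while n < 1e-12:
        vec[0] = np.random.normal()
        vec[1] = np.random.normal()
        vec[2] = np.random.normal()
        n = np.sqrt(vec[0] ** 2 + vec[1] ** 2 + vec[2] ** 2)
    vec[0] /= n
    vec[1] /= n
    vec[2] /= n


@njit(cache=True)
def _sample_position(geom, Lx, Ly, Lz, R, in_cylinder, cyl_r, cyl_hl, out):
    if in_cylinder:  # cylinder along z, centered at origin
        r = cyl_r * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        out[0] = r * np.cos(phi)
        out[1] = r * np.sin(phi)
        out[2] = cyl_hl * (2.0 * np.random.random() - 1.0)
    elif geom == GEOM_SPHERE:
        while True:
            out[0] = R * (2.0 * np.random.random() - 1.0)
            out[1] = R * (2.0 * np.random.random() - 1.0)
            out[2] = R * (2.0 * np.random.random() - 1.0)
            if out[0] ** 2 + out[1] ** 2 + out[2] ** 2 <= R * R:
                break
    else:
        out[0] = Lx * np.random.random()
        out[1] = Ly * np.random.random()
        out[2] = Lz * np.random.random()


@njit(cache=True)
def particle_core(geom, Lx, Ly, Lz, R, localize, cyl_r, cyl_hl,
                  k1AV, km1, km2B, km3,
                  sb_dd, sb_cat, su_dd, su_cat,
                  DX, DX2, dt, n_steps, seed,
                  posX, posX2, nX0, nX20,
                  record_every, rec_t, rec_X, rec_X2,
                  snap_every, snap_start,
                  snapX, snapX2, snap_nX, snap_nX2, snap_t):
    """Fixed-time-step Smoluchowski dynamics of the generalized scheme.

    Per step: Gaussian diffusion + boundary handling; dimerization X+X -> X2
    within sb_dd; catalytic removal X2+X -> X2 within sb_cat (one event per
    dimer per step); first-order events X -> 0, X2 -> 2X, X2 -> X2+X with
    probability 1-exp(-k dt); zeroth-order production Poisson(k1AV dt) placed
    uniformly in the allowed region.  Returns (nX, nX2, n_rec, n_snap, err).
    """
    np.random.seed(seed)
    capX = posX.shape[0]
    capX2 = posX2.shape[0]
    nX = nX0
    nX2 = nX20
    sX = np.sqrt(2.0 * DX * dt)
    sX2 = np.sqrt(2.0 * DX2 * dt)
    p_death = 1.0 - np.exp(-km1 * dt)
    p_dis = 1.0 - np.exp(-km3 * dt)
    p_prod = 1.0 - np.exp(-km2B * dt)
    sb_dd2 = sb_dd * sb_dd
    sb_cat2 = sb_cat * sb_cat
    dead = np.zeros(capX, dtype=np.uint8)
    dvec = np.empty(3)
    uvec = np.empty(3)
    n_rec = 0
    n_snap = 0
    err = 0
    for step in range(n_steps):
        # -- diffusion
        for i in range(nX):
            posX[i, 0] += sX * np.random.normal()
            posX[i, 1] += sX * np.random.normal()
            posX[i, 2] += sX * np.random.normal()
            _apply_boundary(posX, i, geom, Lx, Ly, Lz, R)
        for i in range(nX2):
            posX2[i, 0] += sX2 * np.random.normal()
            posX2[i, 1] += sX2 * np.random.normal()
            posX2[i, 2] += sX2 * np.random.normal()
            _apply_boundary(posX2, i, geom, Lx, Ly, Lz, R)
        # -- dimerization X + X -> X2
        for i in range(nX):
            dead[i] = 0
        if sb_dd > 0.0:
            for i in range(nX):
                if dead[i]:
                    continue
                for j in range(i + 1, nX):
                    if dead[j]:
                        continue
                    _delta(posX[i], posX[j], geom, Lx, Ly, Lz, dvec)
                    if dvec[0] ** 2 + dvec[1] ** 2 + dvec[2] ** 2 < sb_dd2:
                        if nX2 >= capX2:
                            err = 2
                            return nX, nX2, n_rec, n_snap, err
                        for d in range(3):
                            posX2[nX2, d] = posX[i, d] + 0.5 * dvec[d]
                        _apply_boundary(posX2, nX2, geom, Lx, Ly, Lz, R)
                        nX2 += 1
                        dead[i] = 1
                        dead[j] = 1
                        break
        # -- catalytic degradation X2 + X -> X2 (at most one per dimer per step)
        if sb_cat > 0.0:
            for j in range(nX2):
                for i in range(nX):
                    if dead[i]:
                        continue
                    _delta(posX2[j], posX[i], geom, Lx, Ly, Lz, dvec)
                    if dvec[0] ** 2 + dvec[1] ** 2 + dvec[2] ** 2 < sb_cat2:
                        dead[i] = 1
                        break
        # compact X
        k = 0
        for i in range(nX):
            if not dead[i]:
                if k != i:
                    posX[k, 0] = posX[i, 0]
                    posX[k, 1] = posX[i, 1]
                    posX[k, 2] = posX[i, 2]
                k += 1
        nX = k
        # -- monomer death
        i = nX - 1
        while i >= 0:
            if np.random.random() < p_death:
                nX -= 1
                posX[i, 0] = posX[nX, 0]
                posX[i, 1] = posX[nX, 1]
                posX[i, 2] = posX[nX, 2]
            i -= 1
        # -- dimer dissociation and catalytic production
        j = nX2 - 1
        while j >= 0:
            if np.random.random() < p_dis:
                if nX + 2 > capX:
                    err = 1
                    return nX, nX2, n_rec, n_snap, err
                _random_unit(uvec)
                for d in range(3):
                    posX[nX, d] = posX2[j, d] + 0.5 * su_dd * uvec[d]
                    posX[nX + 1, d] = posX2[j, d] - 0.5 * su_dd * uvec[d]
                _apply_boundary(posX, nX, geom, Lx, Ly, Lz, R)
                _apply_boundary(posX, nX + 1, geom, Lx, Ly, Lz, R)
                nX += 2
                nX2 -= 1
                posX2[j, 0] = posX2[nX2, 0]
                posX2[j, 1] = posX2[nX2, 1]
                posX2[j, 2] = posX2[nX2, 2]
            elif np.random.random() < p_prod:
                if nX >= capX:
                    err = 1
                    return nX, nX2, n_rec, n_snap, err
                _random_unit(uvec)
                for d in range(3):
                    posX[nX, d] = posX2[j, d] + su_cat * uvec[d]
                _apply_boundary(posX, nX, geom, Lx, Ly, Lz, R)
                nX += 1
            j -= 1
        # -- zeroth-order production
        nb = np.random.poisson(k1AV * dt)
        for _ in range(nb):
            if nX >= capX:
                err = 1
                return nX, nX2, n_rec, n_snap, err
            _sample_position(geom, Lx, Ly, Lz, R, localize, cyl_r, cyl_hl,
                             posX[nX])
            nX += 1
        # -- recording
        if record_every > 0 and (step + 1) % record_every == 0:
            if n_rec < rec_t.shape[0]:
                rec_t[n_rec] = (step + 1) * dt
                rec_X[n_rec] = nX
                rec_X2[n_rec] = nX2
                n_rec += 1
        if (snap_every > 0 and step + 1 >= snap_start
                and (step + 1 - snap_start) % snap_every == 0
                and n_snap < snap_t.shape[0]):
            m = min(nX, snapX.shape[1])
            for i in range(m):
                snapX[n_snap, i, 0] = posX[i, 0]
                snapX[n_snap, i, 1] = posX[i, 1]
                snapX[n_snap, i, 2] = posX[i, 2]
            m2 = min(nX2, snapX2.shape[1])
            for i in range(m2):
                snapX2[n_snap, i, 0] = posX2[i, 0]
                snapX2[n_snap, i, 1] = posX2[i, 1]
                snapX2[n_snap, i, 2] = posX2[i, 2]
            snap_nX[n_snap] = m
            snap_nX2[n_snap] = m2
            snap_t[n_snap] = (step + 1) * dt
            n_snap += 1
    return nX, nX2, n_rec, n_snap, err


@njit(cache=True)
def pair_survival_steps(sigma_b, r0, s, n_trials, n_steps, seed):
    """Monte-Carlo geminate-recombination probability for an isolated pair.

    The relative coordinate starts at distance r0, takes Gaussian steps of
    per-axis std s, and reacts when it comes within sigma_b.  Used for
    diagnostics of product-placement policies.
    """
    np.random.seed(seed)
    hits = 0
    for _ in range(n_trials):
        x = r0
        y = 0.0
        z = 0.0
        for _ in range(n_steps):
            x += s * np.random.normal()
            y += s * np.random.normal()
            z += s * np.random.normal()
            if x * x + y * y + z * z < sigma_b * sigma_b:
                hits += 1
                break
    return hits / n_trials
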