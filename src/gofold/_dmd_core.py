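"""Event-driven core of the discontinuous MD engine (numba-compiled).

All interactions are piecewise constant, so atoms fly ballistically between
events.  Pair interactions are encoded in flat arrays:

``kind == 0``  hard sphere: reflecting core at ``sqrt(rin2)``;
``kind == 1``  square well: core at ``sqrt(rin2)``, well edge at
               ``sqrt(rout2)``, depth ``eps`` (native contacts);
``kind == 2``  bond: infinite square well between ``sqrt(rin2)`` and
               ``sqrt(rout2)`` (covalent 1-2 and pseudo 1-3 constraints).

The scheduler keeps the absolute next-event time of every pair; after an
event only the pairs involving the two affected atoms are recomputed (other
pairs' relative motion is unchanged).  Positions of all atoms are advanced
to the current event time at every event; the pair separation is snapped
exactly onto the discontinuity before the velocity update, which keeps the
in-well bookkeeping consistent over arbitrarily long runs.

Andersen thermostat ghost collisions (velocity redraw of one atom from the
Maxwell-Boltzmann distribution) are scheduled as Poisson events and count
toward the event budget.  Units: unit masses, k_B = 1, energy in eps,
length in Angstrom.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf

# event kinds
EV_CORE = 0  # hard-core bounce (hard-sphere or well inner wall)
EV_ENTRY = 1  # well outer boundary crossed from outside
EV_ESCAPE = 2  # well outer boundary reached from inside (escape or bounce)
EV_BOND_MIN = 3
EV_BOND_MAX = 4

ERR_OK = 0
ERR_NEGATIVE_DT = 1
ERR_NO_EVENT = 2


@njit(cache=True)
def _pair_event(p, t, pos, vel, pi, pj, kind, rin2, rout2, in_well):
    """Absolute time and kind of the next event of pair *p* (INF if none)."""
    i = pi[p]
    j = pj[p]
    rx = pos[j, 0] - pos[i, 0]
    ry = pos[j, 1] - pos[i, 1]
    rz = pos[j, 2] - pos[i, 2]
    vx = vel[j, 0] - vel[i, 0]
    vy = vel[j, 1] - vel[i, 1]
    vz = vel[j, 2] - vel[i, 2]
    a = vx * vx + vy * vy + vz * vz
    if a == 0.0:
        return INF, -1
    b = rx * vx + ry * vy + rz * vz
    rr = rx * rx + ry * ry + rz * rz
    k = kind[p]
    if k == 0:
        if b < 0.0:
            disc = b * b - a * (rr - rin2[p])
            if disc > 0.0:
                return t + (-b - np.sqrt(disc)) / a, EV_CORE
        return INF, -1
    if k == 1:
        if in_well[p] == 1:
            if b < 0.0:
                disc = b * b - a * (rr - rin2[p])
                if disc > 0.0:
                    return t + (-b - np.sqrt(disc)) / a, EV_CORE
            disc = b * b - a * (rr - rout2[p])
            if disc < 0.0:
                disc = 0.0
            return t + (-b + np.sqrt(disc)) / a, EV_ESCAPE
        if b < 0.0:
            disc = b * b - a * (rr - rout2[p])
            if disc > 0.0:
                dt = (-b - np.sqrt(disc)) / a
                if dt < 0.0:
                    dt = 0.0
                return t + dt, EV_ENTRY
        return INF, -1
    # bond
    tmin = INF
    kmin = -1
    if b < 0.0:
        disc = b * b - a * (rr - rin2[p])
        if disc > 0.0:
            tmin = (-b - np.sqrt(disc)) / a
            kmin = EV_BOND_MIN
    disc = b * b - a * (rr - rout2[p])
    if disc < 0.0:
        disc = 0.0
    tout = (-b + np.sqrt(disc)) / a
    if tout < tmin:
        tmin = tout
        kmin = EV_BOND_MAX
    return t + tmin, kmin


@njit(cache=True)
def _refresh_atom(
    atom, t, pos, vel, pi, pj, kind, rin2, rout2, in_well,
    ap_start, ap_idx, tev, kev,
):
    for q in range(ap_start[atom], ap_start[atom + 1]):
        p = ap_idx[q]
        tev[p], kev[p] = _pair_event(
            p, t, pos, vel, pi, pj, kind, rin2, rout2, in_well
        )


@njit(cache=True)
def run_events(
    pos,
    vel,
    pi,
    pj,
    kind,
    rin2,
    rout2,
    in_well,
    ap_start,
    ap_idx,
    eps,
    n_events,
    temperature,
    thermostat_rate,
    sample_every,
    record_coords,
    seed,
):
    """Run *n_events* events in place; return samples and an error code.

    Returns ``(err, clock, n_formed, sample_t, sample_epot, sample_kin,
    sample_coords, n_samples)``.
    """
    np.random.seed(seed)
    n_atoms = pos.shape[0]
    n_pairs = pi.shape[0]
    t = 0.0

    n_formed = 0
    for p in range(n_pairs):
        if kind[p] == 1 and in_well[p] == 1:
            n_formed += 1

    tev = np.empty(n_pairs)
    kev = np.empty(n_pairs, dtype=np.int8)
    for p in range(n_pairs):
        tev[p], kev[p] = _pair_event(
            p, t, pos, vel, pi, pj, kind, rin2, rout2, in_well
        )

    use_thermo = thermostat_rate > 0.0
    t_thermo = INF
    if use_thermo:
        t_thermo = t + np.random.exponential(
            1.0 / (thermostat_rate * n_atoms)
        )

    max_samples = int(n_events // sample_every) + 1
    sample_t = np.zeros(max_samples)
    sample_epot = np.zeros(max_samples)
    sample_kin = np.zeros(max_samples)
    if record_coords:
        sample_coords = np.zeros((max_samples, n_atoms, 3))
    else:
        sample_coords = np.zeros((1, 1, 3))
    n_samples = 0

    processed = 0
    while processed < n_events:
        # earliest pair event
        pmin = -1
        tmin = INF
        for p in range(n_pairs):
            if tev[p] < tmin:
                tmin = tev[p]
                pmin = p

        if use_thermo and t_thermo < tmin:
            dt = t_thermo - t
            if dt < 0.0:
                return (ERR_NEGATIVE_DT, t, n_formed, sample_t, sample_epot,
                        sample_kin, sample_coords, n_samples)
            for i in range(n_atoms):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t = t_thermo
            k_atom = np.random.randint(0, n_atoms)
            s = np.sqrt(temperature)
            vel[k_atom, 0] = s * np.random.standard_normal()
            vel[k_atom, 1] = s * np.random.standard_normal()
            vel[k_atom, 2] = s * np.random.standard_normal()
            _refresh_atom(
                k_atom, t, pos, vel, pi, pj, kind, rin2, rout2, in_well,
                ap_start, ap_idx, tev, kev,
            )
            t_thermo = t + np.random.exponential(
                1.0 / (thermostat_rate * n_atoms)
            )
        else:
            if pmin < 0:
                return (ERR_NO_EVENT, t, n_formed, sample_t, sample_epot,
                        sample_kin, sample_coords, n_samples)
            dt = tmin - t
            if dt < -1e-9:
                return (ERR_NEGATIVE_DT, t, n_formed, sample_t, sample_epot,
                        sample_kin, sample_coords, n_samples)
            for i in range(n_atoms):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t = tmin

            p = pmin
            ev = kev[p]
            i = pi[p]
            j = pj[p]
            rx = pos[j, 0] - pos[i, 0]
            ry = pos[j, 1] - pos[i, 1]
            rz = pos[j, 2] - pos[i, 2]
            rnorm = np.sqrt(rx * rx + ry * ry + rz * rz)
            # snap the pair exactly onto the discontinuity
            if ev == EV_CORE or ev == EV_BOND_MIN:
                target = np.sqrt(rin2[p])
            else:
                target = np.sqrt(rout2[p])
            if rnorm > 0.0:
                half = 0.5 * (target / rnorm - 1.0)
                dx = half * rx
                dy = half * ry
                dz = half * rz
                pos[j, 0] += dx
                pos[j, 1] += dy
                pos[j, 2] += dz
                pos[i, 0] -= dx
                pos[i, 1] -= dy
                pos[i, 2] -= dz
                rx = pos[j, 0] - pos[i, 0]
                ry = pos[j, 1] - pos[i, 1]
                rz = pos[j, 2] - pos[i, 2]
                rnorm = target
            nx = rx / rnorm
            ny = ry / rnorm
            nz = rz / rnorm
            vx = vel[j, 0] - vel[i, 0]
            vy = vel[j, 1] - vel[i, 1]
            vz = vel[j, 2] - vel[i, 2]
            vr = vx * nx + vy * ny + vz * nz

            if ev == EV_ENTRY:
                # capture: relative radial speed grows, KE += eps
                vr_new = -np.sqrt(vr * vr + 4.0 * eps)
                in_well[p] = 1
                n_formed += 1
            elif ev == EV_ESCAPE:
                if vr * vr > 4.0 * eps:
                    vr_new = np.sqrt(vr * vr - 4.0 * eps)
                    in_well[p] = 0
                    n_formed -= 1
                else:
                    vr_new = -vr  # insufficient radial KE: bounce back in
            else:
                vr_new = -vr  # elastic wall (core, bond walls)

            half_dv = 0.5 * (vr_new - vr)
            vel[j, 0] += half_dv * nx
            vel[j, 1] += half_dv * ny
            vel[j, 2] += half_dv * nz
            vel[i, 0] -= half_dv * nx
            vel[i, 1] -= half_dv * ny
            vel[i, 2] -= half_dv * nz

            _refresh_atom(
                i, t, pos, vel, pi, pj, kind, rin2, rout2, in_well,
                ap_start, ap_idx, tev, kev,
            )
            _refresh_atom(
                j, t, pos, vel, pi, pj, kind, rin2, rout2, in_well,
                ap_start, ap_idx, tev, kev,
            )

        processed += 1
        if processed % sample_every == 0:
            kin = 0.0
            for i in range(n_atoms):
                kin += (
                    vel[i, 0] * vel[i, 0]
                    + vel[i, 1] * vel[i, 1]
                    + vel[i, 2] * vel[i, 2]
                )
            kin *= 0.5
            sample_t[n_samples] = t
            sample_epot[n_samples] = -eps * n_formed
            sample_kin[n_samples] = kin
            if record_coords:
                for i in range(n_atoms):
                    sample_coords[n_samples, i, 0] = pos[i, 0]
                    sample_coords[n_samples, i, 1] = pos[i, 1]
                    sample_coords[n_samples, i, 2] = pos[i, 2]
            n_samples += 1

    return (ERR_OK, t, n_formed, sample_t, sample_epot, sample_kin,
            sample_coords, n_samples)
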