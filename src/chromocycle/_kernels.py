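"""Numba-compiled force and integrator kernels.

Everything here works on bare float64 arrays in reduced units (length sigma,
energy epsilon, time tau, mass 1).  The public modules wrap these kernels with
validated dataclasses; tests exercise the kernels through those wrappers.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# WCA repulsion range
_RCUT2 = 2.0 ** (1.0 / 3.0)  # (2^{1/6})^2
# beyond |eta (r_c - r)| = 8 the contact indicator is flat to ~1e-7
_TANH_SPAN = 8.0


@njit(cache=True, fastmath=True, inline="always")
def _tanh(x):
    # exact to double precision on the spans used here; ~3x faster than libm
    e = math.exp(2.0 * x)
    return 1.0 - 2.0 / (e + 1.0)


@njit(cache=True, fastmath=True)
def homopolymer_ef(x, bond_length, k_bond, k_angle, sc_strength, sc_cap,
                   r_conf, k_wall, forces):
    """Bond + angle + capped soft-core + spherical wall.  Returns the energy.

    ``r_conf < 0`` disables the wall.  Forces are accumulated in place.
    Directly bonded pairs are excluded from the soft-core term.
    """
    n = x.shape[0]
    energy = 0.0

    # harmonic pseudo-bonds
    if k_bond > 0.0:
        for i in range(n - 1):
            dx = x[i + 1, 0] - x[i, 0]
            dy = x[i + 1, 1] - x[i, 1]
            dz = x[i + 1, 2] - x[i, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - bond_length
            energy += 0.5 * k_bond * dr * dr
            if r > 1e-12:
                fmag = -k_bond * dr / r
                forces[i + 1, 0] += fmag * dx
                forces[i + 1, 1] += fmag * dy
                forces[i + 1, 2] += fmag * dz
                forces[i, 0] -= fmag * dx
                forces[i, 1] -= fmag * dy
                forces[i, 2] -= fmag * dz

    # linear-placement favoured angles: V = k_a (1 + cos theta)
    if k_angle > 0.0:
        for i in range(1, n - 1):
            ax = x[i - 1, 0] - x[i, 0]
            ay = x[i - 1, 1] - x[i, 1]
            az = x[i - 1, 2] - x[i, 2]
            bx = x[i + 1, 0] - x[i, 0]
            by = x[i + 1, 1] - x[i, 1]
            bz = x[i + 1, 2] - x[i, 2]
            na2 = ax * ax + ay * ay + az * az
            nb2 = bx * bx + by * by + bz * bz
            if na2 < 1e-24 or nb2 < 1e-24:
                energy += k_angle  # degenerate: cos undefined, treat as 0
                continue
            na = math.sqrt(na2)
            nb = math.sqrt(nb2)
            dot = ax * bx + ay * by + az * bz
            c = dot / (na * nb)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            energy += k_angle * (1.0 + c)
            # grad of cos wrt the two outer beads
            gax = bx / (na * nb) - c * ax / na2
            gay = by / (na * nb) - c * ay / na2
            gaz = bz / (na * nb) - c * az / na2
            gbx = ax / (na * nb) - c * bx / nb2
            gby = ay / (na * nb) - c * by / nb2
            gbz = az / (na * nb) - c * bz / nb2
            forces[i - 1, 0] -= k_angle * gax
            forces[i - 1, 1] -= k_angle * gay
            forces[i - 1, 2] -= k_angle * gaz
            forces[i + 1, 0] -= k_angle * gbx
            forces[i + 1, 1] -= k_angle * gby
            forces[i + 1, 2] -= k_angle * gbz
            forces[i, 0] += k_angle * (gax + gbx)
            forces[i, 1] += k_angle * (gay + gby)
            forces[i, 2] += k_angle * (gaz + gbz)

    # tanh-capped WCA soft core: V = cap * tanh(V_WCA / cap); bounded by cap,
    # force -> 0 as r -> 0 so chains can cross (topoisomerase contract)
    if sc_strength > 0.0 and sc_cap > 0.0:
        for i in range(n):
            for j in range(i + 2, n):
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= _RCUT2:
                    continue
                if r2 < 1e-12:
                    energy += sc_cap
                    continue
                inv6 = 1.0 / (r2 * r2 * r2)
                vw = 4.0 * sc_strength * (inv6 * inv6 - inv6) + sc_strength
                u = vw / sc_cap
                if u > 40.0:
                    energy += sc_cap
                    continue
                t = _tanh(u)
                energy += sc_cap * t
                # dV/dr2 = (1 - t^2) * dvw/dr2 ; dvw/dr2 = -(24 inv6^2 - 12 inv6)*s/r2... derive:
                # vw = 4s(r^-12 - r^-6) + s ; dvw/dr2 = 4s(-6 r^-14 + 3 r^-8)
                dvw_dr2 = 4.0 * sc_strength * (-6.0 * inv6 * inv6 + 3.0 * inv6) / r2
                dV_dr2 = (1.0 - t * t) * dvw_dr2
                fpair = -2.0 * dV_dr2  # force = -dV/dr * rhat = -2 dV/dr2 * dvec
                forces[i, 0] += fpair * dx
                forces[i, 1] += fpair * dy
                forces[i, 2] += fpair * dz
                forces[j, 0] -= fpair * dx
                forces[j, 1] -= fpair * dy
                forces[j, 2] -= fpair * dz

    # half-harmonic spherical wall centred at the origin
    if r_conf >= 0.0 and k_wall > 0.0:
        for i in range(n):
            r2 = x[i, 0] * x[i, 0] + x[i, 1] * x[i, 1] + x[i, 2] * x[i, 2]
            r = math.sqrt(r2)
            if r > r_conf:
                d = r - r_conf
                energy += 0.5 * k_wall * d * d
                if r > 1e-12:
                    fmag = -k_wall * d / r
                    forces[i, 0] += fmag * x[i, 0]
                    forces[i, 1] += fmag * x[i, 1]
                    forces[i, 2] += fmag * x[i, 2]
    return energy


@njit(cache=True, fastmath=True)
def bias_ef(x, alpha, r_c, eta, forces):
    """Hi-C biasing term: sum over pairs of alpha_ij * f(r_ij).

    f is the smooth contact indicator (tanh switch at r_c).  Pairs with
    |i - j| <= 1 carry alpha = 0 by construction and are skipped.
    Returns the energy; forces accumulated in place.
    """
    n = x.shape[0]
    energy = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            a = alpha[i, j]
            if a == 0.0:
                continue
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            arg = eta * (r_c - r)
            if arg > _TANH_SPAN:
                energy += a
                continue
            if arg < -_TANH_SPAN:
                continue
            t = _tanh(arg)
            energy += a * 0.5 * (1.0 + t)
            # df/dr = -eta/2 (1 - t^2); force = -a df/dr rhat
            if r > 1e-12:
                fmag = -a * 0.5 * eta * (1.0 - t * t) / r
                forces[i, 0] -= fmag * dx
                forces[i, 1] -= fmag * dy
                forces[i, 2] -= fmag * dz
                forces[j, 0] += fmag * dx
                forces[j, 1] += fmag * dy
                forces[j, 2] += fmag * dz
    return energy


@njit(cache=True, fastmath=True)
def _fused_pair_ef(x, sc_strength, sc_cap, alpha, r_c, eta, use_bias, forces):
    """Soft-core + bias in one pair loop: one distance evaluation per pair.

    Identical maths to homopolymer_ef's soft-core block plus bias_ef, but the
    tanh switch is short-circuited outside the shell where it is flat to
    ~1e-7 — this loop dominates the integrator cost.
    """
    n = x.shape[0]
    energy = 0.0
    do_sc = sc_strength > 0.0 and sc_cap > 0.0
    r_hi = r_c + _TANH_SPAN / eta
    r_lo = r_c - _TANH_SPAN / eta
    r_hi2 = r_hi * r_hi
    r_lo2 = r_lo * r_lo if r_lo > 0.0 else -1.0
    for i in range(n):
        for j in range(i + 2, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            fpair = 0.0
            if do_sc and r2 < _RCUT2:
                if r2 < 1e-12:
                    energy += sc_cap
                else:
                    inv6 = 1.0 / (r2 * r2 * r2)
                    vw = 4.0 * sc_strength * (inv6 * inv6 - inv6) + sc_strength
                    u = vw / sc_cap
                    if u > 40.0:
                        energy += sc_cap
                    else:
                        t = _tanh(u)
                        energy += sc_cap * t
                        dvw_dr2 = 4.0 * sc_strength * (-6.0 * inv6 * inv6 + 3.0 * inv6) / r2
                        fpair += -2.0 * (1.0 - t * t) * dvw_dr2
            if use_bias:
                a = alpha[i, j]
                if a != 0.0:
                    if r2 >= r_hi2:
                        pass  # f ~ 0
                    elif r2 <= r_lo2:
                        energy += a  # f ~ 1, flat
                    else:
                        r = math.sqrt(r2)
                        t = _tanh(eta * (r_c - r))
                        energy += a * 0.5 * (1.0 + t)
                        if r > 1e-12:
                            # F_i = -dV/dr * (dvec/r); df/dr = -eta/2 (1 - t^2)
                            fpair += a * 0.5 * eta * (1.0 - t * t) / r
            if fpair != 0.0:
                forces[i, 0] += fpair * dx
                forces[i, 1] += fpair * dy
                forces[i, 2] += fpair * dz
                forces[j, 0] -= fpair * dx
                forces[j, 1] -= fpair * dy
                forces[j, 2] -= fpair * dz
    return energy


@njit(cache=True)
def total_forces(x, bond_length, k_bond, k_angle, sc_strength, sc_cap,
                 r_conf, k_wall, alpha, r_c, eta, use_bias, forces):
    forces[:] = 0.0
    e = homopolymer_ef(x, bond_length, k_bond, k_angle, 0.0, sc_cap,
                       r_conf, k_wall, forces)
    e += _fused_pair_ef(x, sc_strength, sc_cap, alpha, r_c, eta, use_bias,
                        forces)
    return e


@njit(cache=True)
def baoab_chunk(x, v, forces, kT_steps, noise, dt, c1,
                bond_length, k_bond, k_angle, sc_strength, sc_cap,
                r_conf, k_wall, alpha, r_c, eta, use_bias):
    """Advance ``len(kT_steps)`` BAOAB steps in place.

    ``forces`` must hold the forces at the incoming positions; it holds the
    forces at the outgoing positions on return.  ``noise`` is standard-normal,
    shape (n_steps, n, 3), generated by the caller so all randomness flows
    from one seeded generator.  With c1 = 1 (zero friction) the scheme
    reduces to velocity Verlet.
    """
    n_steps = kT_steps.shape[0]
    n = x.shape[0]
    half_dt = 0.5 * dt
    for s in range(n_steps):
        c2 = math.sqrt(kT_steps[s] * (1.0 - c1 * c1))
        for i in range(n):
            for k in range(3):
                v[i, k] += half_dt * forces[i, k]
                x[i, k] += half_dt * v[i, k]
                v[i, k] = c1 * v[i, k] + c2 * noise[s, i, k]
                x[i, k] += half_dt * v[i, k]
        total_forces(x, bond_length, k_bond, k_angle, sc_strength, sc_cap,
                     r_conf, k_wall, alpha, r_c, eta, use_bias, forces)
        for i in range(n):
            for k in range(3):
                v[i, k] += half_dt * forces[i, k]


@njit(cache=True, fastmath=True)
def contact_matrix(x, r_c, eta, out):
    """Smooth contact indicator for every pair; symmetric, diagonal = 1."""
    n = x.shape[0]
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            arg = eta * (r_c - r)
            if arg > _TANH_SPAN:
                f = 1.0
            elif arg < -_TANH_SPAN:
                f = 0.0
            else:
                f = 0.5 * (1.0 + _tanh(arg))
            out[i, j] = f
            out[j, i] = f


@njit(cache=True, fastmath=True)
def accumulate_contacts(frames, r_c, eta, acc):
    """Sum the contact indicator matrix over an ensemble of configurations."""
    tmp = np.empty((frames.shape[1], frames.shape[1]))
    for m in range(frames.shape[0]):
        contact_matrix(frames[m], r_c, eta, tmp)
        acc += tmp
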