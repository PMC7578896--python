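"""Numba kernels for the polymer force field and BAOAB Langevin integrator.

All quantities are in reduced units (bead mass = 1, energies in units of the
reduced temperature).  The force field has three terms:

* harmonic bonds between consecutive beads, (k/2)(r - b)^2;
* a soft-core repulsion u(r) = E_cap (1 - (r/sigma)^2)^2 for r < sigma
  between non-bonded pairs -- finite at overlap (u(0) = E_cap), continuously
  differentiable at r = sigma, so chain crossing is possible;
* optional Hi-C restraints alpha_ij * w(r_ij) with the smoothed contact
  step w(r) = (1 + tanh(eta (r_c - r))) / 2 on pairs |i - j| > 1.

The tanh tail is truncated where eta (r - r_c) > 12 (w < 4e-11), which is far
below every tolerance used in this package.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: dimensionless truncation of the tanh switching tail
_TAIL = 12.0


@njit(cache=True, fastmath=True)
def energy_forces(x, alphas, has_field, b, bond_k, sigma, e_cap, r_c, eta, forces):
    """Total potential energy and exact negative gradient. Returns energy."""
    n = x.shape[0]
    forces[:] = 0.0
    e = 0.0
    sig2 = sigma * sigma
    rcut = r_c + _TAIL / eta
    rcut2 = rcut * rcut
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if j == i + 1:
                r = np.sqrt(r2)
                dr = r - b
                e += 0.5 * bond_k * dr * dr
                if r > 0.0:
                    g = bond_k * dr / r  # dV/dr / r
                    forces[i, 0] += g * dx
                    forces[i, 1] += g * dy
                    forces[i, 2] += g * dz
                    forces[j, 0] -= g * dx
                    forces[j, 1] -= g * dy
                    forces[j, 2] -= g * dz
                continue
            if r2 >= rcut2 and r2 >= sig2:
                continue
            r = np.sqrt(r2)
            g = 0.0  # accumulated dV/dr / r
            if r2 < sig2:
                q = 1.0 - r2 / sig2
                e += e_cap * q * q
                # du/dr = -4 E_cap q r / sigma^2 ; g = du/dr / r
                g += -4.0 * e_cap * q / sig2
            if has_field and r2 < rcut2:
                a = alphas[i, j]
                if a != 0.0:
                    t = np.tanh(eta * (r_c - r))
                    e += a * 0.5 * (1.0 + t)
                    if r > 0.0:
                        g += -a * 0.5 * eta * (1.0 - t * t) / r
            forces[i, 0] += g * dx
            forces[i, 1] += g * dy
            forces[i, 2] += g * dz
            forces[j, 0] -= g * dx
            forces[j, 1] -= g * dy
            forces[j, 2] -= g * dz
    return e


@njit(cache=True, fastmath=True)
def baoab_run(x, v, alphas, has_field, b, bond_k, sigma, e_cap, r_c, eta,
              dt, gamma, temperature, n_steps, record_steps, seed,
              frames, pot_out, kin_out):
    """BAOAB Langevin integration, recording frames at given step indices.

    ``record_steps`` must be sorted; step index 0 records the initial state.
    Returns the step index at which the energy became non-finite, or -1.
    Positions/velocities are updated in place.
    """
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(temperature * (1.0 - c1 * c1))
    e = energy_forces(x, alphas, has_field, b, bond_k, sigma, e_cap, r_c, eta, f)
    rec = 0
    n_rec = record_steps.shape[0]
    if n_rec > 0 and record_steps[0] == 0:
        frames[0] = x
        pot_out[0] = e
        ke = 0.0
        for i in range(n):
            ke += v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
        kin_out[0] = 0.5 * ke
        rec = 1
    for step in range(1, n_steps + 1):
        # B: half kick
        for i in range(n):
            v[i, 0] += 0.5 * dt * f[i, 0]
            v[i, 1] += 0.5 * dt * f[i, 1]
            v[i, 2] += 0.5 * dt * f[i, 2]
        # A: half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        # O: Ornstein-Uhlenbeck
        for i in range(n):
            v[i, 0] = c1 * v[i, 0] + c2 * np.random.standard_normal()
            v[i, 1] = c1 * v[i, 1] + c2 * np.random.standard_normal()
            v[i, 2] = c1 * v[i, 2] + c2 * np.random.standard_normal()
        # A: half drift
        for i in range(n):
            x[i, 0] += 0.5 * dt * v[i, 0]
            x[i, 1] += 0.5 * dt * v[i, 1]
            x[i, 2] += 0.5 * dt * v[i, 2]
        # B: half kick with new forces
        e = energy_forces(x, alphas, has_field, b, bond_k, sigma, e_cap, r_c,
                          eta, f)
        for i in range(n):
            v[i, 0] += 0.5 * dt * f[i, 0]
            v[i, 1] += 0.5 * dt * f[i, 1]
            v[i, 2] += 0.5 * dt * f[i, 2]
        if rec < n_rec and record_steps[rec] == step:
            if not np.isfinite(e):
                return step
            frames[rec] = x
            pot_out[rec] = e
            ke = 0.0
            for i in range(n):
                ke += v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2
            kin_out[rec] = 0.5 * ke
            rec += 1
    if not np.isfinite(e):
        return n_steps
    return -1


@njit(cache=True, fastmath=True)
def contact_step_matrix(frames, r_c, eta):
    """Mean smoothed contact step w(r_ij) over an (F, n, 3) frame stack."""
    n_frames = frames.shape[0]
    n = frames.shape[1]
    p = np.zeros((n, n))
    for fidx in range(n_frames):
        for i in range(n):
            p[i, i] += 0.5 * (1.0 + np.tanh(eta * r_c))
            for j in range(i + 1, n):
                dx = frames[fidx, j, 0] - frames[fidx, i, 0]
                dy = frames[fidx, j, 1] - frames[fidx, i, 1]
                dz = frames[fidx, j, 2] - frames[fidx, i, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                w = 0.5 * (1.0 + np.tanh(eta * (r_c - r)))
                p[i, j] += w
                p[j, i] += w
    return p / n_frames


@njit(cache=True, fastmath=True)
def mean_pairwise_distances(frames):
    """Mean distance matrix over an (F, n, 3) frame stack."""
    n_frames = frames.shape[0]
    n = frames.shape[1]
    d = np.zeros((n, n))
    for fidx in range(n_frames):
        for i in range(n):
            for j in range(i + 1, n):
                dx = frames[fidx, j, 0] - frames[fidx, i, 0]
                dy = frames[fidx, j, 1] - frames[fidx, i, 1]
                dz = frames[fidx, j, 2] - frames[fidx, i, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                d[i, j] += r
                d[j, i] += r
    return d / n_frames
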