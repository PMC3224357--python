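"""Numba photon-transport kernel: Woodcock (delta) tracking in a stylized body.

Physics: photoelectric absorption (full local deposition) and incoherent
scattering with Klein-Nishina angular/energy sampling, under the kerma
approximation (secondary electrons deposit locally).  Photons falling below
the low-energy cutoff deposit their remaining energy locally, so deposited
energy never exceeds emitted energy in any run.

The RNG is a counter-based splitmix64/xorshift64* pair seeded independently
per batch, making results independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_INV_2_53 = 1.0 / 9007199254740992.0
MEC2_KEV = 510.99895


@njit(cache=False, inline="always")
def _mix(state):
    # splitmix64 step; state is uint64
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=False, inline="always")
def _u01(state):
    state, z = _mix(state)
    return state, (z >> np.uint64(11)) * _INV_2_53


@njit(cache=False)
def transport_batches(
    photons_per_batch, seeds,
    # source: parallel beam along +/- one transverse axis
    src_axis, src_sign, src_start, t_lo, t_hi, z_lo, z_hi,
    # spectrum (cumulative weights and bin energies)
    e_cdf, e_vals,
    # geometry
    bodies, body_mat, org_c, org_ax, org_mat, org_id, n_org_ids,
    bb_lo, bb_hi,
    # material grids
    e0, de, mu_tot, mu_inc, mu_maj,
    cutoff_keV, primary_only,
):
    """Run ``len(seeds)`` batches; returns (edep[batch, organ], emitted[batch]).

    Organ index ``n_org_ids`` is the rest-of-body compartment; deposits outside
    any region are discarded (free air).
    """
    n_batches = seeds.shape[0]
    n_bins = e_vals.shape[0]
    n_bodies = bodies.shape[0]
    n_parts = org_c.shape[0]
    ng = mu_maj.shape[0]

    edep = np.zeros((n_batches, n_org_ids + 1))
    emitted = np.zeros(n_batches)

    for b in range(n_batches):
        state = seeds[b]
        for _ in range(photons_per_batch):
            # --- sample energy from the spectrum CDF
            state, u = _u01(state)
            lo = 0
            hi = n_bins - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if e_cdf[mid] < u:
                    lo = mid + 1
                else:
                    hi = mid
            energy = e_vals[lo]
            emitted[b] += energy

            # --- source position and direction
            state, u1 = _u01(state)
            state, u2 = _u01(state)
            t = t_lo + (t_hi - t_lo) * u1
            z = z_lo + (z_hi - z_lo) * u2
            if src_axis == 0:
                x = src_start
                y = t
                ux, uy, uz = src_sign, 0.0, 0.0
            else:
                x = t
                y = src_start
                ux, uy, uz = 0.0, src_sign, 0.0

            alive = True
            it = 0
            while alive and it < 100000:
                it += 1
                # majorant at current energy (linear interp on uniform grid)
                g = (energy - e0) / de
                if g < 0.0:
                    g = 0.0
                i0 = int(g)
                if i0 > ng - 2:
                    i0 = ng - 2
                f = g - i0
                mu_m = mu_maj[i0] + (mu_maj[i0 + 1] - mu_maj[i0]) * f

                state, u = _u01(state)
                step = -np.log(1.0 - u) / mu_m
                x += ux * step
                y += uy * step
                z += uz * step

                if (x < bb_lo[0] or x > bb_hi[0] or y < bb_lo[1] or y > bb_hi[1]
                        or z < bb_lo[2] or z > bb_hi[2]):
                    break

                # --- locate region and material
                reg = -1
                m = -1
                for k in range(n_parts):
                    dx = (x - org_c[k, 0]) / org_ax[k, 0]
                    dy = (y - org_c[k, 1]) / org_ax[k, 1]
                    dz = (z - org_c[k, 2]) / org_ax[k, 2]
                    if dx * dx + dy * dy + dz * dz <= 1.0:
                        reg = org_id[k]
                        m = org_mat[k]
                        break
                if m < 0:
                    for k in range(n_bodies):
                        dx = (x - bodies[k, 0]) / bodies[k, 2]
                        dy = (y - bodies[k, 1]) / bodies[k, 3]
                        if (dx * dx + dy * dy <= 1.0
                                and bodies[k, 4] <= z <= bodies[k, 5]):
                            reg = n_org_ids
                            m = body_mat[k]
                            break
                if m < 0:
                    continue  # free air: virtual collision

                mt = mu_tot[m, i0] + (mu_tot[m, i0 + 1] - mu_tot[m, i0]) * f
                state, u = _u01(state)
                if u * mu_m > mt:
                    continue  # virtual collision

                if primary_only:
                    edep[b, reg] += energy
                    break

                mi = mu_inc[m, i0] + (mu_inc[m, i0 + 1] - mu_inc[m, i0]) * f
                state, u = _u01(state)
                if u * mt >= mi:
                    # photoelectric (plus residual coherent lumped in): absorb
                    edep[b, reg] += energy
                    break

                # --- Klein-Nishina incoherent scatter
                kappa = energy / MEC2_KEV
                eps0 = 1.0 / (1.0 + 2.0 * kappa)
                a1 = -np.log(eps0)
                a2 = 0.5 * (1.0 - eps0 * eps0)
                eps = 1.0
                sin2 = 0.0
                for _rej in range(1000):
                    state, r1 = _u01(state)
                    state, r2 = _u01(state)
                    state, r3 = _u01(state)
                    if r1 < a1 / (a1 + a2):
                        eps = eps0 ** (1.0 - r2)
                    else:
                        eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * r2)
                    tt = (1.0 - eps) / (kappa * eps)
                    sin2 = tt * (2.0 - tt)
                    if sin2 < 0.0:
                        sin2 = 0.0
                    if r3 <= 1.0 - eps * sin2 / (1.0 + eps * eps):
                        break
                cos_th = 1.0 - (1.0 - eps) / (kappa * eps)
                edep[b, reg] += energy * (1.0 - eps)
                energy = energy * eps

                # rotate direction by (theta, uniform phi)
                sin_th = np.sqrt(max(0.0, 1.0 - cos_th * cos_th))
                state, u = _u01(state)
                phi = 2.0 * np.pi * u
                cph = np.cos(phi)
                sph = np.sin(phi)
                if abs(uz) < 0.99999999:
                    den = np.sqrt(1.0 - uz * uz)
                    nx = ux * cos_th + sin_th * (ux * uz * cph - uy * sph) / den
                    ny = uy * cos_th + sin_th * (uy * uz * cph + ux * sph) / den
                    nz = uz * cos_th - sin_th * den * cph
                else:
                    nx = sin_th * cph
                    ny = sin_th * sph
                    nz = cos_th if uz > 0.0 else -cos_th
                norm = np.sqrt(nx * nx + ny * ny + nz * nz)
                ux, uy, uz = nx / norm, ny / norm, nz / norm

                if energy < cutoff_keV:
                    edep[b, reg] += energy
                    break

    return edep, emitted
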