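"""Numba kernels for lifetime sweeps and mixture objectives.

These loops are the hot paths of the grid and gradient optimizers; the
science lives in `accounting`/`lifetime`/`mixture`, which these kernels
mirror exactly (shared dissipation table, same drift law, same
decision rule) at compiled speed with common random numbers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._tables import _f_eval

__all__ = ["batch_lifetime_sweep", "mixture_objective_batch", "LOG_EXPM1_CUT"]

# above this, log(expm1(s)) == s to double precision
LOG_EXPM1_CUT = 30.0


@njit(cache=True, fastmath=False)
def _pow_theta(x, theta):
    if theta == 2.0:
        return x * x
    if theta == 1.0:
        return x
    if theta == 0.0:
        return 0.0  # flat-profile convention: the shape factor is 1
    if x == 0.0:
        return 0.0
    return x ** theta


@njit(cache=True, fastmath=False)
def _log_odds(s):
    """log(expm1(s)): log-odds of memory response at load s = beta*E."""
    if s > LOG_EXPM1_CUT:
        return s
    return np.log(np.expm1(s))


@njit(cache=True, fastmath=False)
def batch_lifetime_sweep(
    alphas, betas, omega_hats,            # per-cell strategy arrays
    alpha_max, e_max, theta,
    delta, rel_sd, sqrt_drift, anchored,
    L, z, u,                              # shared randomness (n_ens, L)
    table, a_max, inv_da, na, v_lo, v_hi, inv_dv, nv,
    fsat, sat_hi, sat_inv_da, nsat, ftheta,
    tot_out, scored_out, usage_out, kdiss_out,
):
    """Simulate lifetimes for every strategy cell under shared draws.

    Encounter 0 is the primary infection: a naive response that stores
    memory and contributes only its deliberation cost.  Encounters
    1..L-1 are re-infections with the drifting pathogen; each adds
    -cost + p_mem*E - K_diss in expectation.  ``anchored`` keeps the
    drift clock referenced to the primary antigen; otherwise a realized
    naive response re-centers memory and resets the clock.

    Outputs per cell: total lifetime net utility (all L encounters),
    mean net utility per scored re-infection, memory-usage fraction,
    and mean dissipation per re-infection.
    """
    n_cells = alphas.size
    n_ens = z.shape[0]
    zlim = -0.999 / rel_sd if rel_sd > 0.0 else -1e300
    for c in range(n_cells):
        al = alphas[c]
        be = betas[c]
        cost = e_max * omega_hats[c]
        tot = 0.0
        ksum = 0.0
        used_n = 0
        for e in range(n_ens):
            k = 1.0
            for i in range(1, L):
                zz = z[e, i]
                if zz < zlim:
                    zz = zlim
                kk = np.sqrt(k) if sqrt_drift else k
                d = delta * kk * (1.0 + rel_sd * zz)
                if d < 0.0:
                    d = 0.0
                a = al * d
                E = e_max * (al / alpha_max) * np.exp(-_pow_theta(a, theta))
                s = be * E
                pm = -np.expm1(-s)
                if s > 0.0 and theta > 0.0:
                    v = _log_odds(s)
                    K = _f_eval(table, a_max, inv_da, na, v_lo, v_hi,
                                inv_dv, nv, fsat, sat_hi, sat_inv_da,
                                nsat, ftheta, a, v) / be
                else:
                    K = 0.0
                tot += -cost + pm * E - K
                ksum += K
                used = u[e, i] < pm
                if used:
                    used_n += 1
                    k += 1.0
                else:
                    k = 1.0 if not anchored else k + 1.0
        n_scored = n_ens * (L - 1)
        scored_out[c] = tot / n_scored
        tot_out[c] = (tot - n_ens * cost) / n_ens  # add primary cost, per lifetime
        usage_out[c] = used_n / n_scored
        kdiss_out[c] = ksum / n_scored


@njit(cache=True, fastmath=False)
def _shape_factor(etab, etab_inv_da, a):
    """Linear-interpolated exp(-a^theta); etab covers a in [0, 6]."""
    if a >= 6.0:
        return 0.0
    fa = a * etab_inv_da
    i = int(fa)
    t = fa - i
    return (1.0 - t) * etab[i] + t * etab[i + 1]


@njit(cache=True, fastmath=False)
def mixture_objective_batch(
    alpha_vecs,                       # (n_probe, n_m) specificities
    beta_tilde, alpha_max, e_max, theta, omega_hat,
    deltas, rel_sd, sqrt_drift,       # per-antigen divergence
    L, z,                             # shared distance noise (n_ant, L)
    etab, etab_inv_da,                # tabulated exp(-a^theta)
    table, a_max, inv_da, na, v_lo, v_hi, inv_dv, nv,
    fsat, sat_hi, sat_inv_da, nsat, ftheta,
    obj_out,
):
    """Mean net utility per encounter of multi-specificity strategies.

    All memories are stored at the primary infection; recognition uses
    the pooled load beta_tilde * mean(E_i), the responding receptor is
    selected with probability E_i / sum(E_j), and dissipation is the
    selection-weighted single-responder KL.  With memory anchored to
    the primary antigen the expectation is deterministic given the
    distance draws, which are shared across probe vectors.
    """
    n_probe, n_m = alpha_vecs.shape
    n_ant = deltas.size
    zlim = -0.999 / rel_sd if rel_sd > 0.0 else -1e300
    pref = e_max / alpha_max
    e_buf = np.empty(n_m)
    for p in range(n_probe):
        tot = 0.0
        for ant in range(n_ant):
            delta = deltas[ant]
            for i in range(1, L):
                zz = z[ant, i]
                if zz < zlim:
                    zz = zlim
                kk = np.sqrt(1.0 * i) if sqrt_drift else 1.0 * i
                d = delta * kk * (1.0 + rel_sd * zz)
                if d < 0.0:
                    d = 0.0
                esum = 0.0
                e2sum = 0.0
                for m in range(n_m):
                    al = alpha_vecs[p, m]
                    if theta == 0.0:
                        E = pref * al
                    else:
                        E = pref * al * _shape_factor(etab, etab_inv_da,
                                                      al * d)
                    e_buf[m] = E
                    esum += E
                    e2sum += E * E
                ebar = esum / n_m
                s = beta_tilde * ebar
                pm = -np.expm1(-s)
                # dissipation below ~1e-9 cannot register in the
                # objective; skip the per-slot KL work
                if s > 1e-8 and theta > 0.0:
                    v = _log_odds(s)
                    if v > v_hi:
                        v = v_hi
                    if v < v_lo:
                        v = v_lo
                    # v is shared by every slot this round: hoist its
                    # interpolation weights out of the slot loop
                    fv = (v - v_lo) * inv_dv
                    iv = int(fv)
                    if iv > nv - 2:
                        iv = nv - 2
                    tv = fv - iv
                    sel_cut = 1e-6 * esum
                    K = 0.0
                    for m in range(n_m):
                        E = e_buf[m]
                        if E > sel_cut:
                            # slots passing sel_cut have a < 6 < a_max,
                            # so the plain bilinear stencil is valid
                            fa = alpha_vecs[p, m] * d * inv_da + 2.0
                            ia = int(fa)
                            if ia > na - 2:
                                ia = na - 2
                            ta = fa - ia
                            f00 = table[ia, iv]
                            f01 = table[ia, iv + 1]
                            f10 = table[ia + 1, iv]
                            f11 = table[ia + 1, iv + 1]
                            fval = ((1.0 - ta) * ((1.0 - tv) * f00 + tv * f01)
                                    + ta * ((1.0 - tv) * f10 + tv * f11))
                            if fval > 0.0:
                                K += (E / esum) * fval
                    K /= beta_tilde
                    e_resp = e2sum / esum
                else:
                    K = 0.0
                    e_resp = 0.0
                tot += -e_max * omega_hat + pm * e_resp - K
        # primary infections: one naive response per antigen lineage
        tot += -e_max * omega_hat * n_ant
        obj_out[p] = tot / (n_ant * L)
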