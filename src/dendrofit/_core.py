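"""Compiled inner loop of the branched-cable solver.

The voltage step is a theta-method (Crank-Nicolson by default) on the
spatially discretized cable equation, solved directly on the tree with a
Hines-ordered elimination.  Gate variables use the exact exponential
(Rush-Larsen) update, which is unconditionally stable for HH gates and
staggered with the voltage solve in the classic NEURON fashion (gates
advance on rates evaluated at the step-start voltage; the voltage step
then uses the updated gates).  The submembrane Ca2+ pool uses the same
exact update for its linear ODE, staggered after the voltage solve.

Channel indices (fixed order, matching mechanisms.CHANNEL_NAMES):
0 Na_t, 1 Na_p, 2 I_h, 3 I_m, 4 K_p, 5 K_t, 6 Kv3.1, 7 Ca_HVA,
8 Ca_LVA, 9 SK.
"""

import math

import numpy as np
from numba import njit

from .mechanisms import (
    rates_na_t, rates_na_p, rates_ih, rates_im, rates_k_p,
    rates_k_t, rates_kv31, rates_ca_hva, rates_ca_lva, rates_sk,
    FARADAY,
)

N_CHANNELS = 10
IDX_NA_T, IDX_NA_P, IDX_IH, IDX_IM, IDX_K_P = 0, 1, 2, 3, 4
IDX_K_T, IDX_KV31, IDX_CA_HVA, IDX_CA_LVA, IDX_SK = 5, 6, 7, 8, 9

_RTF2 = 1e3 * 8.3145 / (2.0 * FARADAY)  # Nernst prefactor / temperature


@njit(cache=True)
def _rates(c, v, ca):
    """Literature-form rates for channel index c."""
    if c == 0:
        return rates_na_t(v)
    elif c == 1:
        return rates_na_p(v)
    elif c == 2:
        return rates_ih(v)
    elif c == 3:
        return rates_im(v)
    elif c == 4:
        return rates_k_p(v)
    elif c == 5:
        return rates_k_t(v)
    elif c == 6:
        return rates_kv31(v)
    elif c == 7:
        return rates_ca_hva(v)
    elif c == 8:
        return rates_ca_lva(v)
    else:
        return rates_sk(ca)


@njit(cache=True)
def _open_fraction(c, m, h):
    """m^x * h^y for channel index c."""
    if c == 0 or c == 1:  # Na_t, Na_p: m^3 h
        return m * m * m * h
    elif c == 4:  # K_p: m^2 h
        return m * m * h
    elif c == 5:  # K_t: m^4 h
        return m * m * m * m * h
    elif c == 7 or c == 8:  # Ca_HVA, Ca_LVA: m^2 h
        return m * m * h
    else:  # single activation gate
        return m


@njit(cache=True)
def init_gates(v0, ca0, shift, qt, m, h, n):
    for i in range(n):
        for c in range(N_CHANNELS):
            minf, _, hinf, _ = _rates(c, v0[i] - shift[c], ca0[i])
            m[c, i] = minf
            h[c, i] = hinf


@njit(cache=True)
def run(
    # topology / passive
    parent, cm_nF, g_ax, g_leak_uS, e_leak,
    # channels
    gbar_uS, e_chan, shift, qt, sk_tau,
    # calcium
    gamma, tau_decay, depth, ca_inf, area_um2,
    eca_nernst, ca_out, t_celsius,
    # stimulus: currents (nA) per driven compartment, evaluated at t+theta*dt
    stim_comp, stim_I,
    # integration
    dt, n_steps, theta,
    # state (modified in place)
    V, m, h, ca,
    # recording
    rec_comp, rec_every, out_v, out_ca, out_inat,
):
    """Advance the cable ``n_steps``; returns 0 on success, 1 on divergence."""
    n = V.shape[0]
    diag = np.empty(n)
    rhs = np.empty(n)
    G = np.empty(n)
    B = np.empty(n)
    V_old = np.empty(n)
    v_rate = np.empty(n)
    m_old = np.empty((N_CHANNELS, n))
    h_old = np.empty((N_CHANNELS, n))
    rec_ptr = 1
    for step in range(n_steps):
        for i in range(n):
            V_old[i] = V[i]
            v_rate[i] = V[i]
        for c in range(N_CHANNELS):
            for i in range(n):
                m_old[c, i] = m[c, i]
                h_old[c, i] = h[c, i]

        for corrector in range(1):
            # ---- gate update (Rush-Larsen, exact) from the start-of-step
            # state, rates at the step-start voltage (staggered scheme)
            for i in range(n):
                vi = v_rate[i]
                cai = ca[i]
                for c in range(N_CHANNELS):
                    if gbar_uS[c, i] == 0.0:
                        continue
                    minf, mtau, hinf, htau = _rates(c, vi - shift[c], cai)
                    if c == IDX_SK:
                        mtau = sk_tau
                    else:
                        mtau = mtau / qt[c]
                        htau = htau / qt[c]
                    m[c, i] = minf + (m_old[c, i] - minf) * math.exp(-dt / mtau)
                    if htau < 1e8:
                        h[c, i] = hinf + (h_old[c, i] - hinf) * math.exp(-dt / htau)

            # ---- assemble ionic conductance G_i (uS), driving term B_i (nA)
            for i in range(n):
                gi = g_leak_uS[i]
                bi = g_leak_uS[i] * e_leak[i]
                if eca_nernst == 1:
                    eca = _RTF2 * (273.15 + t_celsius) * math.log(ca_out / ca[i])
                else:
                    eca = e_chan[IDX_CA_HVA]
                for c in range(N_CHANNELS):
                    gb = gbar_uS[c, i]
                    if gb == 0.0:
                        continue
                    g = gb * _open_fraction(c, m[c, i], h[c, i])
                    e = eca if (c == IDX_CA_HVA or c == IDX_CA_LVA) else e_chan[c]
                    gi += g
                    bi += g * e
                G[i] = gi
                B[i] = bi
            for s in range(stim_comp.shape[0]):
                B[stim_comp[s]] += stim_I[s, step]

            # ---- theta-method linear system on the tree
            for i in range(n):
                diag[i] = cm_nF[i] / dt + theta * G[i]
                rhs[i] = cm_nF[i] / dt * V_old[i] + B[i] \
                    + (1.0 - theta) * (-G[i] * V_old[i])
            for i in range(1, n):
                p = parent[i]
                diag[i] += theta * g_ax[i]
                diag[p] += theta * g_ax[i]
                if theta < 1.0:
                    ax = g_ax[i] * (V_old[p] - V_old[i])
                    rhs[i] += (1.0 - theta) * ax
                    rhs[p] -= (1.0 - theta) * ax
            # Hines elimination: leaves toward root, forward substitution
            for i in range(n - 1, 0, -1):
                p = parent[i]
                f = (-theta * g_ax[i]) / diag[i]
                diag[p] -= f * (-theta * g_ax[i])
                rhs[p] -= f * rhs[i]
            V[0] = rhs[0] / diag[0]
            for i in range(1, n):
                V[i] = (rhs[i] + theta * g_ax[i] * V[parent[i]]) / diag[i]

        for i in range(n):
            if not (-200.0 < V[i] < 200.0) or V[i] != V[i]:
                return 1

        # ---- Ca2+ pool update from the updated voltage (exact exponential)
        for i in range(n):
            gb_h = gbar_uS[IDX_CA_HVA, i]
            gb_l = gbar_uS[IDX_CA_LVA, i]
            if gb_h == 0.0 and gb_l == 0.0:
                continue
            if eca_nernst == 1:
                eca = _RTF2 * (273.15 + t_celsius) * math.log(ca_out / ca[i])
            else:
                eca = e_chan[IDX_CA_HVA]
            mh = m[IDX_CA_HVA, i]
            hh = h[IDX_CA_HVA, i]
            ml = m[IDX_CA_LVA, i]
            hl = h[IDX_CA_LVA, i]
            i_nA = (gb_h * mh * mh * hh + gb_l * ml * ml * hl) * (V[i] - eca)
            dens = 1e3 * i_nA / area_um2[i]  # pA/um^2
            # d[Ca]/dt = -k*ica - (ca - ca_inf)/tau ; 1 pA/um^2 = 0.1 mA/cm^2
            k = 1e4 * gamma[i] * 0.1 / (2.0 * FARADAY * depth)
            target = ca_inf - tau_decay[i] * k * dens
            ca[i] = target + (ca[i] - target) * math.exp(-dt / tau_decay[i])

        # ---- recording
        if (step + 1) % rec_every == 0:
            for r in range(rec_comp.shape[0]):
                i = rec_comp[r]
                out_v[r, rec_ptr] = V[i]
                out_ca[r, rec_ptr] = ca[i]
                mm = m[IDX_NA_T, i]
                out_inat[r, rec_ptr] = 1e3 * gbar_uS[IDX_NA_T, i] * mm * mm * mm \
                    * h[IDX_NA_T, i] * (V[i] - e_chan[IDX_NA_T]) / area_um2[i]
            rec_ptr += 1
    return 0
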