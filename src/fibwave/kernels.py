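"""Numba integration kernels shared by the single-cell and tissue solvers.

One kernel, :func:`run_segment`, advances ``n`` coupled CRN nodes over a
fixed number of time steps using operator splitting:

* reaction — Rush–Larsen exponential update for the 12 tabulated
  voltage-dependent gates (steady state and decay factor linearly
  interpolated from the precomputed rate table), exponential update for the
  Ca-dependent ``fCa`` and flux-dependent ``u``/``v`` gates, forward Euler
  for the membrane potential and ionic concentrations;
* diffusion — a precomputed 9-point divergence-form stencil
  ``sum_j w_ij (V_j - V_i)``, identically zero on constant fields by
  construction (no-flux boundaries), evaluated on the start-of-step
  potential field.

Performance notes: the rate table is float32 (interpolation error far
below model error); the sharp sigmoids of the SR-release gates are
tabulated; reversal potentials are refreshed every 8 steps (intracellular
concentrations drift on second scales, so the incurred error is orders of
magnitude below the ionic-model error).

Activation (upward crossing of a threshold, with refractory blanking) and
90%-repolarization events are detected in-kernel with sub-step linear
interpolation; the take-off potential used for the 90% level is the
preceding diastolic minimum.  A single cell is simply ``n = 1`` with no
neighbours.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .crn import (CA_O, CA_UP_MAX, CM, CSQN_MAX, F, G_B_CA, G_B_NA, G_CAL,
                  G_K1, G_KR, G_KS, G_NA, G_TO, I_NACA_MAX, I_NAK_MAX,
                  I_PCA_MAX, I_UP_MAX, K_O, K_REL, K_SAT, K_UP, KM_CA,
                  KM_CMDN, KM_CSQN, KM_K_O, KM_NA, KM_NA_I, KM_TRPN, NA_O,
                  RTF, TAU_F_CA, TAU_TR, TAU_U, TRPN_MAX,
                  CMDN_MAX, V_I, V_REL, V_UP)

#: default activation detection: upward crossing of -40 mV, 50 ms blanking
V_THRESH = -40.0
BLANK_MS = 50.0

# sigmoid table for the SR-release gate steady states
_SIG_XMAX = 40.0
_SIG_N = 4096
_SIG_X = np.linspace(-_SIG_XMAX, _SIG_XMAX, _SIG_N)
SIG_TAB = (1.0 / (1.0 + np.exp(-_SIG_X))).astype(np.float32)
_SIG_SCALE = (_SIG_N - 1) / (2.0 * _SIG_XMAX)

_EVV_N = 512


def aux_tables(dt: float):
    """dt-baked auxiliary tables: exp(-dt/tau_v) indexed by u_inf."""
    u = np.linspace(0.0, 1.0, _EVV_N)
    return np.exp(-dt / (1.91 + 2.09 * u)).astype(np.float32)


_aux_cache: dict[float, np.ndarray] = {}


def aux_table(dt: float) -> np.ndarray:
    key = round(float(dt), 9)
    if key not in _aux_cache:
        _aux_cache[key] = aux_tables(key)
    return _aux_cache[key]


@njit(cache=True, fastmath=True, boundscheck=False)
def _sig(x, tab):
    xx = (x + _SIG_XMAX) * _SIG_SCALE
    if xx <= 0.0:
        return tab[0]
    if xx >= _SIG_N - 1:
        return tab[_SIG_N - 1]
    i = int(xx)
    fr = xx - i
    return tab[i] + fr * (tab[i + 1] - tab[i])


@njit(cache=True, fastmath=True, boundscheck=False)
def run_segment(state, pidx, factors, active, nbr, wgt, table, tab_vmin,
                tab_dv, dt, n_steps, t0,
                stim_mask, stim_times, stim_dur, stim_amp,
                rec_idx, rec_every, vm_out, rec_ptr0,
                act_t, rep_t, n_act, n_rep,
                in_ap, peak_v, takeoff_v, last_act,
                v_thresh, blank, sig_tab, evv_tab, quiet_ms):
    """Advance all nodes ``n_steps`` of size ``dt`` starting at time ``t0``.

    Returns ``(status, node, t, rec_ptr)``; status 0 means success, 1 means
    numerical divergence at ``node`` and time ``t``.

    ``quiet_ms > 0`` enables early exit once no node has activated for that
    long and no stimulus is pending: a quiescent monodomain sheet has no
    spontaneous activity, so the remaining trajectory is identically
    resting and need not be integrated.
    """
    n = state.shape[0]
    nrow = table.shape[0]
    inv_dv = 1.0 / tab_dv
    rlf_fca = np.exp(-dt / TAU_F_CA)
    rlf_u = np.exp(-dt / TAU_U)
    vold = np.empty(n, dtype=state.dtype)
    ena = np.empty(n)
    ek = np.empty(n)
    eca = np.empty(n)
    for i in range(n):
        ena[i] = RTF * np.log(NA_O / state[i, 16])
        ek[i] = RTF * np.log(K_O / state[i, 17])
        eca[i] = 0.5 * RTF * np.log(CA_O / state[i, 18])
    si = 0
    n_stim = stim_times.size
    rec_ptr = rec_ptr0
    nrec = rec_idx.size
    max_ev = act_t.shape[1]
    naca_den = (KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O)
    nak_fac = I_NAK_MAX * K_O / (K_O + KM_K_O)
    KM_NAI_32 = KM_NA_I * np.sqrt(KM_NA_I)
    t_last_global = t0

    for step in range(n_steps):
        t = t0 + step * dt
        while si < n_stim and t >= stim_times[si] + stim_dur:
            si += 1
        stim_on = si < n_stim and t >= stim_times[si]
        if (quiet_ms > 0.0 and si >= n_stim
                and t - t_last_global > quiet_ms):
            return 0, -1, t, rec_ptr

        if rec_every > 0 and step % rec_every == 0:
            for k in range(nrec):
                vm_out[k, rec_ptr] = state[rec_idx[k], 0]
            rec_ptr += 1

        refresh_e = (step & 7) == 0
        for i in range(n):
            vold[i] = state[i, 0]

        for i in range(n):
            if not active[i]:
                continue
            v = vold[i]
            lap = 0.0
            if n > 1:
                for q in range(8):
                    jn = nbr[i, q]
                    if jn >= 0:
                        lap += wgt[i, q] * (vold[jn] - v)

            x = (v - tab_vmin) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nrow - 1.001:
                x = nrow - 1.001
            ix = int(x)
            fr = x - ix

            # Rush-Larsen update of the 11 contiguous tabulated gates
            for g in range(11):
                inf = table[ix, 2 * g] + fr * (table[ix + 1, 2 * g] - table[ix, 2 * g])
                rlf = (table[ix, 2 * g + 1]
                       + fr * (table[ix + 1, 2 * g + 1] - table[ix, 2 * g + 1]))
                state[i, 1 + g] = inf + (state[i, 1 + g] - inf) * rlf
            # w gate (state index 15, table pair 22/23)
            inf = table[ix, 22] + fr * (table[ix + 1, 22] - table[ix, 22])
            rlf = table[ix, 23] + fr * (table[ix + 1, 23] - table[ix, 23])
            state[i, 15] = inf + (state[i, 15] - inf) * rlf

            m = state[i, 1]
            h = state[i, 2]
            jg = state[i, 3]
            oa = state[i, 4]
            oi = state[i, 5]
            ua = state[i, 6]
            ui = state[i, 7]
            xr = state[i, 8]
            xs = state[i, 9]
            d = state[i, 10]
            fg = state[i, 11]
            fca = state[i, 12]
            ug = state[i, 13]
            vg = state[i, 14]
            wg = state[i, 15]
            nai = state[i, 16]
            ki = state[i, 17]
            cai = state[i, 18]
            caup = state[i, 19]
            carel = state[i, 20]

            # fCa gate: Ca-dependent steady state, fixed 2 ms time constant
            fca_inf = 0.00035 / (0.00035 + cai)
            fca = fca_inf + (fca - fca_inf) * rlf_fca
            state[i, 12] = fca

            if refresh_e:
                ena[i] = RTF * np.log(NA_O / nai)
                ek[i] = RTF * np.log(K_O / ki)
                eca[i] = 0.5 * RTF * np.log(CA_O / cai)
            ena_i, ek_i, eca_i = ena[i], ek[i], eca[i]
            fac = factors[pidx[i]]

            t24 = table[ix, 24] + fr * (table[ix + 1, 24] - table[ix, 24])
            t25 = table[ix, 25] + fr * (table[ix + 1, 25] - table[ix, 25])
            t26 = table[ix, 26] + fr * (table[ix + 1, 26] - table[ix, 26])
            t27 = table[ix, 27] + fr * (table[ix + 1, 27] - table[ix, 27])
            t28 = table[ix, 28] + fr * (table[ix + 1, 28] - table[ix, 28])
            t29 = table[ix, 29] + fr * (table[ix + 1, 29] - table[ix, 29])

            ina = fac[0] * G_NA * m * m * m * h * jg * (v - ena_i)
            ik1 = fac[4] * G_K1 * (v - ek_i) * t24
            ito = fac[1] * G_TO * oa * oa * oa * oi * (v - ek_i)
            ikur = fac[3] * t25 * ua * ua * ua * ui * (v - ek_i)
            ikr = fac[5] * G_KR * xr * (v - ek_i) * t26
            iks = fac[6] * G_KS * xs * xs * (v - ek_i)
            ical = fac[2] * G_CAL * d * fg * fca * (v - 65.0)
            nai32 = nai * np.sqrt(nai)
            inak = fac[8] * nak_fac * t27 * nai32 / (nai32 + KM_NAI_32)
            inaca = (fac[9] * I_NACA_MAX
                     * (t28 * nai * nai * nai * CA_O - t29 * NA_O * NA_O * NA_O * cai)
                     / (naca_den * (1.0 + K_SAT * t29)))
            ibna = fac[11] * G_B_NA * (v - ena_i)
            ibca = fac[12] * G_B_CA * (v - eca_i)
            ipca = fac[10] * I_PCA_MAX * cai / (0.0005 + cai)

            irel = K_REL * ug * ug * vg * wg * (carel - cai)
            itr = (caup - carel) * (1.0 / TAU_TR)
            iup = fac[7] * I_UP_MAX * cai / (cai + K_UP)
            iupleak = fac[7] * (I_UP_MAX / CA_UP_MAX) * caup

            # SR release gates driven by the Ca flux signal Fn
            fn = (1e-12 * V_REL * irel
                  - 5e-13 / F * (0.5 * ical * CM - 0.2 * inaca * CM))
            u_inf = _sig((fn - 3.4175e-13) / 13.67e-16, sig_tab)
            state[i, 13] = u_inf + (ug - u_inf) * rlf_u
            v_inf = 1.0 - _sig((fn - 6.835e-14) / 13.67e-16, sig_tab)
            iu = int(u_inf * (_EVV_N - 1))
            state[i, 14] = v_inf + (vg - v_inf) * evv_tab[iu]

            state[i, 16] = nai + dt * CM * (-3.0 * inak - 3.0 * inaca - ibna - ina) / (F * V_I)
            state[i, 17] = ki + dt * CM * (2.0 * inak - ik1 - ito - ikur - ikr - iks) / (F * V_I)
            b1 = (CM * (2.0 * inaca - ipca - ical - ibca) * (0.5 / (F * V_I))
                  + (V_UP * (iupleak - iup) + irel * V_REL) * (1.0 / V_I))
            ca_t = cai + KM_TRPN
            ca_c = cai + KM_CMDN
            qtc = 1.0 / (ca_t * ca_c)
            qt = ca_c * qtc
            qc = ca_t * qtc
            b2 = (1.0 + TRPN_MAX * KM_TRPN * qt * qt
                  + CMDN_MAX * KM_CMDN * qc * qc)
            state[i, 18] = cai + dt * b1 / b2
            state[i, 19] = caup + dt * (iup - iupleak - itr * (V_REL / V_UP))
            ca_s = carel + KM_CSQN
            ca_s2 = ca_s * ca_s
            state[i, 20] = carel + dt * (itr - irel) * ca_s2 / (
                ca_s2 + CSQN_MAX * KM_CSQN)

            iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca
                    + inaca + inak + ibna + ibca)
            ist = stim_amp if (stim_on and stim_mask[i]) else 0.0
            vnew = v + dt * (-iion + ist + lap)
            if not np.isfinite(vnew) or vnew > 300.0 or vnew < -300.0:
                return 1, i, t, rec_ptr
            state[i, 0] = vnew

            # event detection (take-off potential = preceding diastolic minimum)
            if in_ap[i] == 0:
                if vnew < takeoff_v[i]:
                    takeoff_v[i] = vnew
                if v < v_thresh <= vnew and (t - last_act[i]) > blank:
                    t_act = t + dt * (v_thresh - v) / (vnew - v)
                    if n_act[i] < max_ev:
                        act_t[i, n_act[i]] = t_act
                        n_act[i] += 1
                    last_act[i] = t_act
                    peak_v[i] = vnew
                    in_ap[i] = 1
                    t_last_global = t
            else:
                if vnew > peak_v[i]:
                    peak_v[i] = vnew
                else:
                    v90 = peak_v[i] - 0.9 * (peak_v[i] - takeoff_v[i])
                    if v > v90 >= vnew:
                        t_rep = t + dt * (v - v90) / (v - vnew)
                        if n_rep[i] < max_ev and n_rep[i] < n_act[i]:
                            rep_t[i, n_rep[i]] = t_rep
                            n_rep[i] += 1
                        in_ap[i] = 0
                        takeoff_v[i] = vnew
    return 0, -1, t0 + n_steps * dt, rec_ptr


class DivergenceError(RuntimeError):
    """The integrator produced a non-finite or runaway membrane potential."""


def make_event_buffers(n: int, duration_ms: float):
    """Preallocate event-detection state for ``n`` nodes over ``duration_ms``."""
    max_ev = max(8, int(duration_ms / 80.0) + 4)
    return dict(
        act_t=np.full((n, max_ev), np.nan),
        rep_t=np.full((n, max_ev), np.nan),
        n_act=np.zeros(n, dtype=np.int32),
        n_rep=np.zeros(n, dtype=np.int32),
        in_ap=np.zeros(n, dtype=np.uint8),
        peak_v=np.zeros(n),
        takeoff_v=np.full(n, 1e9),  # running diastolic minimum
        last_act=np.full(n, -1e9),
    )
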