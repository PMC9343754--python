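"""Independent brute-force CRN integrator used as a test oracle.

Deliberately naive: a direct transliteration of the published model
equations, forward Euler for *every* state variable at a very small time
step, no lookup tables, no Rush-Larsen update.  Shares nothing with the
package kernels except the model definition itself.
"""

import numpy as np

R, T, F = 8.3143, 310.0, 96.4867
RTF = R * T / F
CM = 100.0
NAO, KO, CAO = 140.0, 5.4, 1.8
VI, VUP, VREL = 13668.0, 1109.52, 96.48
SIGMA = (np.exp(NAO / 67.3) - 1.0) / 7.0

STATE0 = dict(V=-81.18, m=2.908e-3, h=9.649e-1, j=9.775e-1, oa=3.043e-2,
              oi=9.992e-1, ua=4.966e-3, ui=9.986e-1, xr=3.296e-5,
              xs=1.869e-2, d=1.367e-4, f=9.996e-1, fca=7.755e-1, u=0.0,
              v=1.0, w=9.992e-1, nai=11.17, ki=139.0, cai=1.013e-4,
              caup=1.488, carel=1.488)


def _lim(num, den, limit):
    return limit if abs(den) < 1e-12 else num / den


def derivatives(s, factors, ist=0.0):
    """Time derivatives of all 21 CRN state variables.

    ``factors`` maps current name -> multiplicative factor (missing -> 1).
    """
    fac = lambda c: factors.get(c, 1.0)
    V = s["V"]
    ena = RTF * np.log(NAO / s["nai"])
    ek = RTF * np.log(KO / s["ki"])
    eca = 0.5 * RTF * np.log(CAO / s["cai"])

    ina = fac("I_Na") * 7.8 * s["m"] ** 3 * s["h"] * s["j"] * (V - ena)
    ik1 = fac("I_K1") * 0.09 * (V - ek) / (1 + np.exp(0.07 * (V + 80)))
    ito = fac("I_to") * 0.1652 * s["oa"] ** 3 * s["oi"] * (V - ek)
    gkur = 0.005 + 0.05 / (1 + np.exp(-(V - 15) / 13))
    ikur = fac("I_Kur") * gkur * s["ua"] ** 3 * s["ui"] * (V - ek)
    ikr = fac("I_Kr") * 0.029411765 * s["xr"] * (V - ek) / (1 + np.exp((V + 15) / 22.4))
    iks = fac("I_Ks") * 0.12941176 * s["xs"] ** 2 * (V - ek)
    ical = fac("I_CaL") * 0.12375 * s["d"] * s["f"] * s["fca"] * (V - 65.0)
    fnak = 1 / (1 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0365 * SIGMA * np.exp(-V / RTF))
    inak = fac("I_NaK") * 0.59933874 * fnak / (1 + (10.0 / s["nai"]) ** 1.5) * KO / (KO + 1.5)
    inaca = fac("I_NaCa") * 1600.0 * (
        np.exp(0.35 * V / RTF) * s["nai"] ** 3 * CAO
        - np.exp(-0.65 * V / RTF) * NAO ** 3 * s["cai"]) / (
        (87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1 + 0.1 * np.exp(-0.65 * V / RTF)))
    ibna = fac("I_bNa") * 0.0006744375 * (V - ena)
    ibca = fac("I_bCa") * 0.001131 * (V - eca)
    ipca = fac("I_pCa") * 0.275 * s["cai"] / (0.0005 + s["cai"])
    irel = 30.0 * s["u"] ** 2 * s["v"] * s["w"] * (s["carel"] - s["cai"])
    itr = (s["caup"] - s["carel"]) / 180.0
    iup = fac("I_Caup") * 0.005 / (1 + 0.00092 / s["cai"])
    iupleak = fac("I_Caup") * 0.005 * s["caup"] / 15.0

    d = {}
    iion = ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inaca + inak + ibna + ibca
    d["V"] = -iion + ist

    # gate rates
    am = _lim(0.32 * (V + 47.13), 1 - np.exp(-0.1 * (V + 47.13)), 3.2)
    bm = 0.08 * np.exp(-V / 11)
    if V < -40:
        ah = 0.135 * np.exp(-(V + 80) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = ((-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1 + np.exp(0.311 * (V + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * V) / (1 + np.exp(-0.1378 * (V + 40.14)))
    else:
        ah = 0.0
        bh = 1 / (0.13 * (1 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1 + np.exp(-0.1 * (V + 32)))
    d["m"] = am * (1 - s["m"]) - bm * s["m"]
    d["h"] = ah * (1 - s["h"]) - bh * s["h"]
    d["j"] = aj * (1 - s["j"]) - bj * s["j"]

    a = 0.65 / (np.exp(-(V + 10) / 8.5) + np.exp(-(V - 30) / 59.0))
    b = 0.65 / (2.5 + np.exp((V + 82) / 17.0))
    oainf = 1 / (1 + np.exp(-(V + 20.47) / 17.54))
    d["oa"] = (oainf - s["oa"]) * 3.0 * (a + b)
    a = 1 / (18.53 + np.exp((V + 113.7) / 10.95))
    b = 1 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    oiinf = 1 / (1 + np.exp((V + 43.1) / 5.3))
    d["oi"] = (oiinf - s["oi"]) * 3.0 * (a + b)
    a = 0.65 / (np.exp(-(V + 10) / 8.5) + np.exp(-(V - 30) / 59.0))
    b = 0.65 / (2.5 + np.exp((V + 82) / 17.0))
    uainf = 1 / (1 + np.exp(-(V + 30.3) / 9.6))
    d["ua"] = (uainf - s["ua"]) * 3.0 * (a + b)
    a = 1 / (21 + np.exp(-(V - 185) / 28))
    b = np.exp((V - 158) / 16)
    uiinf = 1 / (1 + np.exp((V - 99.45) / 27.48))
    d["ui"] = (uiinf - s["ui"]) * 3.0 * (a + b)

    a = _lim(0.0003 * (V + 14.1), 1 - np.exp(-(V + 14.1) / 5), 0.0015)
    b = _lim(7.3898e-5 * (V - 3.3328), np.exp((V - 3.3328) / 5.1237) - 1,
             7.3898e-5 * 5.1237)
    xrinf = 1 / (1 + np.exp(-(V + 14.1) / 6.5))
    d["xr"] = (xrinf - s["xr"]) * (a + b)
    a = _lim(4e-5 * (V - 19.9), 1 - np.exp(-(V - 19.9) / 17), 4e-5 * 17)
    b = _lim(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9) - 1, 3.5e-5 * 9)
    xsinf = 1 / np.sqrt(1 + np.exp(-(V - 19.9) / 12.7))
    d["xs"] = (xsinf - s["xs"]) * 2.0 * (a + b)

    e = np.exp(-(V + 10) / 6.24)
    taud = _lim(1 - e, 0.035 * (V + 10) * (1 + e), 1 / (6.24 * 0.035 * 2))
    dinf = 1 / (1 + np.exp(-(V + 10) / 8))
    d["d"] = (dinf - s["d"]) / taud
    tauf = 9 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10) ** 2) + 0.02)
    finf = 1 / (1 + np.exp((V + 28) / 6.9))
    d["f"] = (finf - s["f"]) / tauf
    fcainf = 1 / (1 + s["cai"] / 0.00035)
    d["fca"] = (fcainf - s["fca"]) / 2.0

    fn = 1e-12 * VREL * irel - 5e-13 / F * (0.5 * ical * CM - 0.2 * inaca * CM)
    uinf = 1 / (1 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    d["u"] = (uinf - s["u"]) / 8.0
    tauv = 1.91 + 2.09 / (1 + np.exp(-(fn - 3.4175e-13) / 13.67e-16))
    vinf = 1 - 1 / (1 + np.exp(-(fn - 6.835e-14) / 13.67e-16))
    d["v"] = (vinf - s["v"]) / tauv
    e = np.exp(-(V - 7.9) / 5)
    tauw = _lim(6.0 * (1 - e), (1 + 0.3 * e) * (V - 7.9), 6.0 / (5 * 1.3))
    winf = 1 - 1 / (1 + np.exp(-(V - 40) / 17))
    d["w"] = (winf - s["w"]) / tauw

    d["nai"] = CM * (-3 * inak - 3 * inaca - ibna - ina) / (F * VI)
    d["ki"] = CM * (2 * inak - ik1 - ito - ikur - ikr - iks) / (F * VI)
    b1 = (CM * (2 * inaca - ipca - ical - ibca) / (2 * F * VI)
          + (VUP * (iupleak - iup) + irel * VREL) / VI)
    b2 = (1 + 0.070 * 0.0005 / (s["cai"] + 0.0005) ** 2
          + 0.050 * 0.00238 / (s["cai"] + 0.00238) ** 2)
    d["cai"] = b1 / b2
    d["caup"] = iup - iupleak - itr * VREL / VUP
    d["carel"] = (itr - irel) / (1 + 10.0 * 0.8 / (s["carel"] + 0.8) ** 2)
    return d


def integrate(factors=None, duration=600.0, dt=0.005, stim_times=(0.0,),
              stim_amp=20.0, stim_dur=2.0, sample_ms=0.1, state=None):
    """Forward-Euler integration; returns (t, V) sampled every ``sample_ms``
    and the final state dict."""
    factors = dict(factors or {})
    s = dict(STATE0 if state is None else state)
    n = int(round(duration / dt))
    every = int(round(sample_ms / dt))
    ts, vs = [], []
    stim_times = np.asarray(stim_times, dtype=float)
    for k in range(n):
        t = k * dt
        if k % every == 0:
            ts.append(t)
            vs.append(s["V"])
        ist = stim_amp if np.any((t >= stim_times) & (t < stim_times + stim_dur)) else 0.0
        d = derivatives(s, factors, ist)
        for key, dv in d.items():
            s[key] += dt * dv
    return np.asarray(ts), np.asarray(vs), s
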