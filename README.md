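# fibwave

**Genotype-specific atrial fibrillation simulation at desk scale.**

Atrial fibrillation (AF) therapy — catheter ablation and antiarrhythmic
drugs — works differently in carriers of *PITX2* risk variants than in
wild-type patients. `fibwave` is a compact in-silico laboratory for
studying that interaction: it couples the Courtemanche–Ramirez–Nattel
(CRN) human atrial myocyte model to a 2D anisotropic monodomain sheet,
generates seeded synthetic left-atrium-like substrates (labeled pulmonary
veins, correlated bipolar-voltage maps, voltage-driven fibrosis, fiber
fields), induces AF by clinical-style ramp pacing, applies virtual
interventions — circumferential PV isolation (CPVI), high-dominant-
frequency-site ablation (DFA), and drug presets — and quantifies the
resulting wave dynamics.

It is intended for computational electrophysiologists and method
developers who need a fully scripted, reproducible AF pipeline that runs
on one CPU in minutes, not a patient-specific clinical model.

## The model in brief

* **Cell** — CRN dynamics; every condition is a multiplicative
  ion-current scaling preset. AF remodeling: I_Na ×0.90, I_to ×0.30,
  I_CaL ×0.30, I_Kur ×0.50, I_Caup ×0.80, I_K1 ×2.10. *PITX2*⁺/⁻
  deficiency: I_K1 ×0.75, I_Kr ×2.0. Presets compose multiplicatively —
  the *PITX2* AF baseline has I_K1 ×(2.10·0.75) = ×1.575 (+58%).
  Fibrotic myocytes: I_K1 ×0.5, I_CaL ×0.5, I_Na ×0.6 plus halved
  coupling. Drugs are per-dose YAML factor tables.
* **Tissue** — monodomain ∂V/∂t = −I_ion/C_m + ∇·(D∇V) with
  D = D_T I + (D_L−D_T) f fᵀ, 5:1 anisotropy, no-flux boundaries;
  Rush–Larsen + forward-Euler integration with tabulated kinetics; the
  diffusion scale is calibrated per grid so planar CV along fibers is
  0.6 m/s.
* **Protocol** — ramp induction 200→120 ms, 8 beats/stage (11,520 ms),
  then 20,480 ms observation (32 s total); DF and Smax analyzed over
  17–23 s; APD90/CV at CL 600 ms.
* **Metrics** — per-node dominant frequency (Welch, 2.5–20 Hz band),
  maximal APD-restitution slope (Smax; mono-exponential fit, slopes > 1
  favor wave-break), AF cycle length, and an AF / AT / terminated outcome
  classifier (AT or termination = defragmentation).

See `docs/methods.md` for assumptions, parameter tables, numerics and
limitations.

## Worked example

```bash
$ python examples/single_cell_ap.py
wt_sr      APD90 =  288.1 ms
pitx2_sr   APD90 =  255.4 ms
wt_af      APD90 =  140.5 ms
pitx2_af   APD90 =  134.6 ms
```

Each line is the steady-state action potential duration at 90%
repolarization for one genotype/rhythm preset paced at a 600 ms cycle
length. AF remodeling roughly halves APD90 (loss of I_CaL, gain of I_K1);
the *PITX2* modifier shortens it further through the doubled I_Kr — the
direction seen clinically, with the absolute values those of the
unmodified CRN model (see `docs/methods.md` for how they compare with
clinical-platform references).

Other examples, each a few lines with printed, explained output:
`build_substrate.py` (synthetic atrium), `induce_af.py` (ramp induction →
sustained re-entry, mean DF, Smax, AFCL), `virtual_cpvi.py` (ablation
rings and electrical isolation), `drug_effects.py` (drug presets on the
AF baseline).

A thin CLI mirrors the library (`fibwave presets show pitx2_af`,
`fibwave plan`, `fibwave simulate`, `fibwave run`, `fibwave report`).

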