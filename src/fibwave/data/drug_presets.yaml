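# Antiarrhythmic drug ion-current scaling tables.
#
# Each entry maps a dose label to multiplicative factors applied to the CRN
# maximal conductances on top of the genotype AF baseline.  SYNTHETIC
# placeholder values: factor magnitudes are motivated by the drugs' known
# channel-block profiles (amiodarone: broad multi-channel block; dronedarone:
# predominantly I_Kr with I_CaL/I_Na components; flecainide: predominantly
# I_Na with an I_Kr component) but are NOT measured per-dose block fractions.
# Replace this file with experimentally derived tables for quantitative use.
amiodarone:
  provenance: "synthetic placeholder; multi-channel (class III + I/II/IV) block profile"
  doses:
    low:
      dose_label: "5uM"
      factors: {I_Na: 0.85, I_CaL: 0.70, I_Kr: 0.50, I_Ks: 0.80, I_to: 0.90}
    high:
      dose_label: "10uM"
      factors: {I_Na: 0.70, I_CaL: 0.55, I_Kr: 0.30, I_Ks: 0.65, I_to: 0.80, I_Kur: 0.90}
dronedarone:
  provenance: "synthetic placeholder; predominantly I_Kr block with I_CaL/I_Na components"
  doses:
    low:
      dose_label: "3uM"
      factors: {I_Kr: 0.40, I_CaL: 0.75, I_Na: 0.90, I_K1: 0.90}
    high:
      dose_label: "10uM"
      factors: {I_Kr: 0.20, I_CaL: 0.55, I_Na: 0.75, I_K1: 0.80, I_to: 0.85}
flecainide:
  provenance: "synthetic placeholder; predominantly I_Na block with I_Kr component"
  doses:
    low:
      dose_label: "5uM"
      factors: {I_Na: 0.60, I_Kr: 0.80, I_to: 0.90}
    high:
      dose_label: "15uM"
      factors: {I_Na: 0.35, I_Kr: 0.65, I_to: 0.80}
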