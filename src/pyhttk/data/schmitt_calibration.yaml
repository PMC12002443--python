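# Per-tissue affine calibration of the component-based partition model,
# applied in log10 space: log10 Kp_cal = slope * log10 Kp_raw + intercept.
# Defaults are the identity (uncalibrated); edit to apply a regression
# calibration against measured tissue:plasma data.
default: {slope: 1.0, intercept: 0.0}
tissues: {}

# Component-model constants (documented in docs/methods.md)
constants:
  # log10 offset applied to logP for ionized species (logD assumption)
  log_d_ion_offset: -3.7
  # membrane (phospholipid) affinity regression on logP: 10^(a*logP + b)
  membrane_affinity_slope: 0.304
  membrane_affinity_intercept: 0.294
  # multiplicative membrane-affinity factors by charge state
  membrane_factor_cation: 0.5
  membrane_factor_anion: 0.05
  membrane_factor_zwitterion: 0.5
  # plasma protein mass fraction used to infer a protein affinity from fup
  plasma_protein_fraction: 0.075
  # plasma lipid volume fraction for the in vitro/in vivo fup correction
  plasma_lipid_fraction: 0.02
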