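# Ground-truth preset registry for the synthetic generators.
#
# IC50 anchors and 95% CIs are the published assay calibration for
# differentiated HepaRG cells with / without 9 uM CHIR pretreatment; fold
# inductions anchor the CHIR -> CYP calibration curves; the gradient block
# holds the effective diffusion coefficient that reproduces a near-linear
# day-7 profile over the 9 cm channel.  Noise defaults are generator choices
# sized so simulated CI widths are of comparable relative magnitude to the
# published ones.
version: 1
noise:
  viability_sd_pct: 5.0
  ct_sd_cycles: 0.2
  image_noise_frac: 0.02   # sd as a fraction of the rendered dynamic range
gradient:
  D_eff_cm2_s: 1.2444e-5   # effective D: theta = 0.95 at day 7, L = 9 cm
  time_days: 7.0
channel:
  length_cm: 9.0
  diameter_cm: 0.5
  inlet1_uM: 0.0
  inlet2_uM: 9.0
drugs:
  tamoxifen:
    unit: uM
    hill: 2.0
    top: 100.0
    bottom: 0.0
    assay_top_dose: 200.0     # 8 two-fold dilutions in the plate assay
    screen_top_dose: 100.0    # channel screen range 0-100 uM
    ic50:
      untreated: {value: 51.0, ci95: [34.3, 67.7]}
      CHIR_9uM: {value: 35.2, ci95: [25.5, 44.8]}
  isoniazid:
    unit: uM
    hill: 2.0
    top: 100.0
    bottom: 0.0
    assay_top_dose: 200.0
    screen_top_dose: null     # not part of the channel screen
    ic50:
      untreated: {value: 13.3, ci95: [12.5, 14.1]}
      CHIR_9uM: {value: 13.2, ci95: [12.1, 14.3]}
  bromobenzene:
    unit: uM
    hill: 2.0
    top: 100.0
    bottom: 0.0
    assay_top_dose: 50.0
    screen_top_dose: 500.0
    ic50:
      untreated: {value: 12.5, ci95: [9.3, 15.7]}
      CHIR_9uM: {value: 0.8, ci95: [0.4, 1.2]}
  acetaminophen:
    unit: mM
    hill: 2.0
    top: 100.0
    bottom: 0.0
    assay_top_dose: 20.0
    screen_top_dose: 200.0
    ic50:
      untreated: {value: 10.0, ci95: [9.7, 10.3]}
      CHIR_9uM: {value: 4.2, ci95: [3.2, 5.2]}
induction:
  # fold induction anchors (chir_uM: fold); (0, 1) mandatory, intermediate
  # points may be added without re-anchoring
  CYP1A2: {0.0: 1.0, 9.0: 20.0}
  CYP2E1: {0.0: 1.0, 9.0: 5.0}
  CYP3A4: {0.0: 1.0, 9.0: 5.0}
  CYP2B6: {0.0: 1.0, 9.0: 1.0}
qpcr:
  reference_gene: "18S"
  reference_ct: 12.0
  baseline_ct: 25.0          # untreated target-gene Ct
  n_reps: 3
damage:
  slope: 1.0                 # scales EthD-1 signal per unit damage fraction
screen:
  n_sections: 6
  n_doses: 8
  n_reps: 6
image:
  n_rows: 64
  n_cols: 450
  mask_rows: [12, 52]        # in-channel row band
  background: 2000.0
  amplitude: 40000.0
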