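# Synthetic planning-cohort conditions: 21 patients, paired SIB (64.8 Gy boost)
# and standard-dose (50.4 Gy) plans, both in 28 fractions.
cohort:
  n_patients: 21
  seed: 20120901
  n_fractions: 28
  dose_sd_gy: 50.4
  dose_sib_gy: 64.8
  hotspot_factor: 1.03
  penumbra_sigma_mm: 6.0
  out_of_field_floor_gy: 1.5
  noise_rel_sd: 0.01
  bin_width_gy: 0.1
  priors:
    esophagus_length_mm: [220.0, 260.0]
    tumor_length_mm: [40.0, 80.0]
    tumor_center_frac: [0.40, 0.60]
    boost_margin_mm: 5.0
    field_margin_mm: 45.0
    voxel_length_mm: 1.0
    cross_section_cc_per_mm: 0.15
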