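# NTCP model registry.
#
# The two LKB parameter sets are the published values (Wijsman grade>=2 acute;
# Chen late toxicity).  The logistic V50 coefficients below are SYNTHETIC
# placeholders for demonstration and testing only — the published coefficients
# are not part of this repository; transcribe them from the model's source
# publication before any scientific use (set them to null to force an error).
models:
  kwint_g2:
    family: logistic_v50
    endpoint: "grade>=2 acute esophageal toxicity"
    alpha_beta_gy: 10.0
    logistic:
      intercept: -2.0   # synthetic fixture value
      slope: 0.05       # synthetic fixture value
      v50_mode: percent
  kwint_g3:
    family: logistic_v50
    endpoint: "grade>=3 acute esophageal toxicity"
    alpha_beta_gy: 10.0
    logistic:
      intercept: -3.5   # synthetic fixture value
      slope: 0.05       # synthetic fixture value
      v50_mode: percent
  wijsman_g2:
    family: lkb
    endpoint: "grade>=2 acute esophageal toxicity"
    alpha_beta_gy: 10.0
    lkb: {n: 1.04, m: 0.65, td50_gy: 32.84}
  chen_let:
    family: lkb
    endpoint: "late esophageal toxicity"
    alpha_beta_gy: 3.0
    lkb: {n: 0.03, m: 0.03, td50_gy: 76.1}
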