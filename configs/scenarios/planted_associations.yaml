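# Planted outcome-predictor slopes for the association layer
# ("outcome|predictor" -> true beta, in outcome units per predictor unit).
cohort_betas:
  birthweight_g|pl_tau: 250.0       # g per umol/g protein
  weight_1y_g|p32_tau: -18.0        # g per umol/L
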