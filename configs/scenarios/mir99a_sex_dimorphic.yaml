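# Sex-dimorphic expression scenario for the validation cohort.
#
# dCq shifts per "target|group-sex cell" relative to the female-control
# (Con-F) baseline; negative dCq = higher expression.  The magnitudes encode
# the fold patterns the validation layer should recover: e.g. -0.87 dCq for
# a male-vs-female control difference is a 2^0.87 ~ 1.83-fold increase, and
# -0.895 dCq for the intervention females is ~1.86-fold.
cell_effects:
  miR-99a|Con-M: -0.506   # ~1.42-fold vs Con-F
  miR-99a|N3-F: -0.895    # ~1.86-fold vs Con-F
  miR-99a|N3-M: -0.713    # ~1.64-fold vs Con-F
  SLC7A5|Con-M: -0.872    # ~1.83-fold vs Con-F
  SLC7A5|N3-F: -0.722     # ~1.65-fold vs Con-F
  SLC7A5|N3-M: -0.766     # ~1.70-fold vs Con-F
  SLC6A6|N3-F: 0.811      # ~0.57-fold vs Con-F (down in intervention)
  SLC6A6|N3-M: 0.889      # ~0.54-fold vs Con-F
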