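# Example end-to-end run on simulated inputs:
#   placmir run --config configs/pipeline_example.yaml --out pipeline_out
seed: 1
simulate:
  array:
    n_assays: 667
    de_spec: {n: 20, delta: 2.0, cq_window: [18, 30]}
  transcripts:
    n_genes: 10
    length_range: [300, 1000]
    plant_spec:
      - {gene: 0, mirna: sim-miR-99a, mismatches: 0, region: 3UTR}
      - {gene: 1, mirna: sim-miR-99a, mismatches: 1, region: CDS}
      - {gene: 2, mirna: sim-miR-99a, mismatches: 2, region: 3UTR}
  cohort:
    n_pairs: 41
screen: {}
seedmatch: {max_mismatch: 2}
enrich:
  regulated: [gene001, gene002, gene003]
quant: {}
associate:
  models:
    - {outcome: birthweight_g, predictor: pl_tau}
    - {outcome: weight_1y_g, predictor: p32_tau, postnatal: true}
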