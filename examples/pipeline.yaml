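# Two simulated discovery-style cohorts plus an imbalanced replication
# cohort fitted with Firth regression; COPD plus one continuous outcome.
cohorts:
  - label: DISC_A
    simulate: {n: 5000}
  - label: DISC_B
    simulate: {n: 2500, fh_prevalence: 0.17}
  - label: REPL_IMB
    estimator: firth
    simulate:
      n: 6000
      case_control_sampling: [1713, 147]
outcomes: [copd_case, sgrq_total]
fh_mode: copdgene_full
n_pcs: 5
seed: 42
mediation_B: 200
out_dir: famprs_out
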