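# Small end-to-end pipeline configuration.
# Every stage is deterministic given `seed`; rerunning with the same
# config reproduces all outputs byte for byte.
seed: 1

simulate:
  n_tf: 20                 # transcription factors in the ground-truth network
  mean_out_degree: 2.0
  activation_fraction: 0.7
  noise_sd: 0.15           # technical (observation) noise sd
  prior_false_negative_rate: 0.2
  prior_false_positive_rate: 0.2
  n_multiomic_genes: 800   # genome-wide gene count for the accessibility stage
  n_off_target_peaks: 50

design:
  timepoints: [0h, 24h, 72h]
  conditions: [control, treated]
  replicates: 3
  alpha: 0.05
  accessibility_rho: 0.45

inference:
  n_trees: 100
  candidates_per_split: sqrt
  min_samples_leaf: 1

consensus:
  B: 20
  tau: 0.5

overlay:
  mode: intersect          # or: annotate

contextualize:
  strict_roots: true       # orphaned nodes are re-evaluated, not grandfathered
  unsigned_justifies: true # edges of unknown sign justify either direction

pool_adjacent: true        # pool each time point with its predecessor
promoter_window: 2000      # bp around the TSS for peak-to-gene assignment

thresholds:
  de_alpha: 0.05
  acc_fdr: 0.05
  fold_threshold: 2.0

top_k_hubs: 10
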