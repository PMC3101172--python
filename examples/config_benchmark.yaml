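# Full pipeline run: simulate planted-history families, screen them with
# bootstrapped NJ, classify the trees, and report label recovery.
#
#   mosaicscreen run -c examples/config_benchmark.yaml
#
# Threshold provenance (all overridable):
#   screen.stage1_evalue_max  1e-5   first-step gate: green-plant hit strictly below
#   screen.stage2_evalue_max  1e-3   second-step homologue fetch, strict
#   screen.max_hits           500    homologue cap per gene
#   classify.min_bootstrap    70     monophyly threshold on bootstrap trees
#   classify.min_posterior    0.9    monophyly threshold on posterior trees

mode: benchmark
seed: 1
out_dir: runs/benchmark

simulate:
  n_per_label: 5
  internal_branch: 0.5   # substitutions/site on backbone edges
  tip_branch_mean: 0.2   # mean pendant length (exponential)
  seq_length: 500        # alignment columns before indels
  indel_rate: 0.1        # insertion events per positive-length branch

screen:
  n_bootstrap: 100
  col_max_gap_frac: 0.5
  taxon_max_gap_frac: 0.75
  distance_model: poisson

classify:
  min_bootstrap: 70
  min_posterior: 0.9
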