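# Full-pipeline run on the default synthetic stress compendium.
# riboclass all --config examples/run.yaml
seed: 1
output_dir: out/run1
k: null            # select from k_candidates by consensus stability
k_candidates: [3, 4, 5]
n_runs: 50
alpha: null        # default: Bonferroni 0.05 / n_experiments
synthetic:
  n_experiments: 49
  class_sizes: {0: 47, 1: 132, 2: 68, 3: 32, 4: 14}
  effect_size: 1.5
  noise_sd: 0.5
  promoters:
    2: {n_promoters: 60, plant_fraction: 0.7, position_mean: -70, position_sd: 15}
    3: {n_promoters: 30, plant_fraction: 0.1, position_mean: -70, position_sd: 15}
network:
  threshold: 0.75
  mode: on_r2
blocks:
  threshold: 0.8
  mode: on_r
envelope:
  n_resamples: 200
motifs:
  - {name: site_II, iupac: ARGCCCA, center: -70, halfwidth: 25}
  - {name: telo_box, iupac: AAACCCWA, center: -30, halfwidth: 25}
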