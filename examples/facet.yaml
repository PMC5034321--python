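# Full study replica on a synthetic facet-contrast cohort
# (34 buccal T2 vs 49 lingual T3 specimens, 4 sub-surfaces each).
mode: synthetic
cohort:
  template: facet_contrast
  grid: 64            # pixels per 10 µm analysis window
  n_subsurfaces: 4
datasets: [facet_autumn]
seed: 11
out_dir: results/facet
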