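# Study-scale demonstration run: 386 progeny from 42 parents, 850 SNPs
# before QC, grain yield over three harvests in six blocks.
simulation:
  n_parents: 42
  n_progeny: 386
  n_markers: 850
  n_qtl_sim: 400
  n_harvests: 3
  h2_per_harvest: [0.18, 0.19, 0.20]
  n_blocks: 6
  seed: 7
k_folds: 10
seed: 7
output_dir: demo_run
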