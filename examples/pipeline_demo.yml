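# Synthetic end-to-end demo configuration for `workbench run`.
# For real inputs: set `synthetic: false` and list per-system files under
# `systems`, e.g.
#   systems:
#     - {label: Carbo, topology: carbo.pdb, coords: carbo.dcd, stride: 10}
outdir: scratch/pipeline_demo
seed: 0
synthetic: true
demo_matrix_frames: 2000
demo_traj_frames: 300
stages: [hbonds, tree, clustering, kinetics, stacking]
stride: 10
hbond_distance: 3.2
hbond_angle: 120.0
pair_mode: protein_any
prune_to_levels: 2
minkowski_p: 2.0
theta: 1
fes_bins: 40
temperature: 300.0
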