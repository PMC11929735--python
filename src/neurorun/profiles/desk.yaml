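# Desk-scale profile: the reduced model and training sizes this package
# actually runs.  All values are overridable on the command line.
profile: desk
model: builtin:desk
condition: active
seed: 0
duration: 8.0
sim:
  dt: 0.003
  substeps: 16          # control period 48 ms (~20.8 Hz)
  joint_damping: 1.0
  limit_stiffness: 60.0
  limit_damping: 2.0
contact:
  k_n: 100000.0
  c_n: 1.0
  mu: 0.9
  v_reg: 0.05
gait:
  speed: 3.33
  cadence: 1.35
  pelvis_height: 0.93
reward: {}
ppo:
  n_envs: 8
  episode_length: 2.0
  samples_per_update: 2048
  n_updates: 300
  minibatch_size: 256
  epochs: 4
  learning_rate: 0.0003
  hidden: [64, 64]
retrain_updates: 150
output_dir: runs
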