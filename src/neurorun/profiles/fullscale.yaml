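# Documentation-only full-scale profile (25 joint DOF + 150 muscles; 200
# environments, 80,000 samples per update, 80,000 reference updates and
# 40,000 retraining updates; 20 s evaluation rollouts).  Running this
# profile end to end is a multi-day computation and is not the shipped
# workflow.
profile: fullscale
model: builtin:fullscale
condition: active
seed: 0
duration: 20.0
sim:
  dt: 0.001
  substeps: 33
contact:
  k_n: 500000.0
  c_n: 1.0
  mu: 0.9
  v_reg: 0.05
gait:
  speed: 3.33       # 12 km/h
  cadence: 1.35
ppo:
  n_envs: 200
  episode_length: 4.0
  samples_per_update: 80000
  n_updates: 80000
  minibatch_size: 250
  hidden: [256, 256]
retrain_updates: 40000
output_dir: runs
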