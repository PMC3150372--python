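# Reference configuration: a 25-particle geometric-neighbourhood swarm whose
# steady state is a compact rotating mill (max pairwise distance ~1.2 arena
# units, well inside the smallest grid radius), reached from random initial
# conditions within a few hundred timesteps for essentially every seed.
schema_version: 1
model:
  neighbourhood_scheme: geometric
  include_alignment: true
  include_attraction: true
  infer_update_rate: false
params:
  attraction_weight: 0.9
  alignment_weight: 0.15
  interaction_radius: 5.0
  blind_angle: 1.0471975511965976   # pi/3, total width of the rear blind cone
  noise_sd: 0.1
  speed: 0.3
  update_prob: 1.0
  arena_size: 10.0
grid:
  axes:
    attraction_weight: {lower: 0.0, upper: 1.2, points: 9}
    alignment_weight: {lower: 0.0, upper: 0.6, points: 9}
    interaction_radius: {lower: 2.5, upper: 6.0, points: 8}
    blind_angle: {lower: 0.0, upper: 3.141592653589793, points: 7}
    noise_sd: {lower: 0.05, upper: 0.45, points: 9}
run:
  n_particles: 25
  n_steps: 10
  n_seeds: 5
  seed: 0
  burn_in:
    threshold: 0.8
    window: 20
    max_steps: 4000
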