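# swarminfer

Bayesian inference of interaction rules in collective animal motion.

Groups of fish, birds or insects produce strikingly similar collective
patterns — swarms, rotating mills, polarized migration — from very
different individual-level rules, so observing the group pattern alone
cannot identify how the animals actually interact. `swarminfer` is for
behavioural ecologists and modellers who have (or simulate) fine-scale
trajectories of every individual and want to ask: *which* interaction rules,
at *what* strengths, and with *how much* certainty?

The package couples:

* a two-dimensional **self-propelled particle (SPP) simulator** — constant
  speed, periodic arena, attraction to the neighbours' centre of mass,
  alignment with their headings, a rear blind angle, metric (fixed radius)
  or topological (k nearest) neighbourhoods, wrapped-Gaussian heading noise,
  and an optional per-step update probability p;
* an **exact grid-based Bayesian engine** over the model parameters
  θ = (w_attract, w_align, r or k, blind angle, σ [, p]).

Because speed is constant, only heading changes carry information, and the
Markov property makes the likelihood a product over particles i and steps t
of wrapped-Gaussian terms

    L(D | θ) = ∏_{t,i} WG( θ'_{t,i} − θ̂_{t,i}(θ) ; σ ),

with θ̂ the deterministic force prediction (a two-component mixture replaces
each term when p < 1). Posteriors are updated sequentially and exactly,
p(θ | D₁, D₂) ∝ p(D₂ | θ) p(θ | D₁); remaining uncertainty is tracked with
the Shannon entropy H = −Σ p log p of the joint grid posterior; and rule
variants M₁, M₂ (alignment vs none, metric vs topological) are compared
through the marginal-likelihood Bayes factor
log BF = log p(D | M₁) − log p(D | M₂), whose parameter integration
penalizes needless complexity automatically. See `docs/methods.md` for the
full model and the numerical choices.

## Worked example

Simulate ten recorded timesteps of the bundled reference swarm (25
particles, attraction 0.9, alignment 0.15, radius 5, blind angle π/3 ≈ 1.047,
σ = 0.1) and re-infer the rules from the trajectory alone:

```python
import numpy as np
from swarminfer import (Posterior, make_grid, marginal_summary, entropy,
                        simulate, step_observations, update_posterior)
from swarminfer.config import reference_config

cfg = reference_config()
spec, params, grid = cfg.model_spec(), cfg.model_params(), cfg.parameter_grid()

traj = simulate(25, params, spec, n_steps=10, rng=1)
post = Posterior.from_prior(grid)
for obs in step_observations(traj):          # one Bayesian update per step
    post = update_posterior(post, obs, spec, params)
    print(f"step {post.n_steps_assimilated:2d}  entropy {entropy(post):6.3f}")

for name in grid.names:
    mean, sd, _ = marginal_summary(post, name)
    print(f"{name:20s} {mean:7.4f} +- {sd:.4f}")
```

Output:

```
step  1  entropy  1.830
step  2  entropy  0.998
step  3  entropy  0.316
...
step 10  entropy  0.256
attraction_weight     0.9000 +- 0.0007
alignment_weight      0.1447 +- 0.0192
interaction_radius    5.0000 +- 0.0000
blind_angle           1.0472 +- 0.0000
noise_sd              0.1000 +- 0.0000
```

The joint entropy falls from log(40824) ≈ 10.6 nats at the uniform prior to
~0.3 after ten steps, and every marginal mean lands on the generating value:
250 individual heading changes from a disordered configuration pin down all
five parameters. Running the same analysis on steady-state mill data instead
leaves the interaction-radius marginal at its prior (the mill is more
compact than any candidate radius, so the data cannot say where interaction
ceases) while attraction and alignment still converge.

The same pipelines are scriptable from the shell:

```bash
swarminfer simulate --seed 1 --out runs/sim          # reference config
swarminfer infer --config runs/sim/config.yaml \
    --trajectory runs/sim/trajectory.csv --out runs/post
swarminfer scenario convergence --seed 0 --out runs/conv --plots
```

## Layout

```
src/swarminfer/
  model.py        SPP dynamics, domain types, milling order parameter
  likelihood.py   wrapped-Gaussian transition likelihood (+ p<1 mixture)
  bayes.py        parameter grids, exact sequential updating, entropy, BFs
  experiments.py  seeded scenario pipelines -> tabular reports
  studies.py      desk-scale reference studies and their headline metrics
  io.py           trajectory CSV round-trip with validated metadata
  config.py       strict YAML run configs (pydantic)
  cli.py          `swarminfer` command line
  data/reference.yaml   the reference parameter set and default grid
```
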