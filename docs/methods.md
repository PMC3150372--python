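# Methods

## The model

`swarminfer` simulates a two-dimensional self-propelled particle (SPP)
swarm and infers its interaction rules from trajectories. Each of N
particles has a position x_i in a periodic square arena [0, L)^2 and a
heading angle theta_i. One timestep proceeds synchronously:

1. **Neighbourhood.** Particle i interacts with the particles it can see.
   A rear blind cone of total width `blind_angle` hides particle j whenever
   the unsigned bearing |angle(d_ij) - theta_i| exceeds
   pi - blind_angle / 2, where d_ij is the minimum-image displacement from
   i to j. In the *geometric* scheme the neighbourhood is all visible
   particles within `interaction_radius`; in the *topological* scheme it is
   the `neighbour_count` nearest visible particles (distance ties broken by
   particle index).
2. **Social forces.** The alignment vector A_i is the normalized sum of the
   neighbours' heading unit vectors; the attraction vector C_i is the unit
   vector from i to the neighbours' centre of mass, computed in
   minimum-image coordinates relative to i. Either is null for an empty
   neighbourhood or an exactly cancelling sum.
3. **Direction update.** With probability `update_prob` (p) the particle
   adopts the direction of  u_i + w_a * C_i + w_l * A_i,  where u_i is its
   current heading unit vector; the inertial weight is fixed at one, which
   costs no generality because the sum is renormalized. With probability
   1 - p it keeps its previous heading. A null force sum leaves the heading
   unchanged (inertia-only continuation). In both branches a wrapped-
   Gaussian angle with SD `noise_sd` (sigma) is added.
4. **Position update.** The particle advances by the constant `speed` along
   its *new* heading, wrapped into the box.

Synchrony matters: every particle reads the state at t and writes t+1, so
the one-step transition density factorizes over particles and the
trajectory likelihood is exact, not approximate.

For the reference parameters below the swarm converges from random initial
conditions to a rotating mill — particles orbiting a common centre, with
clockwise and anti-clockwise movers coexisting. The mill is detected by the
unsigned order parameter `milling_order`: the mean over particles of |sin|
of the angle between the heading and the radial direction from the periodic
group centroid (1 = perfectly tangential in either sense, 2/pi under random
headings). The steady state is declared when the order stays above 0.8 for
20 consecutive steps (both configurable).

## Likelihood

Speed is constant, so positions carry no information beyond the headings
and only direction changes are scored. The per-particle term is the
wrapped-Gaussian density WG(theta'_i - theta_pred,i ; sigma) of the
observed new heading about the deterministic force prediction; the log
likelihood of a trajectory is the sum over particles and steps. When p < 1
the exact transition density is the two-component mixture

    p * WG(theta' - theta_pred; sigma) + (1 - p) * WG(theta' - theta; sigma),

i.e. updated-and-noised versus retained-and-noised. The wrapped Gaussian is
evaluated by truncating the sum over 2*pi translates at
K = max(3, ceil(4 sigma / 2 pi) + 2) terms; for sigma > 2*pi it is
numerically uniform and short-circuited to 1/(2*pi). Quadrature confirms
unit mass within 1e-6 at all tested (sigma, p), including sigma = 10.

Observation noise and behavioural variability are deliberately folded into
the single angular sigma; there is no separate position-noise channel.

## Inference

The posterior lives on the full Cartesian grid of per-parameter sample
values with a uniform prior over documented broad ranges (below). All mass
bookkeeping is in log space with log-sum-exp normalization after every
update. On a grid, sequential Bayesian updating is exact — assimilating
observations one at a time or in one batch yields identical posteriors —
and the accumulated log normalizing constants equal the log marginal
likelihood of everything assimilated, which is what the Bayes factor

    log BF = log p(D | M1) - log p(D | M2)

compares. Both models must have assimilated the identical observations
(enforced). Marginalizing the prior over each model's parameter space gives
the automatic complexity (Occam) penalty: a model with an extra axis
spreads its prior mass thinner, so when the simpler model suffices the BF
favours it, though only weakly for nested models. For nested comparisons
the |log BF| trajectory typically pays most of that penalty in the first
update and then plateaus: once both posteriors concentrate on the shared
truth their posterior predictives coincide, the expected per-step increment
is positive but tiny, and with a handful of trials the seed-averaged curve
fluctuates around the plateau rather than growing visibly.

Remaining uncertainty is summarized by the Shannon entropy of the joint
grid posterior (natural log by default, base configurable; all entropy
comparisons are base-invariant), which runs from log(grid size) at the
uniform prior to 0 at a point mass. Per-parameter summaries are the
mass-weighted marginal mean and SD.

A grid was chosen over MCMC/SMC deliberately: the entropy bookkeeping is
defined on a finite set of sample values, sequential updates are exact with
no tuning, and the problem has at most six free parameters.

## Reference parameter set and priors

The bundled reference set (`swarminfer/data/reference.yaml`) was tuned by
simulation scan so the mill emerges reliably (sustained milling in 8/8 scan
seeds within ~100 steps) and is compact (max pairwise distance ~1.2 length
units, below the smallest grid radius — the property that makes the
interaction radius unidentifiable from mill data):

| parameter            | value  | grid axis (uniform prior)   |
|----------------------|--------|-----------------------------|
| attraction weight    | 0.9    | [0, 1.2], 9 points          |
| alignment weight     | 0.15   | [0, 0.6], 9 points          |
| interaction radius   | 5.0    | [2.5, 6.0], 8 points        |
| blind angle (total)  | pi/3   | [0, pi], 7 points           |
| noise SD (rad)       | 0.1    | [0.05, 0.45], 9 points      |
| speed (per step)     | 0.3    | known, not inferred         |
| arena size           | 10.0   | known, not inferred         |
| particles N          | 25     | —                           |

Arena size and speed are treated as known: in an experiment both are
directly measurable from the recording, and under the constant-speed model
the speed is determined exactly by consecutive positions.

Generating values sit on grid points by design. This makes the inference
problem well-posed — posterior concentration onto the truth is then limited
by the data, not by discretization — and mirrors the usual simulation-based
calibration practice. With off-grid truths every grid point is mildly
misspecified and the posterior compensates through correlated biases
(notably an inflated noise SD); users fitting real data should refine axes
around the posterior mode rather than interpret single-axis biases.

Study-specific axes: the noise study's sigma axis is
{0.3, 1.0, 2.0, 3.0, 3.8, 4.6, 5.4, 6.1, 6.8}, denser where noise is
resolvable and extending beyond 2*pi so the prior covers the regime where
the wrapped Gaussian is indistinguishable from uniform (otherwise the
entropy plateau at the prior could not be observed). The update-rate
study's sigma axis {0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 0.9, 1.25} reaches
high enough to absorb the inflated noise estimate of the constrained
analysis, its alignment axis is [0, 0.45] with 7 points (0.15 on-grid),
and the update-probability axis is {0.25, 0.5, 0.75, 1.0}. The topological
candidate's neighbour-count axis is {2, 6, 10, 14, 18} with a generating
value of 10 (smaller k does not sustain the mill at these parameters).

## What the synthetic data do and do not show

The simulator is the data generator, so all studies are inverse-crime
exercises: the fitted model class contains the generating process. Passing
them shows the estimator is correct, exact and well-calibrated under its
own assumptions — it does not show that real animal groups follow these
rules. Features of real data deliberately absent here: variable speed,
occlusion/missing detections, per-individual parameter heterogeneity,
asynchronous reactions beyond the Bernoulli update model, and
three-dimensional motion.

## Numerical choices and degenerate inputs

* Angles are wrapped to (-pi, pi] (boundary maps to +pi); positions to
  [0, L). Minimum-image displacement components lie in [-L/2, L/2).
* Zero-length force sums and empty neighbourhoods fall back to inertia.
* Topological ties at the k-th distance break by particle index.
* sigma = 0 is legal in simulation (exact zero noise) but the likelihood
  requires sigma > 0; grid noise axes must be strictly positive.
* update_prob = 0 is legal in simulation (frozen-heading limit); grid
  update-probability axes must lie in (0, 1].
* One seeded generator per simulation; per-step draws are consumed in a
  fixed order (update coin flips, then noise), so trajectories are
  bit-reproducible from (config, seed).
* Posterior normalization is asserted to 1e-10 after every update.

## Study sizes and runtimes

The reference studies use N = 25 particles, ten assimilated timesteps and
five independent trials, with the grids above (16–65k points). Individual
posterior updates take well under a second; a full study is seconds to a
few minutes on one CPU, and the complete acceptance run is roughly ten
minutes. Larger grids and longer trajectories scale linearly in grid size,
steps and N^2.

## Known limitations

* Grid inference scales exponentially in the number of free parameters;
  beyond ~6 axes a sampler would be needed (out of scope here).
* The mill/swarm phase boundary is parameter-sensitive; far from the
  reference set the steady state may be a disordered blob or a fragmented
  pair of clusters, and `simulate_to_mill` then reports failure (seeds are
  excluded from steady-state arms with a flag rather than silently).
* The milling order parameter assumes a single cluster; for fragmented
  configurations its value is not meaningful.
* Rotation invariance of the likelihood holds exactly only away from the
  periodic boundary (the box breaks global rotational symmetry).
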