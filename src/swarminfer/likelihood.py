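"""Transition likelihood of observed heading changes.

Because speed is constant, positions are completely determined by the
headings, so the data enter the likelihood only through direction changes.
The process is Markovian and noise is independent across particles, so the
log likelihood of a trajectory is a sum over particles and timesteps.  Each
term is a wrapped-Gaussian density of the difference between the observed
new heading and the deterministic force-predicted heading.

When the per-step update probability p is below one, a particle either
updated (probability p, heading centred on the prediction) or kept its old
heading (probability 1 - p), with noise in both branches.  The exact
transition density is then a two-component wrapped-Gaussian mixture:

    p * WG(theta' - theta_pred; sigma) + (1 - p) * WG(theta' - theta; sigma)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from ._angles import TWO_PI, wrap_angle
from .model import ModelParams, ModelSpec, SwarmState, Trajectory, predicted_directions

__all__ = [
    "StepObservation",
    "wrapped_gaussian_logpdf",
    "step_loglik",
    "trajectory_loglik",
    "step_observations",
]

_LOG_UNIFORM = -math.log(TWO_PI)


@dataclass(frozen=True)
class StepObservation:
    """One observed transition: the prior state and the headings that followed."""

    prior_state: SwarmState
    new_headings: np.ndarray

    def __post_init__(self):
        new = wrap_angle(np.atleast_1d(np.asarray(self.new_headings, dtype=float)))
        if new.shape != (self.prior_state.n_particles,):
            raise ValueError(
                f"new_headings shape {new.shape} does not match "
                f"{self.prior_state.n_particles} particles"
            )
        object.__setattr__(self, "new_headings", new)

    @property
    def n_particles(self) -> int:
        return self.prior_state.n_particles


def _wrap_terms(sigma_max: float) -> int:
    # enough 2*pi translates that the discarded Gaussian tails are negligible
    return max(3, math.ceil(4.0 * sigma_max / TWO_PI) + 2)


def wrapped_gaussian_logpdf(delta, sigma):
    """Log density of the zero-mean wrapped Gaussian on (-pi, pi].

    Broadcasts over ``delta`` and ``sigma``.  The wrap sum over 2*pi
    translates is truncated adaptively; for sigma > 2*pi the density is
    indistinguishable from uniform and is short-circuited to 1/(2*pi).
    Integrates to one over a single period.
    """
    sigma_arr = np.asarray(sigma, dtype=float)
    if np.any(sigma_arr <= 0):
        raise ValueError("sigma must be strictly positive")
    delta_b, sigma_b = np.broadcast_arrays(wrap_angle(delta), sigma_arr)
    sig_eff = np.minimum(sigma_b, TWO_PI)
    k_max = _wrap_terms(float(sig_eff.max()) if sig_eff.size else 1.0)
    ks = TWO_PI * np.arange(-k_max, k_max + 1)
    z = (delta_b[..., None] + ks) / sig_eff[..., None]
    log_wrapped = logsumexp(-0.5 * z**2, axis=-1) - np.log(
        sig_eff * math.sqrt(TWO_PI)
    )
    out = np.where(sigma_b > TWO_PI, _LOG_UNIFORM, log_wrapped)
    return out if out.ndim else float(out)


def step_loglik(obs: StepObservation, params: ModelParams, spec: ModelSpec) -> float:
    """Log probability of one observed transition, summed over particles."""
    if params.noise_sd <= 0:
        raise ValueError("likelihood requires noise_sd > 0")
    pred = predicted_directions(obs.prior_state, params, spec)
    d_pred = wrap_angle(obs.new_headings - pred)
    lp_pred = wrapped_gaussian_logpdf(d_pred, params.noise_sd)
    p = params.update_prob
    if p >= 1.0:
        return float(np.sum(lp_pred))
    d_old = wrap_angle(obs.new_headings - obs.prior_state.headings)
    lp_old = wrapped_gaussian_logpdf(d_old, params.noise_sd)
    if p <= 0.0:  # degenerate mixture: nobody ever updates
        return float(np.sum(lp_old))
    terms = np.logaddexp(math.log(p) + lp_pred, math.log1p(-p) + lp_old)
    return float(np.sum(terms))


def step_observations(traj: Trajectory,
                      t_range: Optional[Tuple[int, int]] = None) -> list:
    """Consecutive-state observations of a trajectory.

    ``t_range = (t0, t1)`` selects the transitions from state t0 up to state
    t1 (inclusive endpoints in trajectory time indices).
    """
    first, last = traj.time_indices
    if t_range is None:
        t_range = (first, last)
    t0, t1 = t_range
    if not (first <= t0 < t1 <= last):
        raise ValueError(
            f"t_range {t_range} outside trajectory span [{first}, {last}] "
            "or shorter than one transition"
        )
    off = -first
    return [
        StepObservation(traj[t + off], traj[t + off + 1].headings)
        for t in range(t0, t1)
    ]


def trajectory_loglik(traj: Trajectory, params: ModelParams, spec: ModelSpec,
                      t_range: Optional[Tuple[int, int]] = None) -> float:
    """Sum of step log likelihoods over consecutive state pairs in ``t_range``."""
    return float(sum(
        step_loglik(obs, params, spec) for obs in step_observations(traj, t_range)
    ))
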