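"""Exact grid-based Bayesian engine.

The posterior over interaction parameters is represented on the full
Cartesian product of per-parameter sample values, with all mass bookkeeping
in log space.  On a grid, sequential updating is exact: assimilating
observations one at a time or in a single batch gives identical posteriors,
and the accumulated log normalizing constants are the log marginal
likelihood of everything assimilated so far, which is what Bayes factors
compare between model variants.

``grid_step_loglik`` evaluates the transition log likelihood of one observed
step at every grid point simultaneously.  The neighbourhood structure
depends only on the (radius or neighbour count, blind angle) axes, so those
combinations are enumerated in an outer loop while the force weights, noise
scale and update probability are fully vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import logsumexp

from ._angles import unit_vectors, wrap_angle, normalize_rows
from .likelihood import StepObservation, wrapped_gaussian_logpdf
from .model import (
    GEOMETRIC,
    ModelParams,
    ModelSpec,
    _topological_mask,
    pairwise_geometry,
    visibility_mask,
)

__all__ = [
    "ParameterGrid",
    "Posterior",
    "make_grid",
    "grid_step_loglik",
    "update_posterior",
    "marginal_summary",
    "entropy",
    "log_bayes_factor",
]

_NORM_TOL = 1e-10


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian product of per-parameter sample values with a prior."""

    axes: Tuple[Tuple[str, np.ndarray], ...]
    prior_log_mass: np.ndarray

    def __post_init__(self):
        axes = tuple((name, np.asarray(v, dtype=float)) for name, v in self.axes)
        for name, values in axes:
            if values.ndim != 1 or values.size < 2:
                raise ValueError(f"axis {name!r} needs >= 2 sample values")
            if np.any(np.diff(values) <= 0):
                raise ValueError(f"axis {name!r} values must be strictly increasing")
        shape = tuple(v.size for _, v in axes)
        prior = np.asarray(self.prior_log_mass, dtype=float)
        if prior.shape != shape:
            raise ValueError(f"prior shape {prior.shape} != grid shape {shape}")
        if abs(logsumexp(prior)) > _NORM_TOL:
            raise ValueError("prior mass must sum to 1")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "prior_log_mass", prior)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    @property
    def shape(self) -> Tuple[int, ...]:
        return tuple(v.size for _, v in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def values(self, name: str) -> np.ndarray:
        for n, v in self.axes:
            if n == name:
                return v
        raise KeyError(f"no axis named {name!r}")

    def axis_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no axis named {name!r}") from None


def make_grid(spec: ModelSpec,
              resolution: Union[int, Dict[str, Union[int, Sequence[float]]]]
              ) -> ParameterGrid:
    """Uniform-prior grid over the free parameters of ``spec``.

    ``resolution`` is either one point count for every axis or a mapping
    from parameter name to a point count (evenly spaced between the spec's
    bounds) or to an explicit sorted list of sample values inside them.
    """
    axes = []
    for name, lo, hi in spec.parameter_axes:
        res = resolution if isinstance(resolution, int) else resolution[name]
        if isinstance(res, (int, np.integer)):
            if res < 2:
                raise ValueError(f"axis {name!r}: need >= 2 points, got {res}")
            values = np.linspace(lo, hi, int(res))
            if name == "neighbour_count":
                values = np.unique(np.rint(values))
                if values.size < 2:
                    raise ValueError("neighbour_count axis collapsed to < 2 values")
        else:
            values = np.asarray(res, dtype=float)
            if values.size < 2:
                raise ValueError(f"axis {name!r}: need >= 2 points")
            if np.any(values < lo) or np.any(values > hi):
                raise ValueError(f"axis {name!r}: values outside bounds [{lo}, {hi}]")
        axes.append((name, values))
    shape = tuple(v.size for _, v in axes)
    prior = np.full(shape, -math.log(float(np.prod(shape))))
    return ParameterGrid(tuple(axes), prior)


@dataclass(frozen=True)
class Posterior:
    """Normalized log posterior mass on a grid plus the evidence ledger."""

    grid: ParameterGrid
    log_mass: np.ndarray
    n_steps_assimilated: int = 0
    cumulative_log_evidence: float = 0.0

    def __post_init__(self):
        lm = np.asarray(self.log_mass, dtype=float)
        if lm.shape != self.grid.shape:
            raise ValueError("log_mass shape does not match grid")
        if abs(logsumexp(lm)) > _NORM_TOL:
            raise ValueError("posterior mass must sum to 1")
        if self.n_steps_assimilated < 0:
            raise ValueError("n_steps_assimilated must be >= 0")
        object.__setattr__(self, "log_mass", lm)

    @classmethod
    def from_prior(cls, grid: ParameterGrid) -> "Posterior":
        return cls(grid, grid.prior_log_mass.copy(), 0, 0.0)


# ---------------------------------------------------------------------------
# vectorized per-step likelihood on the grid


def _axis_or_fixed(grid: ParameterGrid, name: str, fixed: float) -> np.ndarray:
    return grid.values(name) if name in grid.names else np.asarray([fixed])


def grid_step_loglik(obs: StepObservation, grid: ParameterGrid,
                     spec: ModelSpec, base_params: ModelParams) -> np.ndarray:
    """Log likelihood of one observed step at every grid point.

    ``base_params`` supplies the arena size and the values of any model
    parameters that are not grid axes (for instance a fixed update
    probability of one when the update rate is not inferred).
    """
    if obs.n_particles < 1:
        raise ValueError("empty observation")
    arena = base_params.arena_size
    state = obs.prior_state
    disp, dist, bearing = pairwise_geometry(state, arena)
    u = unit_vectors(state.headings)

    if spec.neighbourhood_scheme == GEOMETRIC:
        nb_name = "interaction_radius"
        nb_fixed = base_params.interaction_radius
    else:
        nb_name = "neighbour_count"
        nb_fixed = base_params.neighbour_count
    nb_vals = _axis_or_fixed(grid, nb_name, nb_fixed)
    blind_vals = _axis_or_fixed(grid, "blind_angle", base_params.blind_angle)
    att_vals = (
        _axis_or_fixed(grid, "attraction_weight", base_params.attraction_weight)
        if spec.include_attraction else np.asarray([0.0])
    )
    ali_vals = (
        _axis_or_fixed(grid, "alignment_weight", base_params.alignment_weight)
        if spec.include_alignment else np.asarray([0.0])
    )
    sig_vals = _axis_or_fixed(grid, "noise_sd", base_params.noise_sd)
    p_vals = _axis_or_fixed(grid, "update_prob", base_params.update_prob)

    d_old = wrap_angle(obs.new_headings - state.headings)  # (N,)
    lp_old = wrapped_gaussian_logpdf(d_old[None, :], sig_vals[:, None])  # (S, N)
    with np.errstate(divide="ignore"):
        log_p = np.log(p_vals)
        log_1mp = np.where(p_vals < 1.0, np.log1p(-p_vals), -np.inf)
    pure = np.all(p_vals >= 1.0)

    nR, nB = nb_vals.size, blind_vals.size
    nA, nL, nS, nP = att_vals.size, ali_vals.size, sig_vals.size, p_vals.size
    out = np.empty((nR, nB, nA, nL, nS, nP))

    for ib, blind in enumerate(blind_vals):
        visible = visibility_mask(dist, bearing, blind)
        for ir, nb in enumerate(nb_vals):
            if spec.neighbourhood_scheme == GEOMETRIC:
                mask = visible & (dist <= nb)
            else:
                mask = _topological_mask(dist, visible, int(nb))
            a_hat, c_hat = _social_units(u, disp, mask)
            # force sum over the weight axes: (A, L, N, 2)
            v = (
                u[None, None]
                + att_vals[:, None, None, None] * c_hat[None, None]
                + ali_vals[None, :, None, None] * a_hat[None, None]
            )
            norm = np.linalg.norm(v, axis=-1)
            pred = np.where(
                norm > 1e-12,
                np.arctan2(v[..., 1], v[..., 0]),
                state.headings[None, None, :],
            )
            d_pred = wrap_angle(obs.new_headings[None, None, :] - pred)
            # (A, L, S, N)
            lp_pred = wrapped_gaussian_logpdf(
                d_pred[:, :, None, :], sig_vals[None, None, :, None]
            )
            if pure:
                ll = lp_pred.sum(axis=-1)[..., None]  # (A, L, S, 1)
            else:
                mix = np.logaddexp(
                    log_p[None, None, None, :, None]
                    + lp_pred[:, :, :, None, :],
                    log_1mp[None, None, None, :, None]
                    + lp_old[None, None, :, None, :],
                )
                ll = mix.sum(axis=-1)  # (A, L, S, P)
            out[ir, ib] = ll

    return _to_grid_order(out, grid, spec, nb_name)


def _social_units(u, disp, mask):
    m = mask.astype(float)
    counts = m.sum(axis=1)
    a_hat, _ = normalize_rows(m @ u)
    com = np.einsum("ij,ijk->ik", m, disp) / np.where(counts > 0, counts, 1.0)[:, None]
    c_hat, _ = normalize_rows(com)
    return a_hat, c_hat


def _to_grid_order(out: np.ndarray, grid: ParameterGrid, spec: ModelSpec,
                   nb_name: str) -> np.ndarray:
    internal = [nb_name, "blind_angle", "attraction_weight",
                "alignment_weight", "noise_sd", "update_prob"]
    perm = [internal.index(name) for name in grid.names]
    rest = [i for i in range(6) if i not in perm]
    return np.transpose(out, perm + rest).reshape(grid.shape)


# ---------------------------------------------------------------------------
# posterior updating and summaries


def update_posterior(post: Posterior,
                     new_data: Union[StepObservation, Sequence[StepObservation]],
                     spec: ModelSpec, base_params: ModelParams) -> Posterior:
    """Assimilate one or more observed steps (exact sequential Bayes).

    The posterior after the previous data acts as the prior for the new
    data; the Markov property makes the per-step likelihoods conditionally
    independent given the parameters.  The log normalizing constant of each
    update is added to the cumulative log evidence.
    """
    if isinstance(new_data, StepObservation):
        new_data = [new_data]
    else:
        new_data = list(new_data)
    if not new_data:
        return post
    ll = np.zeros(post.grid.shape)
    for obs in new_data:
        ll += grid_step_loglik(obs, post.grid, spec, base_params)
    unnorm = post.log_mass + ll
    log_z = float(logsumexp(unnorm))
    return Posterior(
        post.grid,
        unnorm - log_z,
        post.n_steps_assimilated + len(new_data),
        post.cumulative_log_evidence + log_z,
    )


def marginal_summary(post: Posterior, name: str):
    """Marginal mass over one axis plus its mass-weighted mean and SD."""
    axis = post.grid.axis_index(name)  # raises KeyError for unknown names
    values = post.grid.values(name)
    other = tuple(i for i in range(len(post.grid.shape)) if i != axis)
    marginal = np.exp(logsumexp(post.log_mass, axis=other))
    marginal = marginal / marginal.sum()
    mean = float(np.dot(marginal, values))
    var = float(np.dot(marginal, (values - mean) ** 2))
    return mean, math.sqrt(max(var, 0.0)), marginal


def entropy(dist: Union[Posterior, np.ndarray], base: Optional[float] = None) -> float:
    """Shannon entropy of a posterior (or any probability mass array).

    Natural log by default; pass ``base=2`` for bits.  0 * log 0 := 0.
    """
    if isinstance(dist, Posterior):
        log_mass = dist.log_mass
    else:
        mass = np.asarray(dist, dtype=float)
        with np.errstate(divide="ignore"):
            log_mass = np.log(mass)
    mass = np.exp(log_mass)
    with np.errstate(invalid="ignore"):
        terms = np.where(mass > 0, mass * log_mass, 0.0)
    h = -float(terms.sum())
    if base is not None:
        h /= math.log(base)
    return max(h, 0.0)


def log_bayes_factor(post_1: Posterior, post_2: Posterior) -> float:
    """Log evidence ratio of two models fitted to the same observations.

    Positive values favour the first model.  Additive across sequential
    data blocks because each posterior's cumulative evidence is.
    """
    if post_1.n_steps_assimilated != post_2.n_steps_assimilated:
        raise ValueError(
            "Bayes factors require both models to have assimilated the same "
            f"data ({post_1.n_steps_assimilated} vs {post_2.n_steps_assimilated} steps)"
        )
    return post_1.cumulative_log_evidence - post_2.cumulative_log_evidence
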