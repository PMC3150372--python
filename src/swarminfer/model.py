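"""Two-dimensional self-propelled particle (SPP) swarm model.

Particles move at constant speed in a periodic square arena.  At every
timestep each particle (with some update probability, one by default)
recomputes its direction from three contributions: inertia (its current
heading, weight fixed at one), attraction towards the centre of mass of its
neighbours, and alignment with the neighbours' headings.  A rear "blind
angle" removes particles it cannot see; neighbours are either all visible
particles within a fixed interaction radius (geometric scheme) or a fixed
number of nearest visible particles (topological scheme).  Wrapped-Gaussian
angular noise is added to the new heading, and the particle advances along
it.  For suitable parameters the swarm converges to a rotating mill, with
clockwise and anti-clockwise movers coexisting.

All updates are synchronous: every particle reads the state at time t and
writes the state at time t+1, which makes the transition density a product
over particles and so keeps the trajectory likelihood exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from ._angles import (
    TWO_PI,
    minimum_image_displacement,
    normalize_rows,
    unit_vectors,
    wrap_angle,
    wrap_position,
)

__all__ = [
    "ModelSpec",
    "ModelParams",
    "SwarmState",
    "Trajectory",
    "minimum_image_displacement",
    "neighbourhood",
    "social_vectors",
    "predicted_direction",
    "predicted_directions",
    "sample_wrapped_gaussian",
    "step",
    "simulate",
    "milling_order",
    "default_parameter_axes",
]

GEOMETRIC = "geometric"
TOPOLOGICAL = "topological"

#: broad, documented prior bounds used when a spec does not override them
_DEFAULT_BOUNDS = {
    "attraction_weight": (0.0, 1.2),
    "alignment_weight": (0.0, 0.6),
    "interaction_radius": (2.0, 6.0),
    "neighbour_count": (2, 18),
    "blind_angle": (0.0, math.pi),
    "noise_sd": (0.05, 0.45),
    "update_prob": (0.125, 1.0),
}


def default_parameter_axes(
    neighbourhood_scheme: str = GEOMETRIC,
    include_alignment: bool = True,
    include_attraction: bool = True,
    infer_update_rate: bool = False,
    overrides: Optional[dict] = None,
) -> Tuple[Tuple[str, float, float], ...]:
    """Build the ordered axis list of free parameters implied by the flags."""
    names = []
    if include_attraction:
        names.append("attraction_weight")
    if include_alignment:
        names.append("alignment_weight")
    names.append(
        "interaction_radius" if neighbourhood_scheme == GEOMETRIC else "neighbour_count"
    )
    names.append("blind_angle")
    names.append("noise_sd")
    if infer_update_rate:
        names.append("update_prob")
    overrides = overrides or {}
    return tuple(
        (n,) + tuple(overrides.get(n, _DEFAULT_BOUNDS[n])) for n in names
    )


@dataclass(frozen=True)
class ModelSpec:
    """Which interaction rules are active, and the bounds of the free parameters.

    A spec identifies a model *class* (the M of Bayes-factor comparisons):
    the neighbourhood scheme, which social forces exist, and whether the
    per-step update probability is a free parameter of the inference.
    """

    neighbourhood_scheme: str = GEOMETRIC
    include_alignment: bool = True
    include_attraction: bool = True
    infer_update_rate: bool = False
    parameter_axes: Tuple[Tuple[str, float, float], ...] = ()

    def __post_init__(self):
        if self.neighbourhood_scheme not in (GEOMETRIC, TOPOLOGICAL):
            raise ValueError(
                f"unknown neighbourhood scheme {self.neighbourhood_scheme!r}"
            )
        if not (self.include_alignment or self.include_attraction):
            raise ValueError("at least one social force must be included")
        axes = tuple(tuple(a) for a in self.parameter_axes)
        if not axes:
            axes = default_parameter_axes(
                self.neighbourhood_scheme,
                self.include_alignment,
                self.include_attraction,
                self.infer_update_rate,
            )
        object.__setattr__(self, "parameter_axes", axes)
        expected = [n for n, *_ in default_parameter_axes(
            self.neighbourhood_scheme,
            self.include_alignment,
            self.include_attraction,
            self.infer_update_rate,
        )]
        got = [name for name, *_ in self.parameter_axes]
        if sorted(got) != sorted(expected):
            raise ValueError(
                f"parameter_axes must contain exactly {expected}, got {got}"
            )
        for name, lo, hi in self.parameter_axes:
            if not lo < hi:
                raise ValueError(f"axis {name!r}: lower bound {lo} !< upper {hi}")
            if name == "noise_sd" and lo <= 0:
                raise ValueError("noise_sd axis must be strictly positive")
            if name == "update_prob" and not (0 < lo and hi <= 1):
                raise ValueError("update_prob axis must lie in (0, 1]")

    @property
    def free_parameters(self) -> Tuple[str, ...]:
        return tuple(name for name, *_ in self.parameter_axes)


@dataclass(frozen=True)
class ModelParams:
    """One concrete parameter vector of the SPP model.

    ``interaction_radius`` is used by the geometric scheme and
    ``neighbour_count`` by the topological one; either may be left unset
    when not needed.  ``blind_angle`` is the *total* angular width of the
    rear blind cone, so blind_angle = 0 means full vision.
    """

    attraction_weight: float = 0.0
    alignment_weight: float = 0.0
    interaction_radius: Optional[float] = None
    neighbour_count: Optional[int] = None
    blind_angle: float = 0.0
    noise_sd: float = 0.0
    speed: float = 1.0
    update_prob: float = 1.0
    arena_size: float = 1.0

    def __post_init__(self):
        if self.attraction_weight < 0 or self.alignment_weight < 0:
            raise ValueError("force weights must be non-negative")
        if not (0 <= self.blind_angle < TWO_PI):
            raise ValueError("blind_angle must lie in [0, 2*pi)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not (0 <= self.update_prob <= 1):
            raise ValueError("update_prob must lie in [0, 1]")
        if self.arena_size <= 0:
            raise ValueError("arena_size must be positive")
        if self.interaction_radius is not None:
            if not (0 < self.interaction_radius <= self.arena_size):
                raise ValueError(
                    "interaction_radius must lie in (0, arena_size]"
                )
        if self.neighbour_count is not None:
            if int(self.neighbour_count) != self.neighbour_count or self.neighbour_count < 1:
                raise ValueError("neighbour_count must be an integer >= 1")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SwarmState:
    """Positions and headings of all particles at a single timestep."""

    time_index: int
    positions: np.ndarray  # (N, 2), coordinates in [0, arena_size)
    headings: np.ndarray  # (N,), angles in (-pi, pi]

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        head = np.atleast_1d(np.asarray(self.headings, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError(f"positions must have shape (N, 2), got {pos.shape}")
        if head.shape != (pos.shape[0],):
            raise ValueError("headings must have shape (N,) matching positions")
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")
        if pos.shape[0] < 1:
            raise ValueError("need at least one particle")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "headings", wrap_angle(head))

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered sequence of swarm states (the data D of the inference)."""

    states: Sequence[SwarmState]
    params_used: Optional[ModelParams] = None
    rng_seed: Optional[int] = None

    def __post_init__(self):
        states = list(self.states)
        if not states:
            raise ValueError("trajectory must contain at least one state")
        n = states[0].n_particles
        for prev, nxt in zip(states, states[1:]):
            if nxt.time_index != prev.time_index + 1:
                raise ValueError(
                    f"non-consecutive time indices {prev.time_index} -> {nxt.time_index}"
                )
            if nxt.n_particles != n:
                raise ValueError("particle count must be constant over time")
        self.states = states

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]

    @property
    def n_particles(self) -> int:
        return self.states[0].n_particles

    @property
    def time_indices(self) -> Tuple[int, int]:
        return self.states[0].time_index, self.states[-1].time_index


# ---------------------------------------------------------------------------
# geometry of the interaction neighbourhood


def pairwise_geometry(state: SwarmState, arena_size: float):
    """Minimum-image displacements, distances and absolute bearings.

    Returns (disp, dist, bearing) where disp[i, j] is the displacement from
    particle i to particle j, dist[i, j] its norm, and bearing[i, j] in
    [0, pi] the unsigned angle between particle i's heading and disp[i, j].
    The diagonal of dist is set to +inf so a particle never neighbours itself.
    """
    pos = state.positions
    disp = minimum_image_displacement(pos[:, None, :], pos[None, :, :], arena_size)
    dist = np.linalg.norm(disp, axis=-1)
    np.fill_diagonal(dist, np.inf)
    angle_to = np.arctan2(disp[..., 1], disp[..., 0])
    bearing = np.abs(wrap_angle(angle_to - state.headings[:, None]))
    return disp, dist, bearing


def visibility_mask(dist, bearing, blind_angle: float):
    """Visibility under the rear blind cone: |bearing| <= pi - blind/2."""
    return (bearing <= np.pi - blind_angle / 2.0) & np.isfinite(dist)


def neighbour_mask(state: SwarmState, params: ModelParams, spec: ModelSpec,
                   dist=None, bearing=None):
    """Boolean (N, N) mask: mask[i, j] True iff j is a neighbour of i."""
    if dist is None or bearing is None:
        _, dist, bearing = pairwise_geometry(state, params.arena_size)
    visible = visibility_mask(dist, bearing, params.blind_angle)
    if spec.neighbourhood_scheme == GEOMETRIC:
        if params.interaction_radius is None:
            raise ValueError("geometric scheme requires interaction_radius")
        return visible & (dist <= params.interaction_radius)
    if params.neighbour_count is None:
        raise ValueError("topological scheme requires neighbour_count")
    return _topological_mask(dist, visible, int(params.neighbour_count))


def _topological_mask(dist, visible, k: int):
    n = dist.shape[0]
    masked = np.where(visible, dist, np.inf)
    # nearest k visible, ties at equal distance broken by particle index
    idx = np.arange(n)
    order = np.lexsort((np.broadcast_to(idx, (n, n)), masked), axis=1)
    out = np.zeros_like(visible)
    take = order[:, :k]
    rows = np.repeat(np.arange(n), take.shape[1])
    out[rows, take.ravel()] = True
    return out & visible  # strip slots that were padded with invisible entries


def neighbourhood(state: SwarmState, focal: int, params: ModelParams,
                  spec: ModelSpec) -> np.ndarray:
    """Indices of the particles in the interaction neighbourhood of ``focal``."""
    if not 0 <= focal < state.n_particles:
        raise IndexError(f"focal index {focal} out of range")
    mask = neighbour_mask(state, params, spec)
    return np.flatnonzero(mask[focal])


def social_vectors(state: SwarmState, focal: int, neighbours, arena_size: float):
    """Unit alignment and attraction vectors for one particle.

    The alignment vector is the normalized sum of the neighbours' heading
    unit vectors.  The attraction vector points from the focal particle to
    the neighbours' centre of mass, computed in minimum-image coordinates
    relative to the focal particle.  Either is None when the neighbour set
    is empty or the summed vector has zero length.
    """
    neighbours = np.asarray(neighbours, dtype=int)
    if neighbours.size == 0:
        return None, None
    align_sum = unit_vectors(state.headings[neighbours]).sum(axis=0)
    a_hat, a_ok = normalize_rows(align_sum)
    disp = minimum_image_displacement(
        state.positions[focal], state.positions[neighbours], arena_size
    )
    com = disp.mean(axis=0)  # focal -> centre of mass, minimum-image frame
    c_hat, c_ok = normalize_rows(com)
    return (a_hat if a_ok else None), (c_hat if c_ok else None)


# ---------------------------------------------------------------------------
# deterministic direction update (inertia + forces, weight of inertia = 1)


def predicted_directions(state: SwarmState, params: ModelParams,
                         spec: ModelSpec) -> np.ndarray:
    """Noise-free updated headings of all particles (vectorized)."""
    disp, dist, bearing = pairwise_geometry(state, params.arena_size)
    mask = neighbour_mask(state, params, spec, dist=dist, bearing=bearing)
    a_hat, c_hat = _social_unit_vectors(state, disp, mask)
    v = unit_vectors(state.headings)
    if spec.include_attraction:
        v = v + params.attraction_weight * c_hat
    if spec.include_alignment:
        v = v + params.alignment_weight * a_hat
    return _angles_of(v, state.headings)


def _social_unit_vectors(state: SwarmState, disp, mask):
    """Per-particle unit alignment / attraction vectors; zero rows when null."""
    m = mask.astype(float)
    counts = m.sum(axis=1)
    align_sum = m @ unit_vectors(state.headings)
    a_hat, _ = normalize_rows(align_sum)
    com = np.einsum("ij,ijk->ik", m, disp)
    com = com / np.where(counts > 0, counts, 1.0)[:, None]
    c_hat, _ = normalize_rows(com)
    return a_hat, c_hat


def _angles_of(v, fallback_headings):
    norm = np.linalg.norm(v, axis=-1)
    ang = np.arctan2(v[..., 1], v[..., 0])
    return wrap_angle(np.where(norm > 1e-12, ang, fallback_headings))


def predicted_direction(state: SwarmState, focal: int, params: ModelParams,
                        spec: ModelSpec) -> float:
    """Noise-free updated heading of one particle."""
    if not 0 <= focal < state.n_particles:
        raise IndexError(f"focal index {focal} out of range")
    return float(predicted_directions(state, params, spec)[focal])


def sample_wrapped_gaussian(sigma: float, rng: np.random.Generator, size=None):
    """Draw zero-mean wrapped-Gaussian angles in (-pi, pi].

    sigma = 0 returns exactly zero (degenerate distribution).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    draws = rng.normal(0.0, sigma, size=size) if sigma > 0 else (
        np.zeros(size) if size is not None else 0.0
    )
    return wrap_angle(draws)


# ---------------------------------------------------------------------------
# time stepping


def step(state: SwarmState, params: ModelParams, spec: ModelSpec,
         rng: np.random.Generator) -> SwarmState:
    """Advance the swarm by one synchronous timestep.

    Each particle independently updates its heading with probability
    ``update_prob`` to the force-predicted direction, otherwise keeps its
    previous heading; wrapped-Gaussian noise is added in both cases, and the
    particle moves by ``speed`` along the *new* heading.  Random draws are
    consumed in a fixed order (update coin flips, then noise) so runs are
    reproducible for a given generator state.
    """
    n = state.n_particles
    updates = rng.random(n) < params.update_prob
    noise = sample_wrapped_gaussian(params.noise_sd, rng, size=n)
    pred = predicted_directions(state, params, spec)
    base = np.where(updates, pred, state.headings)
    new_headings = wrap_angle(base + noise)
    new_positions = wrap_position(
        state.positions + params.speed * unit_vectors(new_headings),
        params.arena_size,
    )
    return SwarmState(state.time_index + 1, new_positions, new_headings)


def _as_rng(rng):
    if isinstance(rng, np.random.Generator):
        return rng, None
    seed = int(rng)
    return np.random.default_rng(seed), seed


def random_state(n_particles: int, arena_size: float,
                 rng: np.random.Generator, time_index: int = 0) -> SwarmState:
    """Uniformly random positions in the box and headings on the circle."""
    pos = rng.uniform(0.0, arena_size, size=(n_particles, 2))
    head = rng.uniform(-np.pi, np.pi, size=n_particles)
    return SwarmState(time_index, pos, head)


def simulate(n_particles: int, params: ModelParams, spec: ModelSpec,
             n_steps: int, rng, init: Optional[SwarmState] = None) -> Trajectory:
    """Simulate a trajectory of ``n_steps`` transitions (n_steps + 1 states).

    ``rng`` may be an integer seed (recorded on the trajectory) or a
    numpy Generator.  Without ``init``, positions are uniform on the box and
    headings uniform on the circle.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    gen, seed = _as_rng(rng)
    state = init if init is not None else random_state(n_particles, params.arena_size, gen)
    if state.n_particles != n_particles:
        raise ValueError("init state has wrong particle count")
    states = [state]
    for _ in range(n_steps):
        state = step(state, params, spec, gen)
        states.append(state)
    return Trajectory(states, params_used=params, rng_seed=seed)


def periodic_centroid(positions: np.ndarray, arena_size: float) -> np.ndarray:
    """Centre of mass on the torus via the circular mean of each coordinate."""
    theta = positions * (TWO_PI / arena_size)
    mean_angle = np.arctan2(
        np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0)
    )
    return np.mod(mean_angle, TWO_PI) * (arena_size / TWO_PI)


def milling_order(state: SwarmState, arena_size: float) -> float:
    """Unsigned rotational order parameter in [0, 1].

    Mean over particles of |sin| of the angle between the heading and the
    radial vector from the group centroid: 1 for perfectly tangential motion
    in either rotational sense, about 2/pi for uniformly random headings.
    Mills here routinely mix clockwise and anti-clockwise movers, hence the
    unsigned measure.  Particles sitting exactly on the centroid contribute 0.
    """
    if state.n_particles < 2:
        raise ValueError("milling_order needs at least two particles")
    centroid = periodic_centroid(state.positions, arena_size)
    radial = minimum_image_displacement(centroid, state.positions, arena_size)
    rnorm = np.linalg.norm(radial, axis=-1)
    radial_angle = np.arctan2(radial[:, 1], radial[:, 0])
    s = np.abs(np.sin(state.headings - radial_angle))
    return float(np.where(rnorm > 1e-12, s, 0.0).mean())
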