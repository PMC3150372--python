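"""Simulator unit and property tests: geometry, neighbourhoods, dynamics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarminfer import (
    ModelParams,
    ModelSpec,
    SwarmState,
    milling_order,
    minimum_image_displacement,
    neighbourhood,
    predicted_direction,
    sample_wrapped_gaussian,
    simulate,
    social_vectors,
    step,
)
from swarminfer._angles import wrap_angle
from swarminfer.model import pairwise_geometry, random_state


# ---------------------------------------------------------------------------
# angles and periodic geometry


def test_wrap_angle_convention():
    assert wrap_angle(np.pi) == pytest.approx(np.pi)
    assert wrap_angle(-np.pi) == pytest.approx(np.pi)
    assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)
    assert wrap_angle(0.0) == 0.0


def test_minimum_image_identity_and_wraparound():
    assert np.allclose(minimum_image_displacement((0, 0), (0, 0), 10.0), (0, 0))
    # crossing the boundary is shorter than going through the box interior
    assert np.allclose(minimum_image_displacement((9, 5), (1, 5), 10.0), (2, 0))


def test_minimum_image_requires_positive_arena():
    with pytest.raises(ValueError):
        minimum_image_displacement((0, 0), (1, 1), 0.0)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0, 6.999), min_size=4, max_size=4))
def test_minimum_image_matches_brute_force_over_images(coords):
    """The result equals the shortest of the nine periodic image displacements."""
    length = 7.0
    a, b = np.array(coords[:2]), np.array(coords[2:])
    d = minimum_image_displacement(a, b, length)
    images = [
        b + np.array([i, j]) * length - a
        for i, j in itertools.product((-1, 0, 1), repeat=2)
    ]
    best = min(images, key=lambda v: (np.linalg.norm(v), tuple(v)))
    assert np.linalg.norm(d) == pytest.approx(np.linalg.norm(best), abs=1e-9)
    assert np.all(d >= -length / 2) and np.all(d < length / 2)


# ---------------------------------------------------------------------------
# validated domain types


def test_model_spec_axes_must_match_flags():
    with pytest.raises(ValueError):
        ModelSpec(include_alignment=False, parameter_axes=(
            ("attraction_weight", 0, 1), ("alignment_weight", 0, 1),
            ("interaction_radius", 1, 5), ("blind_angle", 0, 3), ("noise_sd", 0.05, 1),
        ))
    with pytest.raises(ValueError):
        ModelSpec(include_alignment=False, include_attraction=False)
    with pytest.raises(ValueError):  # inverted bounds
        ModelSpec(parameter_axes=(
            ("attraction_weight", 1, 0), ("alignment_weight", 0, 1),
            ("interaction_radius", 1, 5), ("blind_angle", 0, 3), ("noise_sd", 0.05, 1),
        ))


@pytest.mark.parametrize("bad", [
    dict(blind_angle=2 * np.pi),
    dict(update_prob=1.5),
    dict(speed=0.0),
    dict(noise_sd=-0.1),
    dict(interaction_radius=20.0),  # exceeds arena
])
def test_model_params_validation(bad):
    base = dict(attraction_weight=0.5, interaction_radius=3.0, blind_angle=1.0,
                noise_sd=0.1, speed=0.5, arena_size=10.0)
    with pytest.raises(ValueError):
        ModelParams(**{**base, **bad})


def test_swarm_state_wraps_headings():
    s = SwarmState(0, [[1.0, 1.0]], [3 * np.pi / 2])
    assert s.headings[0] == pytest.approx(-np.pi / 2)


# ---------------------------------------------------------------------------
# neighbourhoods


def _params(**kw):
    base = dict(attraction_weight=1.0, alignment_weight=0.5,
                interaction_radius=5.0, blind_angle=0.0, noise_sd=0.1,
                speed=0.5, arena_size=10.0)
    base.update(kw)
    return ModelParams(**base)


def test_neighbourhood_no_exclusion(geometric_spec):
    """Full vision and a radius covering all pairs -> all other particles."""
    pos = [[5, 5], [5.5, 5], [5, 5.5], [4.5, 5]]
    state = SwarmState(0, pos, [0.0] * 4)
    nb = neighbourhood(state, 0, _params(), geometric_spec)
    assert sorted(nb) == [1, 2, 3]


def test_directly_behind_is_always_blind(geometric_spec):
    """A particle exactly opposite the focal heading is invisible for any blind angle > 0."""
    state = SwarmState(0, [[5, 5], [4, 5]], [0.0, 0.0])  # focal faces +x, other behind
    nb = neighbourhood(state, 0, _params(blind_angle=np.pi / 2), geometric_spec)
    assert len(nb) == 0


def test_neighbourhood_matches_brute_force_predicates(rng):
    """Vectorized neighbourhoods equal an independent per-pair predicate filter."""
    spec_g = ModelSpec()
    spec_t = ModelSpec(neighbourhood_scheme="topological")
    for trial in range(20):
        n = 8
        state = random_state(n, 10.0, rng)
        params = _params(blind_angle=float(rng.uniform(0, np.pi)),
                         interaction_radius=float(rng.uniform(1, 6)),
                         neighbour_count=int(rng.integers(1, n)))
        for focal in range(n):
            visible = []
            for j in range(n):
                if j == focal:
                    continue
                d = minimum_image_displacement(state.positions[focal],
                                               state.positions[j], 10.0)
                bearing = abs(wrap_angle(np.arctan2(d[1], d[0])
                                         - state.headings[focal]))
                if bearing <= np.pi - params.blind_angle / 2:
                    visible.append((float(np.linalg.norm(d)), j))
            expected_g = sorted(j for dist, j in visible
                                if dist <= params.interaction_radius)
            got_g = sorted(neighbourhood(state, focal, params, spec_g))
            assert got_g == expected_g
            expected_t = sorted(
                j for _, j in sorted(visible)[: params.neighbour_count]
            )
            got_t = sorted(neighbourhood(state, focal, params, spec_t))
            assert got_t == expected_t


def test_neighbourhood_can_be_asymmetric(geometric_spec):
    """The blind angle makes the interaction graph directed: i sees j, j not i."""
    # j is ahead of i; i is behind j (j faces away from i)
    state = SwarmState(0, [[5, 5], [6, 5]], [0.0, 0.0])
    params = _params(blind_angle=np.pi / 2)
    assert list(neighbourhood(state, 0, params, geometric_spec)) == [1]
    assert list(neighbourhood(state, 1, params, geometric_spec)) == []


# ---------------------------------------------------------------------------
# social vectors and the direction update


def test_social_vectors_single_and_cancelling():
    state = SwarmState(0, [[5, 5], [6, 5], [5, 6]], [0.0, 0.0, 0.0])
    align, _ = social_vectors(state, 0, [1], 10.0)
    assert np.allclose(align, [1, 0])
    state2 = SwarmState(0, [[5, 5], [6, 5], [5, 6]], [0.0, np.pi / 2, -np.pi / 2])
    align2, attract2 = social_vectors(state2, 0, [1, 2], 10.0)
    assert align2 is None  # opposite headings cancel exactly
    assert attract2 is not None


def test_attraction_vector_hand_computed():
    state = SwarmState(0, [[5, 5], [6, 5], [5, 6]], [0.0, 0.0, 0.0])
    _, attract = social_vectors(state, 0, [1, 2], 10.0)
    assert np.allclose(attract, [np.sqrt(2) / 2, np.sqrt(2) / 2])


def test_empty_neighbourhood_returns_nulls_and_inertia(geometric_spec):
    state = SwarmState(0, [[1, 1], [9, 9]], [0.7, 0.0])
    params = _params(interaction_radius=1.0)
    align, attract = social_vectors(state, 0, [], 10.0)
    assert align is None and attract is None
    assert predicted_direction(state, 0, params, geometric_spec) == pytest.approx(0.7)


def test_attraction_dominates_in_large_weight_limit(geometric_spec):
    """With overwhelming attraction, the new heading points at the neighbour."""
    state = SwarmState(0, [[5, 5], [5, 6]], [0.0, 0.0])  # neighbour to the left
    params = _params(attraction_weight=1e9, alignment_weight=0.0)
    assert predicted_direction(state, 0, params, geometric_spec) == pytest.approx(
        np.pi / 2, abs=1e-6
    )


def test_predicted_direction_hand_evaluated_vector_sum(geometric_spec):
    """Three particles, hand-evaluated inertia + attraction + alignment sum."""
    state = SwarmState(0, [[5.0, 5.0], [6.0, 5.0], [5.0, 6.0]],
                       [0.0, np.pi / 2, np.pi])
    params = _params(attraction_weight=1.0, alignment_weight=0.5)
    # neighbours of 0: particles 1 and 2 (full vision, radius 5)
    align_sum = np.array([np.cos(np.pi / 2) + np.cos(np.pi),
                          np.sin(np.pi / 2) + np.sin(np.pi)])
    align_hat = align_sum / np.linalg.norm(align_sum)
    com = np.array([0.5, 0.5])
    com_hat = com / np.linalg.norm(com)
    v = np.array([1.0, 0.0]) + 1.0 * com_hat + 0.5 * align_hat
    expected = np.arctan2(v[1], v[0])
    assert predicted_direction(state, 0, params, geometric_spec) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# noise


def test_wrapped_gaussian_sampling_moments(rng):
    assert sample_wrapped_gaussian(0.0, rng) == 0.0
    with pytest.raises(ValueError):
        sample_wrapped_gaussian(-1.0, rng)
    draws = sample_wrapped_gaussian(0.1, rng, size=100_000)
    # circular mean and dispersion
    z = np.exp(1j * draws)
    assert abs(np.angle(z.mean())) < 0.01
    circ_sd = np.sqrt(-2 * np.log(abs(z.mean())))
    assert circ_sd == pytest.approx(0.1, rel=0.05)


def test_heavy_wrapping_limit_is_uniform(rng):
    from scipy.stats import kstest, uniform

    draws = sample_wrapped_gaussian(10.0, rng, size=20_000)
    stat = kstest(draws, uniform(loc=-np.pi, scale=2 * np.pi).cdf)
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# stepping and trajectories


def test_ballistic_limit(geometric_spec, rng):
    """No neighbours in range, no noise: straight-line motion."""
    state = SwarmState(0, [[1, 1], [9, 9]], [0.0, np.pi / 2])
    params = _params(interaction_radius=1.0, noise_sd=0.0)
    new = step(state, params, geometric_spec, rng)
    assert np.allclose(new.headings, state.headings)
    assert np.allclose(new.positions[0], [1.5, 1])
    assert np.allclose(new.positions[1], [9, 9.5])


def test_frozen_limit_rigid_translation(geometric_spec, rng):
    """update_prob = 0 with zero noise freezes headings and relative geometry."""
    state = random_state(6, 10.0, rng)
    params = _params(noise_sd=0.0, update_prob=0.0)
    new = step(state, params, geometric_spec, rng)
    assert np.allclose(new.headings, state.headings)
    shift = minimum_image_displacement(state.positions, new.positions, 10.0)
    expected = 0.5 * np.stack([np.cos(state.headings), np.sin(state.headings)], -1)
    assert np.allclose(shift, expected)


def test_zero_noise_dynamics_deterministic(geometric_spec, reference_params):
    params = reference_params.replace(noise_sd=0.0)
    t1 = simulate(10, params, geometric_spec, 20, 7)
    t2 = simulate(10, params, geometric_spec, 20, 7)
    for a, b in zip(t1.states, t2.states):
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.headings, b.headings)


def test_same_seed_reproducible(geometric_spec, reference_params):
    t1 = simulate(5, reference_params, geometric_spec, 10, 99)
    t2 = simulate(5, reference_params, geometric_spec, 10, 99)
    assert all(np.array_equal(a.positions, b.positions)
               and np.array_equal(a.headings, b.headings)
               for a, b in zip(t1.states, t2.states))
    assert t1.rng_seed == 99


def test_simulate_zero_steps_returns_initial_only(geometric_spec, reference_params, rng):
    init = random_state(5, 10.0, rng)
    traj = simulate(5, reference_params, geometric_spec, 0, rng, init=init)
    assert len(traj) == 1
    assert traj[0] is init


def test_containment_and_speed_conservation(geometric_spec, reference_params):
    """Positions stay in the box; consecutive displacements equal the speed."""
    traj = simulate(12, reference_params, geometric_spec, 60, 3)
    for state in traj.states:
        assert np.all(state.positions >= 0) and np.all(state.positions < 10.0)
    for a, b in zip(traj.states, traj.states[1:]):
        d = minimum_image_displacement(a.positions, b.positions, 10.0)
        assert np.allclose(np.linalg.norm(d, axis=-1), reference_params.speed,
                           rtol=1e-9)
    # positions advance along the *new* heading exactly
    for a, b in zip(traj.states, traj.states[1:]):
        d = minimum_image_displacement(a.positions, b.positions, 10.0)
        expected = reference_params.speed * np.stack(
            [np.cos(b.headings), np.sin(b.headings)], -1)
        assert np.allclose(d, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# milling order parameter


def _circle_state(n, radius, center, tangential=True, senses=None):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pos = center + radius * np.stack([np.cos(ang), np.sin(ang)], -1)
    if tangential:
        senses = senses if senses is not None else np.ones(n)
        head = wrap_angle(ang + senses * np.pi / 2)
    else:
        head = wrap_angle(ang)  # radially outward
    return SwarmState(0, pos, head)


def test_milling_order_tangential_mixed_senses():
    senses = np.array([1, -1] * 5)
    state = _circle_state(10, 1.5, np.array([5.0, 5.0]), senses=senses)
    assert milling_order(state, 10.0) == pytest.approx(1.0, abs=1e-9)


def test_milling_order_radial_is_zero():
    state = _circle_state(10, 1.5, np.array([5.0, 5.0]), tangential=False)
    assert milling_order(state, 10.0) == pytest.approx(0.0, abs=1e-9)


def test_milling_order_random_headings_expectation(rng):
    """Uniform random headings give E|sin| = 2/pi."""
    ang = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
    pos = np.array([5.0, 5.0]) + 1.5 * np.stack([np.cos(ang), np.sin(ang)], -1)
    state = SwarmState(0, pos, rng.uniform(-np.pi, np.pi, 4000))
    assert milling_order(state, 10.0) == pytest.approx(2 / np.pi, abs=0.03)
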