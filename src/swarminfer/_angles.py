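"""Angle and periodic-box helpers shared across the package.

Headings are stored as angles in radians wrapped to the half-open interval
(-pi, pi]; positions live in the half-open periodic box [0, L)^2.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles to (-pi, pi].

    Accepts scalars or arrays.  The representative of the boundary angle is
    +pi (so -pi maps to +pi), matching the convention used for headings.
    """
    return np.pi - np.mod(np.pi - np.asarray(theta, dtype=float), TWO_PI)


def wrap_position(x, arena_size: float):
    """Wrap coordinates into the periodic box [0, arena_size)."""
    return np.mod(np.asarray(x, dtype=float), arena_size)


def minimum_image_displacement(a, b, arena_size: float):
    """Shortest displacement from ``a`` to ``b`` under periodic wrapping.

    Each component of the result lies in [-arena_size/2, arena_size/2).
    Broadcasts over leading dimensions; the last axis holds coordinates.
    """
    if arena_size <= 0:
        raise ValueError(f"arena_size must be positive, got {arena_size}")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - arena_size * np.floor(d / arena_size + 0.5)


def unit_vectors(theta):
    """Unit vectors for heading angles; output shape = theta.shape + (2,)."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def normalize_rows(v, eps: float = 1e-12):
    """Normalize vectors along the last axis.

    Returns (unit_vectors, nonzero_mask); rows with norm <= eps are left as
    zero vectors and flagged False in the mask.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    ok = norm[..., 0] > eps
    out = np.where(norm > eps, v / np.where(norm > eps, norm, 1.0), 0.0)
    return out, ok
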