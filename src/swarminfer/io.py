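"""Trajectory file I/O.

Trajectories are stored as plain CSV with header ``t,particle,x,y,heading``,
one row per particle per timestep (t-major, particle-minor), angles in
radians and positions in box coordinates.  Metadata (arena size, seed,
generating parameters when known) lives in commented header lines beginning
``#`` so a file is self-describing.  Floats are written with 17 significant
digits, which round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from ._angles import wrap_angle
from .model import ModelParams, SwarmState, Trajectory

__all__ = ["read_trajectory", "write_trajectory", "TrajectoryParseError"]

_HEADER = "t,particle,x,y,heading"


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file fails validation; names the first bad row."""


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_trajectory(traj: Trajectory, path: Union[str, Path],
                     arena_size: Optional[float] = None) -> None:
    """Write a trajectory as commented-header CSV (deterministic byte output)."""
    if arena_size is None:
        if traj.params_used is None:
            raise ValueError("arena_size required when trajectory has no params")
        arena_size = traj.params_used.arena_size
    meta = {"arena_size": arena_size}
    if traj.rng_seed is not None:
        meta["rng_seed"] = traj.rng_seed
    if traj.params_used is not None:
        meta["params"] = dataclasses.asdict(traj.params_used)
    lines = [
        "# swarminfer trajectory v1",
        "# meta: " + json.dumps(meta, sort_keys=True),
        _HEADER,
    ]
    for state in traj.states:
        for i in range(state.n_particles):
            x, y = state.positions[i]
            lines.append(
                f"{state.time_index},{i},{_fmt(x)},{_fmt(y)},{_fmt(state.headings[i])}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    """Read and validate a trajectory CSV written by :func:`write_trajectory`.

    Headings are wrapped to (-pi, pi] on read.  Raises
    :class:`TrajectoryParseError` naming the first offending file line for
    missing columns, non-contiguous timesteps, inconsistent particle sets,
    or positions outside the box.
    """
    path = Path(path)
    meta: dict = {}
    rows = []  # (line_no, t, particle, x, y, heading)
    header_seen = False
    with path.open() as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("meta:"):
                    meta = json.loads(body[len("meta:"):])
                continue
            if not header_seen:
                if line != _HEADER:
                    raise TrajectoryParseError(
                        f"{path}:{line_no}: expected header {_HEADER!r}, got {line!r}"
                    )
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 5:
                raise TrajectoryParseError(
                    f"{path}:{line_no}: expected 5 columns, got {len(fields)}"
                )
            try:
                rows.append((line_no, int(fields[0]), int(fields[1]),
                             float(fields[2]), float(fields[3]), float(fields[4])))
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}:{line_no}: {exc}") from None
    if not header_seen:
        raise TrajectoryParseError(f"{path}: missing header line {_HEADER!r}")
    if not rows:
        raise TrajectoryParseError(f"{path}: no data rows")
    if "arena_size" not in meta:
        raise TrajectoryParseError(f"{path}: metadata lacks arena_size")
    arena = float(meta["arena_size"])

    # group by timestep, preserving file order
    by_t: dict = {}
    for row in rows:
        by_t.setdefault(row[1], []).append(row)
    times = sorted(by_t)
    for a, b in zip(times, times[1:]):
        if b != a + 1:
            line_no = by_t[b][0][0]
            raise TrajectoryParseError(
                f"{path}:{line_no}: non-contiguous timestep {a} -> {b}"
            )
    expected_ids = sorted(r[2] for r in by_t[times[0]])
    if expected_ids != list(range(len(expected_ids))):
        raise TrajectoryParseError(
            f"{path}:{by_t[times[0]][0][0]}: particle ids at t={times[0]} "
            f"must be 0..N-1, got {expected_ids}"
        )
    states = []
    for t in times:
        group = sorted(by_t[t], key=lambda r: r[2])
        ids = [r[2] for r in group]
        if ids != expected_ids:
            missing = sorted(set(expected_ids) - set(ids))
            extra = sorted(set(ids) - set(expected_ids))
            line_no = group[0][0]
            raise TrajectoryParseError(
                f"{path}:{line_no}: inconsistent particle set at t={t}"
                + (f", missing {missing}" if missing else "")
                + (f", unexpected {extra}" if extra else "")
            )
        for r in group:
            if not (0 <= r[3] < arena and 0 <= r[4] < arena):
                raise TrajectoryParseError(
                    f"{path}:{r[0]}: position ({r[3]}, {r[4]}) outside "
                    f"[0, {arena}) box"
                )
        pos = np.array([[r[3], r[4]] for r in group])
        head = wrap_angle(np.array([r[5] for r in group]))
        states.append(SwarmState(t, pos, head))

    params = None
    if "params" in meta:
        params = ModelParams(**meta["params"])
    return Trajectory(states, params_used=params, rng_seed=meta.get("rng_seed"))
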