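"""Scripted, seeded experiment pipelines.

Each runner simulates data, performs sequential grid inference, and returns
a :class:`ScenarioReport` whose records hold one row per increment
(assimilated step or swept value) per seed, plus seed-averaged rows
(``seed == "mean"``).  The config snapshot stored on the report suffices to
re-run the scenario bit-identically.

The four scenarios are:

* ``convergence`` — sequential inference on data from a random initial
  configuration and from the steady-state rotating mill, tracking marginal
  means/SDs and joint posterior entropy step by step.
* ``noise`` — full 10-step inference at a sweep of generating noise levels;
  entropy rises towards the prior entropy as noise washes out the signal.
* ``update_rate`` — data generated with per-step update probability p < 1,
  analysed either assuming p = 1 (biased force estimates) or with p as an
  extra inferred axis (bias removed).
* ``model_selection`` — cumulative log Bayes factors between two candidate
  rule variants, with data generated from each candidate in turn.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .bayes import (
    ParameterGrid,
    Posterior,
    entropy,
    make_grid,
    marginal_summary,
    update_posterior,
)
from .likelihood import StepObservation, step_observations
from .model import (
    ModelParams,
    ModelSpec,
    SwarmState,
    Trajectory,
    default_parameter_axes,
    milling_order,
    random_state,
    simulate,
    step,
)

__all__ = [
    "ScenarioReport",
    "simulate_to_mill",
    "run_convergence_scenario",
    "run_noise_sweep",
    "run_update_rate_sweep",
    "run_model_selection",
]


@dataclass
class ScenarioReport:
    """Tabular result of one scenario run plus everything needed to re-run it."""

    name: str
    records: pd.DataFrame
    seeds: Sequence[int]
    config: Dict

    def save(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / f"{self.name}.csv", index=False)
        payload = {
            "name": self.name,
            "seeds": list(self.seeds),
            "config": self.config,
            "records": self.records.to_dict(orient="records"),
        }
        import json

        (out / f"{self.name}.json").write_text(json.dumps(payload, indent=2))


def spawn_seeds(master_seed: int, n: int) -> list:
    """Independent per-trial seeds derived from one master seed (all < 2^31)."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def simulate_to_mill(params: ModelParams, spec: ModelSpec,
                     rng: np.random.Generator, threshold: float = 0.8,
                     window: int = 20, max_steps: int = 4000,
                     n_particles: int = 25) -> Optional[SwarmState]:
    """Run from a random configuration until the mill is sustained.

    The steady state is declared when the milling order parameter stays
    above ``threshold`` for ``window`` consecutive steps.  Returns the state
    at that point (time index reset to 0), or None if the mill never forms
    within ``max_steps``.
    """
    state = random_state(n_particles, params.arena_size, rng)
    recent: deque = deque(maxlen=window)
    for _ in range(max_steps):
        state = step(state, params, spec, rng)
        recent.append(milling_order(state, params.arena_size))
        if len(recent) == window and min(recent) > threshold:
            return SwarmState(0, state.positions, state.headings)
    return None


def _summary_row(post: Posterior) -> Dict:
    row = {
        "entropy": entropy(post),
        "log_evidence": post.cumulative_log_evidence,
    }
    for name in post.grid.names:
        mean, sd, marginal = marginal_summary(post, name)
        row[f"mean_{name}"] = mean
        row[f"sd_{name}"] = sd
        row[f"marg_entropy_{name}"] = entropy(marginal)
    return row


def _sequential_rows(observations: Sequence[StepObservation], spec: ModelSpec,
                     grid: ParameterGrid, base_params: ModelParams,
                     tags: Dict) -> list:
    post = Posterior.from_prior(grid)
    rows = []
    for k, obs in enumerate(observations, start=1):
        post = update_posterior(post, obs, spec, base_params)
        rows.append({**tags, "step": k, **_summary_row(post)})
    return rows


def _with_mean_rows(df: pd.DataFrame, group_cols: list) -> pd.DataFrame:
    """Append seed-averaged rows (seed == 'mean') per group."""
    num_cols = [c for c in df.columns
                if c not in group_cols + ["seed"] and pd.api.types.is_numeric_dtype(df[c])]
    means = (
        df[df["excluded"] == False] if "excluded" in df.columns else df  # noqa: E712
    ).groupby(group_cols, dropna=False)[num_cols].mean().reset_index()
    means["seed"] = "mean"
    out = pd.concat([df, means], ignore_index=True)
    return out


def _grid_for(spec: ModelSpec, resolution) -> ParameterGrid:
    return make_grid(spec, resolution)


# ---------------------------------------------------------------------------


def run_convergence_scenario(spec: ModelSpec, params_true: ModelParams,
                             resolution, n_seeds: int = 5, n_steps: int = 10,
                             n_particles: int = 25, seed: int = 0,
                             mill_threshold: float = 0.8,
                             mill_window: int = 20,
                             max_burn_in: int = 4000) -> ScenarioReport:
    """Sequential inference from random and steady-state (mill) configurations.

    For each seed, ``n_steps`` transitions are assimilated one at a time,
    once starting from a random configuration and once starting inside the
    rotating mill.  Seeds whose mill never forms within ``max_burn_in``
    steps are flagged ``excluded`` and left out of the seed averages.
    """
    grid = _grid_for(spec, resolution)
    seeds = spawn_seeds(seed, n_seeds)
    rows = []
    for s in seeds:
        rng = np.random.default_rng(s)
        traj = simulate(n_particles, params_true, spec, n_steps, rng)
        rows += _sequential_rows(step_observations(traj), spec, grid,
                                 params_true, {"seed": s, "arm": "random",
                                               "excluded": False})
        mill = simulate_to_mill(params_true, spec, rng, mill_threshold,
                                mill_window, max_burn_in, n_particles)
        if mill is None:
            rows.append({"seed": s, "arm": "steady", "step": 0,
                         "excluded": True})
            continue
        traj = simulate(n_particles, params_true, spec, n_steps, rng, init=mill)
        rows += _sequential_rows(step_observations(traj), spec, grid,
                                 params_true, {"seed": s, "arm": "steady",
                                               "excluded": False})
    df = _with_mean_rows(pd.DataFrame(rows), ["arm", "step"])
    config = {
        "scenario": "convergence",
        "spec": _spec_dict(spec),
        "params_true": _params_dict(params_true),
        "resolution": _res_dict(resolution),
        "n_seeds": n_seeds, "n_steps": n_steps, "n_particles": n_particles,
        "seed": seed, "prior_entropy": math.log(grid.size),
        "mill": {"threshold": mill_threshold, "window": mill_window,
                 "max_burn_in": max_burn_in},
    }
    return ScenarioReport("convergence", df, seeds, config)


def run_noise_sweep(spec: ModelSpec, params_true: ModelParams,
                    sigma_values: Sequence[float], resolution,
                    n_seeds: int = 5, n_steps: int = 10,
                    n_particles: int = 25, seed: int = 0) -> ScenarioReport:
    """Full inference at each generating noise level (random configuration)."""
    grid = _grid_for(spec, resolution)
    sig_axis = grid.values("noise_sd")
    for sig in sigma_values:
        if not (sig_axis[0] <= sig <= sig_axis[-1]):
            raise ValueError(
                f"sweep value sigma={sig} outside grid range "
                f"[{sig_axis[0]}, {sig_axis[-1]}]"
            )
    seeds = spawn_seeds(seed, n_seeds)
    rows = []
    for sig in sigma_values:
        gen = params_true.replace(noise_sd=float(sig))
        for s in seeds:
            rng = np.random.default_rng(s)
            traj = simulate(n_particles, gen, spec, n_steps, rng)
            post = Posterior.from_prior(grid)
            post = update_posterior(post, step_observations(traj), spec, gen)
            rows.append({"seed": s, "sigma_true": float(sig),
                         "step": n_steps, **_summary_row(post)})
    df = _with_mean_rows(pd.DataFrame(rows), ["sigma_true"])
    config = {
        "scenario": "noise",
        "spec": _spec_dict(spec), "params_true": _params_dict(params_true),
        "resolution": _res_dict(resolution),
        "sigma_values": [float(s) for s in sigma_values],
        "n_seeds": n_seeds, "n_steps": n_steps, "n_particles": n_particles,
        "seed": seed, "prior_entropy": math.log(grid.size),
    }
    return ScenarioReport("noise", df, seeds, config)


def run_update_rate_sweep(spec: ModelSpec, params_true: ModelParams,
                          p_values: Sequence[float], infer_p: bool,
                          resolution, n_seeds: int = 5, n_steps: int = 10,
                          n_particles: int = 25, seed: int = 0,
                          p_axis_bounds: Tuple[float, float] = (0.25, 1.0),
                          p_axis_points: int = 4) -> ScenarioReport:
    """Inference on data generated with per-step update probability < 1.

    With ``infer_p=False`` the analysis assumes every particle updates every
    step (p = 1), which biases the force weights low; with ``infer_p=True``
    the update probability becomes an extra grid axis and is inferred
    jointly with the other parameters.
    """
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"update probability {p} outside (0, 1]")
    if infer_p:
        overrides = {name: (lo, hi) for name, lo, hi in spec.parameter_axes}
        overrides["update_prob"] = p_axis_bounds
        infer_spec = ModelSpec(
            spec.neighbourhood_scheme, spec.include_alignment,
            spec.include_attraction, True,
            default_parameter_axes(
                spec.neighbourhood_scheme, spec.include_alignment,
                spec.include_attraction, True, overrides,
            ),
        )
        if isinstance(resolution, int):
            res = {name: resolution for name in infer_spec.free_parameters}
        else:
            res = dict(resolution)
        res["update_prob"] = p_axis_points
        grid = make_grid(infer_spec, res)
    else:
        infer_spec = spec
        grid = _grid_for(spec, resolution)
    base = params_true.replace(update_prob=1.0)
    seeds = spawn_seeds(seed, n_seeds)
    rows = []
    for p in p_values:
        gen = params_true.replace(update_prob=float(p))
        for s in seeds:
            rng = np.random.default_rng(s)
            traj = simulate(n_particles, gen, spec, n_steps, rng)
            post = Posterior.from_prior(grid)
            post = update_posterior(post, step_observations(traj), infer_spec, base)
            rows.append({"seed": s, "p_true": float(p), "step": n_steps,
                         "infer_p": infer_p, **_summary_row(post)})
    df = _with_mean_rows(pd.DataFrame(rows), ["p_true"])
    config = {
        "scenario": "update_rate",
        "spec": _spec_dict(spec), "params_true": _params_dict(params_true),
        "resolution": _res_dict(resolution), "infer_p": infer_p,
        "p_values": [float(p) for p in p_values],
        "p_axis": {"bounds": list(p_axis_bounds), "points": p_axis_points},
        "n_seeds": n_seeds, "n_steps": n_steps, "n_particles": n_particles,
        "seed": seed, "prior_entropy": math.log(grid.size),
    }
    return ScenarioReport("update_rate", df, seeds, config)


def run_model_selection(candidates, n_seeds: int = 5, n_steps: int = 10,
                        n_particles: int = 25, seed: int = 0,
                        arms: Sequence[str] = ("random", "steady"),
                        mill_threshold: float = 0.8, mill_window: int = 20,
                        max_burn_in: int = 4000) -> ScenarioReport:
    """Cumulative log Bayes factors between two candidate rule variants.

    ``candidates`` is a pair of ``(label, spec, params_true, resolution)``
    tuples.  Data are generated from each candidate in turn and scored under
    both; the reported log Bayes factor is candidate 1 over candidate 2, so
    positive values favour the first candidate.  Both candidates see the
    identical observation sequence.
    """
    (label_a, spec_a, params_a, res_a), (label_b, spec_b, params_b, res_b) = candidates
    grid_a, grid_b = make_grid(spec_a, res_a), make_grid(spec_b, res_b)
    seeds = spawn_seeds(seed, n_seeds)
    rows = []
    for gen_label, gen_spec, gen_params in (
        (label_a, spec_a, params_a), (label_b, spec_b, params_b)
    ):
        for s in seeds:
            rng = np.random.default_rng(s)
            inits = {}
            if "random" in arms:
                inits["random"] = random_state(n_particles, gen_params.arena_size, rng)
            if "steady" in arms:
                inits["steady"] = simulate_to_mill(
                    gen_params, gen_spec, rng, mill_threshold, mill_window,
                    max_burn_in, n_particles,
                )
            for arm, init in inits.items():
                if init is None:
                    rows.append({"seed": s, "generating": gen_label, "arm": arm,
                                 "step": 0, "excluded": True})
                    continue
                traj = simulate(n_particles, gen_params, gen_spec, n_steps,
                                rng, init=init)
                post_a = Posterior.from_prior(grid_a)
                post_b = Posterior.from_prior(grid_b)
                for k, obs in enumerate(step_observations(traj), start=1):
                    post_a = update_posterior(post_a, obs, spec_a, params_a)
                    post_b = update_posterior(post_b, obs, spec_b, params_b)
                    rows.append({
                        "seed": s, "generating": gen_label, "arm": arm,
                        "step": k, "excluded": False,
                        "log_evidence_a": post_a.cumulative_log_evidence,
                        "log_evidence_b": post_b.cumulative_log_evidence,
                        "log_bf": post_a.cumulative_log_evidence
                        - post_b.cumulative_log_evidence,
                    })
    df = _with_mean_rows(pd.DataFrame(rows), ["generating", "arm", "step"])
    config = {
        "scenario": "model_selection",
        "candidates": [
            {"label": label_a, "spec": _spec_dict(spec_a),
             "params": _params_dict(params_a), "resolution": _res_dict(res_a)},
            {"label": label_b, "spec": _spec_dict(spec_b),
             "params": _params_dict(params_b), "resolution": _res_dict(res_b)},
        ],
        "n_seeds": n_seeds, "n_steps": n_steps, "n_particles": n_particles,
        "seed": seed, "arms": list(arms),
        "mill": {"threshold": mill_threshold, "window": mill_window,
                 "max_burn_in": max_burn_in},
    }
    return ScenarioReport("model_selection", df, seeds, config)


# ---------------------------------------------------------------------------


def _spec_dict(spec: ModelSpec) -> Dict:
    return {
        "neighbourhood_scheme": spec.neighbourhood_scheme,
        "include_alignment": spec.include_alignment,
        "include_attraction": spec.include_attraction,
        "infer_update_rate": spec.infer_update_rate,
        "parameter_axes": [list(a) for a in spec.parameter_axes],
    }


def _params_dict(params: ModelParams) -> Dict:
    import dataclasses

    return dataclasses.asdict(params)


def _res_dict(resolution) -> Dict:
    if isinstance(resolution, int):
        return {"all": resolution}
    return {k: (v if isinstance(v, int) else [float(x) for x in v])
            for k, v in resolution.items()}
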