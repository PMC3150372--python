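"""Desk-scale reference studies: the canonical end-to-end analyses.

Each study simulates its own data with the bundled reference parameter set
(25 particles, ten recorded timesteps, five independent trials by default),
runs the inference, and reduces the outcome to a small dictionary of named
quantities: recovery fractions, entropy ratios, biases, Bayes-factor signs.
These are the numbers the package's claims rest on; the test suite asserts
them and ``scripts/acceptance.py`` re-computes and exports them.

Grid resolutions here are the documented defaults, sized so a full study
finishes in minutes on one CPU.  The generating parameter values sit on
grid points: the inference problem is then well-posed and any residual
error is attributable to the data, not to grid discretization.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import quad

from .bayes import (
    Posterior,
    entropy,
    make_grid,
    update_posterior,
)
from .config import reference_config
from .experiments import (
    ScenarioReport,
    run_convergence_scenario,
    run_model_selection,
    run_noise_sweep,
    run_update_rate_sweep,
    simulate_to_mill,
    spawn_seeds,
)
from .likelihood import step_loglik, step_observations, wrapped_gaussian_logpdf
from .model import (
    ModelParams,
    ModelSpec,
    default_parameter_axes,
    simulate,
)

__all__ = [
    "reference_setup",
    "mill_emergence_study",
    "convergence_study",
    "noise_study",
    "update_rate_study",
    "selection_study",
    "exactness_study",
]

#: default grid resolution for the reference geometric model
REFERENCE_RESOLUTION = {
    "attraction_weight": 9,
    "alignment_weight": 9,
    "interaction_radius": 8,
    "blind_angle": 7,
    "noise_sd": 9,
}

#: noise-sweep sigma axis: dense where inference resolves the noise level,
#: extending past 2*pi where the wrapped Gaussian is indistinguishable from
#: uniform, so the prior covers the full washed-out regime
NOISE_SIGMA_AXIS = [0.3, 1.0, 2.0, 3.0, 3.8, 4.6, 5.4, 6.1, 6.8]
NOISE_SWEEP = [0.3, 0.8, 1.5, 2.2, math.pi, 4.0]

#: update-rate study noise axis reaches high enough to absorb the inflated
#: noise estimates that the constrained (p = 1) analysis produces
UPDATE_RATE_SIGMA_AXIS = [0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 0.9, 1.25]


def reference_setup() -> Tuple[ModelSpec, ModelParams, Dict]:
    """Spec, generating parameters and grid resolution of the reference model."""
    cfg = reference_config()
    return cfg.model_spec(), cfg.model_params(), REFERENCE_RESOLUTION


def _axis_overrides(spec: ModelSpec) -> Dict:
    return {name: (lo, hi) for name, lo, hi in spec.parameter_axes}


# ---------------------------------------------------------------------------


def mill_emergence_study(seed: int, n_seeds: int = 5) -> Dict:
    """Fraction of random starts that reach the sustained rotating mill."""
    cfg = reference_config()
    spec, params = cfg.model_spec(), cfg.model_params()
    bi = cfg.run.burn_in
    seeds = spawn_seeds(seed, n_seeds)
    hits = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        state = simulate_to_mill(params, spec, rng, bi.threshold, bi.window,
                                 bi.max_steps, cfg.run.n_particles)
        hits += state is not None
    return {"mill_emergence_fraction": hits / n_seeds, "n": n_seeds}


def convergence_study(seed: int, n_seeds: int = 5) -> Tuple[Dict, ScenarioReport]:
    """Parameter recovery and entropy in random vs steady-state regimes."""
    spec, params, res = reference_setup()
    cfg = reference_config()
    bi = cfg.run.burn_in
    report = run_convergence_scenario(
        spec, params, res, n_seeds=n_seeds, n_steps=cfg.run.n_steps,
        n_particles=cfg.run.n_particles, seed=seed,
        mill_threshold=bi.threshold, mill_window=bi.window,
        max_burn_in=bi.max_steps,
    )
    df = report.records
    truth = report.config["params_true"]
    last = df[(df.step == cfg.run.n_steps) & (df.seed != "mean")
              & (~df.excluded.astype(bool))]
    recovery = {}
    for arm in ("random", "steady"):
        sub = last[last.arm == arm]
        for name in spec.free_parameters:
            ok = (sub[f"mean_{name}"] - truth[name]).abs() <= 2 * sub[f"sd_{name}"]
            recovery[(arm, name)] = float(ok.mean()) if len(sub) else float("nan")
    mean_rows = df[df.seed == "mean"]
    rand_h = mean_rows[mean_rows.arm == "random"].sort_values("step").entropy.to_numpy()
    steady_h = mean_rows[mean_rows.arm == "steady"].sort_values("step").entropy.to_numpy()
    prior_h = report.config["prior_entropy"]
    n_radius = len(make_grid(spec, res).values("interaction_radius"))
    steady_last = last[last.arm == "steady"]
    radius_retained = (
        steady_last["marg_entropy_interaction_radius"] / math.log(n_radius)
    ).mean() * 100
    metrics = {
        "recovery_min_fraction_random": min(
            recovery[("random", n)] for n in spec.free_parameters
        ),
        "recovery_attraction_steady": recovery[("steady", "attraction_weight")],
        "recovery_alignment_steady": recovery[("steady", "alignment_weight")],
        "entropy_drop_random_nats": float(prior_h - rand_h[-1]),
        "entropy_decreasing_random": float(rand_h[-1] < rand_h[0]),
        "steady_entropy_ge_random_fraction": float(
            np.mean(steady_h >= rand_h) if steady_h.size == rand_h.size else np.nan
        ),
        "radius_prior_entropy_retained_pct": float(radius_retained),
        "n": n_seeds,
    }
    return metrics, report


def noise_study(seed: int, n_seeds: int = 5) -> Tuple[Dict, ScenarioReport]:
    """Posterior entropy as generating noise sweeps into the washout regime."""
    cfg = reference_config()
    base_spec, params = cfg.model_spec(), cfg.model_params()
    overrides = _axis_overrides(base_spec)
    overrides["noise_sd"] = (NOISE_SIGMA_AXIS[0], NOISE_SIGMA_AXIS[-1])
    spec = ModelSpec(
        base_spec.neighbourhood_scheme, base_spec.include_alignment,
        base_spec.include_attraction, False,
        default_parameter_axes(base_spec.neighbourhood_scheme, overrides=overrides),
    )
    res = dict(REFERENCE_RESOLUTION)
    res["noise_sd"] = NOISE_SIGMA_AXIS
    report = run_noise_sweep(spec, params, NOISE_SWEEP, res, n_seeds=n_seeds,
                             n_steps=cfg.run.n_steps,
                             n_particles=cfg.run.n_particles, seed=seed)
    mean_rows = report.records[report.records.seed == "mean"].sort_values("sigma_true")
    prior_h = report.config["prior_entropy"]
    h = mean_rows.entropy.to_numpy()
    sig = mean_rows.sigma_true.to_numpy()
    inversions = int(np.sum(np.diff(h) < 0))
    washout = h[sig >= math.pi] / prior_h * 100
    metrics = {
        "entropy_pct_lowest_noise": float(h[0] / prior_h * 100),
        "entropy_inversions": inversions,
        "washout_entropy_pct_min": float(washout.min()),
        "n": n_seeds * len(NOISE_SWEEP),
    }
    return metrics, report


def update_rate_study(seed: int, n_seeds: int = 5) -> Tuple[Dict, Dict[str, ScenarioReport]]:
    """Force-weight bias under rapid sampling and its cure by inferring p."""
    cfg = reference_config()
    base_spec, params = cfg.model_spec(), cfg.model_params()
    overrides = _axis_overrides(base_spec)
    overrides["noise_sd"] = (UPDATE_RATE_SIGMA_AXIS[0], UPDATE_RATE_SIGMA_AXIS[-1])
    overrides["alignment_weight"] = (0.0, 0.45)
    spec = ModelSpec(
        base_spec.neighbourhood_scheme, base_spec.include_alignment,
        base_spec.include_attraction, False,
        default_parameter_axes(base_spec.neighbourhood_scheme, overrides=overrides),
    )
    res = dict(REFERENCE_RESOLUTION)
    res["noise_sd"] = UPDATE_RATE_SIGMA_AXIS
    res["alignment_weight"] = 7
    common = dict(n_seeds=n_seeds, n_steps=cfg.run.n_steps,
                  n_particles=cfg.run.n_particles, seed=seed)
    constrained = run_update_rate_sweep(spec, params, [0.5, 0.75, 1.0],
                                        infer_p=False, resolution=res, **common)
    freed = run_update_rate_sweep(spec, params, [0.5], infer_p=True,
                                  resolution=res, **common)
    att_true = params.attraction_weight
    sig_true = params.noise_sd
    cmean = constrained.records[constrained.records.seed == "mean"].set_index("p_true")
    fmean = freed.records[freed.records.seed == "mean"].set_index("p_true")
    fseed = freed.records[(freed.records.seed != "mean")
                          & (freed.records.p_true == 0.5)]
    p_ok = (fseed["mean_update_prob"] - 0.5).abs() <= 2 * fseed["sd_update_prob"]
    att_ok = (fseed["mean_attraction_weight"] - att_true).abs() \
        <= 2 * fseed["sd_attraction_weight"]
    biases = (cmean["mean_attraction_weight"] - att_true).loc[[0.5, 0.75, 1.0]]
    metrics = {
        "attraction_bias_constrained_half_rate": float(biases.loc[0.5]),
        "attraction_bias_monotone": float(np.all(np.diff(biases.to_numpy()) > 0)),
        "noise_sd_excess_constrained_half_rate": float(
            cmean.loc[0.5, "mean_noise_sd"] - sig_true
        ),
        "noise_sd_freed_half_rate": float(fmean.loc[0.5, "mean_noise_sd"]),
        "update_prob_recovery_fraction": float(p_ok.mean()),
        "attraction_recovery_fraction_freed": float(att_ok.mean()),
        "entropy_freed_minus_constrained": float(
            fmean.loc[0.5, "entropy"] - cmean.loc[0.5, "entropy"]
        ),
        "n": n_seeds,
    }
    return metrics, {"constrained": constrained, "freed": freed}


def _selection_candidates():
    cfg = reference_config()
    spec_full, params_g = cfg.model_spec(), cfg.model_params()
    overrides = _axis_overrides(spec_full)
    spec_noa = ModelSpec(
        "geometric", include_alignment=False, include_attraction=True,
        parameter_axes=default_parameter_axes(
            "geometric", include_alignment=False, overrides=overrides,
        ),
    )
    spec_topo = ModelSpec(
        "topological",
        parameter_axes=default_parameter_axes("topological", overrides={
            k: v for k, v in overrides.items() if k != "interaction_radius"
        }),
    )
    params_noa = params_g.replace(alignment_weight=0.0)
    params_t = ModelParams(
        attraction_weight=params_g.attraction_weight,
        alignment_weight=params_g.alignment_weight,
        neighbour_count=10, blind_angle=params_g.blind_angle,
        noise_sd=params_g.noise_sd, speed=params_g.speed,
        arena_size=params_g.arena_size,
    )
    res_full = REFERENCE_RESOLUTION
    res_noa = {k: v for k, v in res_full.items() if k != "alignment_weight"}
    res_topo = {**{k: v for k, v in res_full.items() if k != "interaction_radius"},
                "neighbour_count": 5}
    return (spec_full, params_g, res_full), (spec_noa, params_noa, res_noa), \
        (spec_topo, params_t, res_topo)


def selection_study(seed: int, n_seeds: int = 5,
                    arms=("random",)) -> Tuple[Dict, Dict[str, ScenarioReport]]:
    """Bayes-factor model selection: alignment presence and neighbourhood scheme."""
    cfg = reference_config()
    full, noa, topo = _selection_candidates()
    common = dict(n_seeds=n_seeds, n_steps=cfg.run.n_steps,
                  n_particles=cfg.run.n_particles, seed=seed, arms=arms,
                  mill_threshold=cfg.run.burn_in.threshold,
                  mill_window=cfg.run.burn_in.window,
                  max_burn_in=cfg.run.burn_in.max_steps)
    rep_align = run_model_selection(
        (("alignment", *full), ("no_alignment", *noa)), **common)
    rep_scheme = run_model_selection(
        (("geometric", *full), ("topological", *topo)), **common)
    metrics: Dict = {"n": n_seeds}
    final_means = {}
    violations = 0
    for rep, (label_pos, label_neg) in (
        (rep_align, ("alignment", "no_alignment")),
        (rep_scheme, ("geometric", "topological")),
    ):
        df = rep.records
        for gen, want_sign in ((label_pos, 1.0), (label_neg, -1.0)):
            per_seed = df[(df.seed != "mean") & (df.generating == gen)
                          & (df.step == cfg.run.n_steps)]
            frac = float((np.sign(per_seed.log_bf) == want_sign).mean())
            metrics[f"sign_correct_{gen}_data"] = frac
            curve = df[(df.seed == "mean") & (df.generating == gen)
                       ].sort_values("step").log_bf.abs().to_numpy()
            violations += int(np.sum(np.diff(curve) < -1e-9))
            final_means[gen] = curve[-1]
    metrics["bf_magnitude_decrease_count"] = violations
    metrics["occam_gap_log_bf"] = float(
        final_means["alignment"] - final_means["no_alignment"]
    )
    return metrics, {"alignment": rep_align, "scheme": rep_scheme}


# ---------------------------------------------------------------------------


def exactness_study(seed: int) -> Dict:
    """Grid-engine exactness against brute-force enumeration and quadrature.

    Sequential updating, batch updating and a naive per-point enumeration of
    Bayes' rule must agree on a small grid; the per-particle transition
    density must integrate to one for pure and mixture forms alike.
    """
    spec = ModelSpec(
        include_alignment=False,
        parameter_axes=default_parameter_axes(include_alignment=False),
    )
    params = ModelParams(attraction_weight=0.9, interaction_radius=5.0,
                         blind_angle=math.pi / 3, noise_sd=0.1, speed=0.3,
                         arena_size=10.0)
    traj = simulate(4, params, spec, 4, seed)
    obs = step_observations(traj)
    grid = make_grid(spec, {"attraction_weight": 2, "interaction_radius": 2,
                            "blind_angle": 2, "noise_sd": 3})
    # sequential
    post_seq = Posterior.from_prior(grid)
    for o in obs:
        post_seq = update_posterior(post_seq, o, spec, params)
    # batch
    post_batch = update_posterior(Posterior.from_prior(grid), obs, spec, params)
    # naive enumeration with scalar likelihoods
    names = grid.names
    values = [grid.values(n) for n in names]
    log_w = np.empty(grid.shape)
    for idx in itertools.product(*[range(v.size) for v in values]):
        kw = dict(zip(names, (v[i] for v, i in zip(values, idx))))
        theta = params.replace(**kw)
        log_w[idx] = grid.prior_log_mass[idx] + sum(
            step_loglik(o, theta, spec) for o in obs
        )
    from scipy.special import logsumexp

    naive = log_w - logsumexp(log_w)
    max_diff = max(
        float(np.max(np.abs(post_seq.log_mass - post_batch.log_mass))),
        float(np.max(np.abs(post_seq.log_mass - naive))),
        abs(post_seq.cumulative_log_evidence - post_batch.cumulative_log_evidence),
        abs(post_seq.cumulative_log_evidence - float(logsumexp(log_w))),
    )
    # transition-density normalization (pure and mixture forms)
    worst = 0.0
    for sigma in (0.05, 0.3, 1.0, 2.0, math.pi, 10.0):
        for p in (1.0, 0.6, 0.25):
            mu = 0.7  # arbitrary offset between predicted and old heading

            def dens(x, sigma=sigma, p=p, mu=mu):
                lp = wrapped_gaussian_logpdf(np.array([x, x - mu]), sigma)
                return p * math.exp(lp[0]) + (1 - p) * math.exp(lp[1])

            total, _ = quad(dens, -math.pi, math.pi, limit=200)
            worst = max(worst, abs(total - 1.0))
    return {
        "posterior_max_abs_log_diff": max_diff,
        "density_normalization_error": worst,
        "n": grid.size,
    }
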