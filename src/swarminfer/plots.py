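"""Static plots of scenario reports (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import ScenarioReport  # noqa: E402

__all__ = ["plot_report", "plot_state"]


def plot_state(state, arena_size: float, path: Union[str, Path]) -> None:
    """Scatter + quiver snapshot of a swarm state."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.quiver(state.positions[:, 0], state.positions[:, 1],
              np.cos(state.headings), np.sin(state.headings),
              color="crimson", width=0.005)
    ax.scatter(state.positions[:, 0], state.positions[:, 1], s=12, c="k")
    ax.set_xlim(0, arena_size)
    ax.set_ylim(0, arena_size)
    ax.set_aspect("equal")
    ax.set_title(f"t = {state.time_index}")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_report(report: ScenarioReport, out_dir: Union[str, Path]) -> None:
    """One summary figure per report: means/SDs (or log BF) per increment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = report.records
    mean_df = df[df["seed"] == "mean"]
    if report.name == "model_selection":
        fig, ax = plt.subplots(figsize=(6, 4))
        for (gen, arm), sub in mean_df.groupby(["generating", "arm"]):
            ax.plot(sub["step"], sub["log_bf"], marker="o", label=f"{gen}/{arm}")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("assimilated steps")
        ax.set_ylabel("cumulative log Bayes factor")
        ax.legend(fontsize=8)
    else:
        x = {"convergence": "step", "noise": "sigma_true",
             "update_rate": "p_true"}[report.name]
        params = sorted(c[5:] for c in df.columns if c.startswith("mean_"))
        n = len(params) + 1
        fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
        group = [c for c in ("arm",) if c in mean_df.columns]
        for i, p in enumerate(params):
            ax = axes[0, i]
            if group:
                for key, sub in mean_df.groupby(group[0]):
                    ax.errorbar(sub[x], sub[f"mean_{p}"], yerr=sub[f"sd_{p}"],
                                marker="o", ms=3, capsize=2, label=str(key))
            else:
                ax.errorbar(mean_df[x], mean_df[f"mean_{p}"],
                            yerr=mean_df[f"sd_{p}"], marker="o", ms=3, capsize=2)
            ax.set_title(p, fontsize=9)
            ax.set_xlabel(x)
        ax = axes[0, -1]
        if group:
            for key, sub in mean_df.groupby(group[0]):
                ax.plot(sub[x], sub["entropy"], marker="o", ms=3, label=str(key))
            ax.legend(fontsize=7)
        else:
            ax.plot(mean_df[x], mean_df["entropy"], marker="o", ms=3)
        if "prior_entropy" in report.config:
            ax.axhline(report.config["prior_entropy"], color="grey", ls="--", lw=0.8)
        ax.set_title("joint entropy", fontsize=9)
        ax.set_xlabel(x)
        fig.tight_layout()
    fig.savefig(out / f"{report.name}.png", dpi=120)
    plt.close(fig)
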