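"""Run reporting: state-wise stream densities, budgets, stationary curves.

Reads only completed run artefacts and writes figures plus a Markdown
summary; it never alters data outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises

from allomove.config import PipelineConfig
from allomove.hmm import HMMParameters
from allomove.hmm.decode import state_names
from allomove.hmm.series import ObservationSeries

__all__ = ["write_report"]

_GAMMA_STREAMS = ("step", "max_depth", "wiggles", "dist_shore")


def _plot_state_densities(params: HMMParameters, series, path: Path) -> None:
    names = state_names(params)
    cbar = float(np.mean([s.csi for s in series]))
    streams = [e.stream for e in params.structure.emissions]
    fig, axes = plt.subplots(1, len(streams), figsize=(3.2 * len(streams), 3))
    for ax, stream in zip(np.atleast_1d(axes), streams):
        pooled = np.concatenate([getattr(s, stream) for s in series])
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            continue
        ax.hist(pooled, bins=40, density=True, color="0.85")
        if stream in _GAMMA_STREAMS:
            grid = np.linspace(pooled.min(), pooled.max(), 200)
            for k, name in enumerate(names):
                shape, rate = params.gamma_shape_rate(stream, k, cbar)
                ax.plot(grid, gamma_dist.pdf(grid, shape, scale=1.0 / rate), label=name)
        else:
            grid = np.linspace(-np.pi, np.pi, 200)
            for k, name in enumerate(names):
                ax.plot(
                    grid,
                    vonmises.pdf(grid, params.turn_kappa(k), loc=params.turn_mean[k]),
                    label=name,
                )
        ax.set_title(stream)
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_budgets(budgets: pd.DataFrame, path: Path) -> None:
    b = budgets.sort_values("csi").set_index("id")
    states = [c for c in b.columns if c != "csi"]
    fig, ax = plt.subplots(figsize=(6, 3))
    bottom = np.zeros(len(b))
    for st in states:
        ax.bar(b.index, b[st], bottom=bottom, label=st)
        bottom += b[st].to_numpy()
    ax.set_ylabel("fraction of intervals")
    ax.set_xlabel("individual (ordered by CSI)")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_curves(curves: pd.DataFrame, path: Path) -> bool:
    have_ci = curves["lo"].notna().any()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, g in curves.groupby("label"):
        ax.plot(g["c"], g["delta"], label=label)
        if have_ci:
            ax.fill_between(g["c"], g["lo"], g["hi"], alpha=0.25)
    ax.set_xlabel("composite stress index")
    ax.set_ylabel("stationary state probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return have_ci


def _plot_emission_means(params: HMMParameters, c_max: float, path: Path) -> None:
    names = state_names(params)
    cov_streams = [
        e.stream for e in params.structure.emissions if e.covariate_on_mean
    ]
    if not cov_streams:
        return
    grid = np.linspace(0.0, c_max, 50)
    fig, axes = plt.subplots(1, len(cov_streams), figsize=(3.2 * len(cov_streams), 3))
    for ax, stream in zip(np.atleast_1d(axes), cov_streams):
        for k, name in enumerate(names):
            ax.plot(grid, [params.emission_mean(stream, k, c) for c in grid], label=name)
        ax.set_title(stream)
        ax.set_xlabel("CSI")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(cfg: PipelineConfig) -> Path:
    run_dir = Path(cfg.run_dir)
    series = ObservationSeries.list_from_csv(cfg.resolve("streams_csv"))
    with open(cfg.resolve("fit_json")) as fh:
        fit_payload = json.load(fh)
    params = HMMParameters.from_dict(fit_payload["parameters"])
    budgets = pd.read_csv(cfg.resolve("budgets_csv"))
    curves = pd.read_csv(cfg.resolve("curves_csv"))

    _plot_state_densities(params, series, run_dir / "fig_state_densities.png")
    _plot_budgets(budgets, run_dir / "fig_activity_budgets.png")
    have_ci = _plot_curves(curves, run_dir / "fig_stationary_curves.png")
    _plot_emission_means(params, cfg.hmm.curve_grid_max, run_dir / "fig_emission_means.png")

    lines = [
        "# Run report",
        "",
        f"- individuals: {len(series)}",
        f"- intervals: {sum(len(s) for s in series)}",
        f"- states: {params.structure.n_states}",
        f"- log-likelihood: {fit_payload['loglik']:.2f}",
        f"- AIC: {fit_payload['aic']:.2f} ({fit_payload['n_params']} parameters)",
        "",
        "## Activity budgets (fraction of decoded intervals)",
        "",
        budgets.round(4).to_markdown(index=False),
        "",
    ]
    if not have_ci:
        lines.append(
            "**Note:** no parameter covariance was available; stationary "
            "curves are drawn without confidence intervals."
        )
    aic_path = cfg.resolve("aic_csv")
    if aic_path.exists():
        lines += ["", "## Model comparison", "", pd.read_csv(aic_path).round(2).to_markdown(index=False)]
    out = cfg.resolve("report_md")
    out.write_text("\n".join(lines) + "\n")
    return out
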