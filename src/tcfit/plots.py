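"""Matplotlib views of fitting runs: parameter trajectories, fitness
curves, scheme error comparison, and voltage-trace overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_fit_history",
    "plot_fitness_curves",
    "plot_error_comparison",
    "plot_overlay",
]

_PARAM_LABELS = (r"$I_{Gi\to Th}$", r"$g_T$", r"$E_T$")


def plot_fit_history(fit, truth=None, path: str | Path | None = None):
    """Per-iteration trajectory of the three fitted parameters."""
    hist = fit.history_frame()
    fig, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True)
    for d, (ax, label) in enumerate(zip(axes, _PARAM_LABELS)):
        ax.plot(hist["k"], hist[f"gbest_x_{d + 1}"], lw=1.2)
        if truth is not None:
            ax.axhline(truth[d], color="k", ls="--", lw=0.8)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("iteration $k$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_fitness_curves(curves: dict, path: str | Path | None = None):
    """Global-best fitness vs iteration, one line per (scheme, seed)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (scheme, seed), curve in curves.items():
        ks, qs = zip(*curve)
        ax.semilogy(ks, np.maximum(qs, 1e-300), lw=1, alpha=0.7,
                    label=f"{scheme} ({seed})")
    ax.set_xlabel("iteration $k$")
    ax.set_ylabel("fitness $q_T$")
    if len(curves) <= 10:
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_error_comparison(report, path: str | Path | None = None):
    """Final ln e_T per scheme (points per seed, bar at the median)."""
    df = report.frame()
    schemes = list(dict.fromkeys(df["scheme"]))
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, s in enumerate(schemes):
        vals = df.loc[df["scheme"] == s, "ln_e_t"]
        ax.scatter([i] * len(vals), vals, s=18, alpha=0.7, zorder=3)
        ax.bar(i, vals.median(), width=0.6, alpha=0.3, zorder=1)
    ax.set_xticks(range(len(schemes)), schemes, rotation=20)
    ax.set_ylabel(r"$\ln e_T$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_overlay(point_report: dict, path: str | Path | None = None):
    """Voltage overlay of original vs reconstructed model with the input."""
    tr = point_report["_traces"]
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.plot(tr["times"], tr["original_v"], "k", lw=0.8, label="original")
    if "reconstructed_v" in tr:
        ax.plot(tr["times"], tr["reconstructed_v"], "r", lw=0.8, alpha=0.7,
                label="reconstructed")
    ax.plot(tr["times"], np.asarray(tr["i_sm"]) * 4 - 110, "b", lw=0.6,
            label="input (scaled)")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("V (mV)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
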