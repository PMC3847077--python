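"""Matplotlib figures for the simulation experiments (PNG/SVG output)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_shell_bias(table: pd.DataFrame, path: str | Path) -> Path:
    """Median stiffness vs shell thickness, one line per erosion count,
    one panel per processing mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = sorted(table["mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(5 * len(modes), 4), sharey=True)
    for ax, mode in zip(axes if len(modes) > 1 else [axes], modes):
        sub = table[table["mode"] == mode]
        for e, grp in sub.groupby("erosions"):
            grp = grp.sort_values("thickness")
            ax.plot(grp["thickness"], grp["median_kPa"], marker="o", label=f"{e} erosions")
        ax.set_xlabel("shell thickness (voxels)")
        ax.set_title(f"{mode} processing")
        ax.legend(fontsize=8)
    (axes[0] if len(modes) > 1 else axes).set_ylabel("median stiffness (kPa)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_precision(summary: pd.DataFrame, path: str | Path) -> Path:
    """Sliding-window median stiffness vs SNR with 10-90 percentile bands,
    one panel per window size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = sorted(summary["window"].unique())
    fig, axes = plt.subplots(1, len(windows), figsize=(4 * len(windows), 3.5), sharey=True)
    for ax, w in zip(axes if len(windows) > 1 else [axes], windows):
        sub = summary[summary["window"] == w].sort_values("snr_mid")
        ax.plot(sub["snr_mid"], sub["median_kPa"], "r-", label="median")
        ax.plot(sub["snr_mid"], sub["p10_kPa"], "g--", label="10th/90th pct")
        ax.plot(sub["snr_mid"], sub["p90_kPa"], "g--")
        ax.set_xlabel("median SNR")
        ax.set_title(f"{w}x{w}x{w} window")
        ax.legend(fontsize=8)
    (axes[0] if len(windows) > 1 else axes).set_ylabel("median stiffness (kPa)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
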