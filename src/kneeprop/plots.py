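"""Diagnostic figures for study reports (matplotlib, optional extra).

Pixel-perfect reproduction of any published figure is not a goal; these are
working plots for inspecting a run: per-participant AME pre/post, IE
distributions per group, and synergy weight bars.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_ame(metrics_df, path) -> None:
    """Pre/post AME per participant, one panel per movement group."""
    plt = _plt()
    groups = sorted(metrics_df["movement_group"].unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(5 * len(groups), 4), squeeze=False)
    for ax, mg in zip(axes[0], groups):
        sub = metrics_df[metrics_df["movement_group"] == mg]
        for _, row in sub.iterrows():
            color = "tab:blue" if row["group"] == "EG" else "tab:orange"
            ax.plot([0, 1], [row["ame_pre"], row["ame_post"]], "o-", color=color, alpha=0.6)
        ax.set_xticks([0, 1], ["pre", "post"])
        ax.set_ylabel("AME (deg)")
        ax.set_title(mg)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ie_violin(metrics_df, path) -> None:
    """IE distributions per study group and movement group."""
    plt = _plt()
    groups = sorted(metrics_df["movement_group"].unique())
    fig, ax = plt.subplots(figsize=(2.5 * len(groups) + 2, 4))
    data, labels = [], []
    for mg in groups:
        for grp in ("EG", "CG"):
            sub = metrics_df[(metrics_df["movement_group"] == mg) & (metrics_df["group"] == grp)]
            data.append(sub["ie"].to_numpy())
            labels.append(f"{mg}\n{grp}")
    ax.violinplot([d if d.size else np.array([0.0]) for d in data], showmedians=True)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.set_ylabel("IE (deg)")
    ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_synergy_weights(W, path, muscle_names=None, title="") -> None:
    """Bar panels of one weight matrix, one panel per synergy."""
    plt = _plt()
    W = np.asarray(W)
    k = W.shape[1]
    names = muscle_names or [f"m{i}" for i in range(W.shape[0])]
    fig, axes = plt.subplots(1, k, figsize=(2.2 * k, 3), squeeze=False, sharey=True)
    for j, ax in enumerate(axes[0]):
        ax.bar(np.arange(W.shape[0]), W[:, j])
        ax.set_xticks(np.arange(W.shape[0]), names, rotation=90, fontsize=7)
        ax.set_title(f"synergy {j + 1}{title}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
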