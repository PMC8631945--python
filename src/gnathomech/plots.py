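"""Figure export: MA curves per species and PC1-PC2 functional space."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

DIET_COLORS = {"herbivore": "tab:green", "omnivore": "tab:orange",
               "carnivore": "tab:red", None: "0.5"}


def plot_ma_curves(curves, diet: dict[str, str] | None, path,
                   fossil_id: str | None = None) -> None:
    """MA against normalized edge position, coloured by diet class."""
    diet = diet or {}
    fig, ax = plt.subplots(figsize=(6, 4))
    seen = set()
    for curve in curves:
        cls = diet.get(curve.specimen_id)
        color = DIET_COLORS.get(cls, "0.5")
        is_fossil = curve.specimen_id == fossil_id
        label = None
        if is_fossil:
            label = fossil_id
        elif cls not in seen:
            label = cls
            seen.add(cls)
        ax.plot(curve.s, curve.ma,
                color="black" if is_fossil else color,
                lw=2.0 if is_fossil else 0.8,
                alpha=1.0 if is_fossil else 0.6, label=label)
    ax.set_xlabel("normalized edge position s (proximal → distal)")
    ax.set_ylabel("mechanical advantage")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pc_scatter(scores: np.ndarray, specimen_ids, diet: dict[str, str] | None,
                    variance_explained: np.ndarray, path,
                    fossil_id: str | None = None, title: str = "PCA") -> None:
    """PC1-PC2 scatter with diet-class colouring and the fossil highlighted."""
    diet = diet or {}
    fig, ax = plt.subplots(figsize=(5, 5))
    seen = set()
    for i, sid in enumerate(specimen_ids):
        cls = diet.get(sid)
        y = scores[i, 1] if scores.shape[1] > 1 else 0.0
        if sid == fossil_id:
            ax.scatter(scores[i, 0], y, marker="*", s=220, color="black",
                       zorder=5, label=fossil_id)
        else:
            label = cls if cls not in seen else None
            seen.add(cls)
            ax.scatter(scores[i, 0], y, color=DIET_COLORS.get(cls, "0.5"),
                       s=30, alpha=0.8, label=label)
    ax.set_xlabel(f"PC1 ({variance_explained[0]:.1f}%)")
    if len(variance_explained) > 1:
        ax.set_ylabel(f"PC2 ({variance_explained[1]:.1f}%)")
    ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
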