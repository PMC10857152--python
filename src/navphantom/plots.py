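"""Basic diagnostic plots for a cohort run (not publication styling)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_landmark_metrics", "plot_dsc_volume"]


def plot_landmark_metrics(landmark_df: pd.DataFrame, path: str | Path) -> None:
    """Box plots of per-case FLE/TRE/FRE (mm) and FN, grouped by position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(13, 3.2), sharey=False)
    for ax, (col, title) in zip(
        axes,
        [
            ("mean_fle", "FLE [mm]"),
            ("mean_tre", "TRE [mm]"),
            ("mean_fre", "FRE [mm]"),
            ("fn", "FN"),
        ],
    ):
        groups = [g for g in ("supine", "prone", "lateral")
                  if g in set(landmark_df["group"])]
        ax.boxplot(
            [landmark_df.loc[landmark_df["group"] == g, col] for g in groups],
            tick_labels=groups,
        )
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dsc_volume(lesion_df: pd.DataFrame, path: str | Path) -> None:
    """Scatter of DSC against lesion volume (cm^3)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    ax.scatter(lesion_df["volume_cm3"], lesion_df["dsc"], s=24)
    ax.set_xlabel("lesion volume [cm$^3$]")
    ax.set_ylabel("DSC")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
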