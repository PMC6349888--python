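"""Optional three-panel visualisation of one run.

Top: similarity matrix heat map.  Middle: events per individual per
window.  Bottom: the state sequence as a coloured ribbon.  Plots are a
convenience; the TSV outputs are the interface of record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["plot_state_dynamics"]


def plot_state_dynamics(result, path: str | Path | None = None):
    """Render similarity matrix, event-rate series and state ribbon."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_max = result.t_max
    fig, axes = plt.subplots(
        3, 1, figsize=(6, 8),
        gridspec_kw={"height_ratios": [4, 1, 0.5]}, constrained_layout=True,
    )

    im = axes[0].imshow(
        result.similarity.sim, origin="lower", cmap="viridis",
        extent=(0.5, t_max + 0.5, 0.5, t_max + 0.5), vmin=0, vmax=1,
    )
    axes[0].set_xlabel("window")
    axes[0].set_ylabel("window")
    fig.colorbar(im, ax=axes[0], label="similarity")

    axes[1].plot(np.arange(1, t_max + 1), result.event_rate, drawstyle="steps-mid")
    axes[1].set_ylabel("events / node")
    axes[1].set_xlim(0.5, t_max + 0.5)

    labels = result.states.labels
    axes[2].imshow(
        labels[np.newaxis, :], aspect="auto", cmap="tab10",
        extent=(0.5, t_max + 0.5, 0, 1), vmin=1, vmax=max(10, labels.max()),
    )
    axes[2].set_yticks([])
    axes[2].set_xlabel("window")
    axes[2].set_title(f"states (C = {result.states.C})", fontsize=10)

    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
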