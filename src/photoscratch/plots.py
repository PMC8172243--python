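"""Standard figures: peri-event heatmap and averaged trace ± SEM."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .perievent import PeriEventMatrix, perievent_average  # noqa: E402


def heatmap(m: PeriEventMatrix, path=None, cmap: str = "viridis"):
    """Trials × time heatmap aligned to bout onset (vertical line at time 0)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        m.values, aspect="auto", cmap=cmap, origin="lower",
        extent=[-m.pre_s, m.post_s, 0.5, m.n_trials + 0.5],
    )
    ax.axvline(0.0, color="w", lw=1, ls="--")
    ax.set_xlabel("time from bout onset (s)")
    ax.set_ylabel("trial")
    fig.colorbar(im, ax=ax, label=m.units)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def average_trace(m: PeriEventMatrix, path=None):
    """Column-wise mean (line) with ± SEM shading and a line at bout onset."""
    mean, sem = perievent_average(m)
    t = m.bin_times()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(t, mean, color="tab:blue")
    ax.fill_between(t, mean - sem, mean + sem, color="gray", alpha=0.4, lw=0)
    ax.axvline(0.0, color="k", lw=1, ls="--")
    ax.set_xlabel("time from bout onset (s)")
    ax.set_ylabel(m.units)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
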