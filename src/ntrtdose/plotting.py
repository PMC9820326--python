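"""Overlay and summary figures (plumbing; nothing quantitative is asserted
on these)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def overlay_map(anatomy_slice: np.ndarray, quantity_slice: np.ndarray, path, title=""):
    """Fuse a scored quantity on an anatomy slice with 25/50/75%-of-max
    contours."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(anatomy_slice.T, cmap="gray", origin="lower")
    q = np.nan_to_num(quantity_slice)
    im = ax.imshow(np.ma.masked_where(q <= 0, q).T, cmap="jet", alpha=0.6, origin="lower")
    if q.max() > 0:
        ax.contour(
            q.T,
            levels=[0.25 * q.max(), 0.5 * q.max(), 0.75 * q.max()],
            colors=["blue", "green", "orange"],
        )
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def ide_bars(ide_table, path):
    """Grouped bars of IDE vs concentration per scenario and field setup."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, (scen, sub) in enumerate(ide_table.groupby("scenario")):
        sub = sub.sort_values("fe_mass_fraction")
        x = np.arange(len(sub)) + 0.25 * i
        ax.bar(x, sub["ide"], width=0.22, yerr=sub["ide_sigma"], label=scen)
    ax.set_xlabel("configuration (increasing FeNP concentration)")
    ax.set_ylabel("IDE")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
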