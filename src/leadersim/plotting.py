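"""Static figure helpers (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_trajectories(log, ax=None):
    """Robot trajectories over the arena, food zones shaded."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    from .world import COLOUR_NAMES, COLOUR_NORM

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    side = log.config.side_length
    for (cx, cy) in log.config.zones:
        ax.add_patch(Circle((cx, cy), log.config.zone_radius,
                            color="0.8", zorder=0))
    for i in range(4):
        if not log.active[i]:
            continue
        ax.plot(log.pos[:, i, 0], log.pos[:, i, 1],
                color=np.clip(COLOUR_NORM[i] * 0.85, 0, 1),
                lw=0.8, label=COLOUR_NAMES[i])
    ax.set_xlim(0, side)
    ax.set_ylim(0, side)
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    return ax


def plot_curves(curves, labels=None, ax=None):
    """Overlay temporal curves against generations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, c in enumerate(curves):
        label = labels[k] if labels else None
        ax.plot(c.generations, c.values, label=label)
    ax.set_xlabel("generation")
    if labels:
        ax.legend(fontsize=8)
    return ax


def plot_vision_bars(vision, labels=None, ax=None):
    """Sorted bar plot of leaders' vision activations, coloured by style."""
    import matplotlib.pyplot as plt

    vision = np.asarray(vision, dtype=float)
    order = np.argsort(vision)
    colours = None
    if labels is not None:
        palette = {"passive": "0.7", "weak_active": "tab:orange",
                   "strong_active": "tab:red"}
        colours = [palette.get(labels[i], "0.4") for i in order]
    if ax is None:
        _, ax = plt.subplots()
    ax.bar(range(len(vision)), vision[order], color=colours)
    ax.set_xlabel("replication (sorted)")
    ax.set_ylabel("vision of leader (steps)")
    return ax
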