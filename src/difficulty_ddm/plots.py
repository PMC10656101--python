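"""Figure helpers for the standard views of difficulty-judgment behavior."""

from __future__ import annotations

import numpy as np

__all__ = ["choice_heatmap", "rt_crisscross", "policy_region_map"]


def choice_heatmap(summary, ax=None):
    """P(choose S1) over the (S1 strength, S2 strength) grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = summary.by_strength.pivot(index="s2", columns="s1", values="p_s1")
    im = ax.imshow(
        tab.to_numpy(), origin="lower", vmin=0, vmax=1, cmap="RdBu_r", aspect="auto"
    )
    ax.set_xticks(range(len(tab.columns)), [f"{c:g}" for c in tab.columns])
    ax.set_yticks(range(len(tab.index)), [f"{c:g}" for c in tab.index])
    ax.set_xlabel("S1 strength")
    ax.set_ylabel("S2 strength")
    ax.figure.colorbar(im, ax=ax, label="P(choose S1)")
    return ax


def rt_crisscross(summary, ax=None):
    """Mean RT versus S1 strength, one line per S2 strength.

    The difference-type models produce the characteristic criss-cross:
    at hard S1 the slowest line is the hard S2 one, at easy S1 it is the
    easy S2 one.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = summary.by_strength
    for s2, sub in tab.groupby("s2"):
        ax.errorbar(
            sub["s1"], sub["mean_rt"], yerr=sub["sem_rt"], label=f"S2={s2:g}"
        )
    ax.set_xlabel("S1 strength")
    ax.set_ylabel("mean RT (s)")
    ax.legend(fontsize="small")
    return ax


def policy_region_map(solution, slice_index: int, ax=None):
    """Action regions over (DV1, DV2) at one sampling slice of the MDP."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = solution.config.dv_grid
    pol = solution.policy[slice_index]
    im = ax.pcolormesh(grid, grid, pol.T, cmap="viridis", vmin=0, vmax=2)
    ax.set_xlabel("DV S1")
    ax.set_ylabel("DV S2")
    t = slice_index * solution.config.dt
    ax.set_title(f"t = {t:.2f} s (0 sample, 1 choose S1, 2 choose S2)")
    ax.figure.colorbar(im, ax=ax, ticks=[0, 1, 2])
    return ax
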