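"""Minimal figures: the two-channel level-colored dot plot and the screening scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cytometry import GateConfig, N_LEVELS, assign_levels
from .io import EventTable

LEVEL_COLORS = ["#999999", "#4477aa", "#66ccee", "#228833", "#ccbb44"]


def dotplot(table: EventTable, gate: GateConfig, path: str, baseline_lc3: float | None = None) -> None:
    """GFP-vs-LC3 dot plot with expression-level coloring and gate boundaries."""
    levels = assign_levels(table, gate)
    fig, ax = plt.subplots(figsize=(5, 5))
    gfp = table.events["gfp"]
    lc3 = table.events["lc3"]
    for lv in range(N_LEVELS):
        mask = levels == lv
        ax.scatter(gfp[mask], lc3[mask], s=2, alpha=0.3, color=LEVEL_COLORS[lv], label=f"Level {lv}")
    for b in gate.gfp_boundaries:
        ax.axvline(b, color="k", lw=0.5)
    if baseline_lc3 is not None:
        ax.axhline(baseline_lc3, color="k", ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("GFP intensity (a.u.)")
    ax.set_ylabel("LC3 intensity (a.u.)")
    ax.legend(markerscale=5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def screen_scatter(results, gag_max: float, vps33a_min: float, path: str) -> None:
    """VPS33A-ratio vs adjusted-GAG-ratio scatter with the hit quadrant marked."""
    vps = np.array([r.vps33a_ratio for r in results])
    gag = np.array([r.sdc1_ratio for r in results])
    hit = np.array([r.flags.get("dual_hit", False) for r in results])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(vps[~hit], gag[~hit], s=4, alpha=0.4, color="#888888")
    ax.scatter(vps[hit], gag[hit], s=10, color="#cc3311", label="dual hit")
    ax.axhline(gag_max, color="k", lw=0.6, ls=":")
    ax.axvline(vps33a_min, color="k", lw=0.6, ls=":")
    ax.scatter([1.0], [1.0], color="#228833", s=30, label="vehicle (1, 1)")
    ax.set_xlabel("VPS33A reporter ratio (drug / vehicle)")
    ax.set_ylabel("GAG reporter ratio, cell-adjusted")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
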