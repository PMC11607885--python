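"""Raw-vs-fitted overlay figures: one panel per study block, raw group
mean (SD) alongside the posterior fitted mean with its 95% credible band,
dark phase shaded ZT12-ZT24, axis ZT6-ZT30."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import PosteriorCurves
from .splines import unwrap_zt

COLORS = {"nonpregnant": "tab:blue", "pregnant": "tab:red"}
UNITS = {"food": "g/h", "water": "g/h", "activity": "m/h", "wake": "fraction awake"}


def behaviour_figure(hourly, curves: PosteriorCurves, path) -> None:
    blocks = sorted({b for _, b in curves.draws})
    fig, axes = plt.subplots(1, len(blocks), figsize=(4.2 * len(blocks), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    sub = hourly[(hourly["behaviour"] == curves.behaviour) & (hourly["phase"] == "study")]
    for ax, block in zip(axes, blocks):
        ax.axvspan(12, 24, color="0.92", zorder=0)
        for group in ("nonpregnant", "pregnant"):
            raw = sub[(sub["group"] == group) & (sub["study_block"] == block)].copy()
            if not raw.empty:
                raw["t"] = unwrap_zt(raw["zt_hour"].to_numpy(float) + 0.5)
                per_mouse = raw.groupby(["mouse_id", "t"])["value"].mean()
                m = per_mouse.groupby("t").mean()
                sd = per_mouse.groupby("t").std()
                ax.errorbar(m.index, m.values, yerr=sd.values, fmt="o", ms=2.5,
                            color=COLORS[group], alpha=0.45, lw=0.8)
            d = curves.draws[(group, block)]
            ax.plot(curves.zt_grid, d.mean(axis=0), color=COLORS[group], label=group)
            ax.plot(curves.zt_grid, np.quantile(d, 0.025, axis=0), "--", lw=0.8, color=COLORS[group])
            ax.plot(curves.zt_grid, np.quantile(d, 0.975, axis=0), "--", lw=0.8, color=COLORS[group])
        ax.set_xlim(6, 30)
        ax.set_xticks(range(6, 31, 4))
        ax.set_xlabel("ZT (h)")
        ax.set_title(f"block {block}")
    axes[0].set_ylabel(f"{curves.behaviour} ({UNITS[curves.behaviour]})")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
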