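"""Cosmetic plots of the policy grid and selectivity sweep.

CSV/JSON are the canonical outputs; these figures are quick visual checks.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_grid(result, path) -> None:
    """Acceptance and completion probability vs Test percentile, per cell."""
    scenarios = list(dict.fromkeys(c.scenario for c in result.cells))
    policies = list(dict.fromkeys(c.policy for c in result.cells))
    fig, axes = plt.subplots(
        len(scenarios), len(policies),
        figsize=(3.2 * len(policies), 2.6 * len(scenarios)),
        sharex=True, sharey=True, squeeze=False,
    )
    by_key = {(c.scenario, c.policy): c for c in result.cells}
    for i, sc in enumerate(scenarios):
        for j, po in enumerate(policies):
            cell = by_key[(sc, po)]
            ax = axes[i][j]
            ax.plot(cell.curve.bin_centers, cell.curve.acceptance_rate,
                    lw=1, color="tab:gray", label="P(accept)")
            ax.plot(cell.curve.bin_centers, cell.curve.completion_rate,
                    lw=1.5, color="tab:blue", label="P(complete | accepted)")
            stars = "**" if cell.report.curve_p < 0.001 else ""
            ax.text(0.03, 0.92, f"r = {cell.report.curve_r:.3f}{stars}",
                    transform=ax.transAxes, fontsize=8, va="top")
            ax.text(0.97, 0.05, f"{cell.report.completion_pct:.1f}%",
                    transform=ax.transAxes, fontsize=8, ha="right")
            if i == 0:
                ax.set_title(po, fontsize=9)
            if j == 0:
                ax.set_ylabel(sc, fontsize=8)
            ax.set_ylim(-0.02, 1.02)
    axes[-1][len(policies) // 2].set_xlabel("Test percentile")
    axes[0][0].legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(result, path) -> None:
    """Completion-curve slope vs acceptance percentage, per scenario."""
    df = result.to_dataframe()
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for sc, grp in df.groupby("scenario", sort=False):
        ax.plot(100 * grp["fraction"], grp["slope"], marker="o", ms=3, label=sc)
    ax.axhline(0, color="k", lw=0.7)
    ax.axvline(10, color="k", lw=0.7, ls="--")
    ax.set_xlabel("acceptance percentage")
    ax.set_ylabel("slope (% completion per Test percentile)")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
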