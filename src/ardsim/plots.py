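"""Optional figures: cohort index responses (blue) against relative risk (red)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

PANEL_INDICES = ("dynamic_strain", "tidal_recruitment", "mechanical_power")


def plot_sweep_panels(condition_table, risk_frame, out_path,
                      indices=PANEL_INDICES):
    """Grid of index-vs-condition panels, one column per intervention."""
    interventions = sorted(condition_table["intervention_id"].unique())
    fig, axes = plt.subplots(len(indices), len(interventions),
                             figsize=(4 * len(interventions), 3 * len(indices)),
                             squeeze=False)
    for j, iid in enumerate(interventions):
        grp = condition_table[condition_table["intervention_id"] == iid]
        risks = risk_frame[risk_frame["intervention_id"] == iid]
        for i, index in enumerate(indices):
            ax = axes[i][j]
            sub = grp[grp["index"] == index].sort_values("delta_p")
            ax.errorbar(sub["delta_p"], sub["mean"], yerr=sub["sd"],
                        fmt="x-", color="tab:blue", capsize=3)
            ax.set_xlabel("driving pressure (cmH2O)")
            ax.set_ylabel(index.replace("_", " "))
            if not risks.empty:
                ax2 = ax.twinx()
                r = risks.sort_values("delta_p")
                ax2.plot(r["delta_p"], r["relative_risk"], "o--",
                         color="tab:red", alpha=0.7)
                ax2.set_ylabel("relative risk", color="tab:red")
            if i == 0:
                ax.set_title(f"intervention {iid}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
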