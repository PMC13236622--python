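"""Figures for the simulated sweep.

Produces (a) box plots of the per-profile VPDR distributions by diameter
and separation for each direction, and (b) a stacked bar chart of per-arc
MU contributions for the reference cohort.  Requires matplotlib (the
``plot`` extra); outputs PNG files under results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from latticedose.plan_metrics import arc_fractions
from latticedose.reference_tables import load_plan_table, plans_from_table
from latticedose.workflow import SweepConfig, run_sweep, write_reports

OUT = Path(__file__).resolve().parent.parent / "results"


def load_or_run(seed: int) -> pd.DataFrame:
    path = OUT / "sweep_vpdr_values.csv"
    if path.exists():
        return pd.read_csv(path, comment="#")
    write_reports(run_sweep(SweepConfig(seed=seed)), OUT)
    return pd.read_csv(path, comment="#")


def main(seed: int = 0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = OUT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    values = load_or_run(seed)

    # VPDR distributions per direction (non-coplanar mode)
    ncp = values[values["mode"] == "noncoplanar"]
    fig, axes = plt.subplots(1, 3, figsize=(14, 4), sharey=True)
    for ax, direction in zip(axes, ("AP", "LAT", "SI")):
        sub = ncp[ncp["direction"] == direction]
        groups, labels = [], []
        for (d, s), g in sub.groupby(["diameter_cm", "separation_cm"]):
            groups.append(g["vpdr_pct"].to_numpy())
            labels.append(f"{d:g}/{s:g}")
        ax.boxplot(groups, tick_labels=labels)
        ax.set_title(f"{direction} VPDR by diameter/separation (cm)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        ax.set_ylabel("VPDR (%)")
    fig.tight_layout()
    fig.savefig(figdir / "vpdr_boxplots.png", dpi=150)
    plt.close(fig)

    # per-arc MU stacked bars for the reference cohort
    table = load_plan_table()
    plans = plans_from_table(table)
    labels = [f"D{r.diameter_cm:g}_S{r.separation_cm:g}"
              for _, r in table.iterrows()]
    fracs = pd.DataFrame([arc_fractions(p) for p in plans],
                         columns=["couch 0", "couch 315", "couch 45",
                                  "couch 90"])
    mu = table["total_mu"].to_numpy()
    fig, ax = plt.subplots(figsize=(12, 4))
    bottom = 0.0 * mu
    for col in fracs.columns:
        part = fracs[col].to_numpy() / 100.0 * mu
        ax.bar(labels, part, bottom=bottom, label=col)
        bottom = bottom + part
    ax.set_ylabel("MU")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.legend(fontsize=8)
    ax.set_title("Per-arc MU contribution by configuration")
    fig.tight_layout()
    fig.savefig(figdir / "mu_distribution.png", dpi=150)
    plt.close(fig)
    print(f"wrote figures to {figdir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
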