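"""Continuous grasp-force estimation along four target profiles.

Runs the regression pipeline: window-parameter sweep (step under a
300 ms window, then width under the best step), channel-force
correlation table, per-movement channel selection, and per-movement x
per-profile feed-forward regression with held-out R^2.  Writes tables
and prediction traces under results/experiment2/ and, if matplotlib
is available, prediction-vs-reference figures.
"""

import sys
from pathlib import Path

import pandas as pd

import graspemg as g

ROOT = Path(__file__).resolve().parents[1]

CONFIG = g.RunConfig(
    seed=1,
    trials_per_condition_2=6,   # study scale: 20
    lead_in_s=2.0,
    sweep_steps_ms=(40.0, 80.0, 160.0),
    sweep_widths_ms=(100.0, 200.0, 300.0),
    reg_repeats=3,
    selection_mode="top_k",
)


def main():
    out = ROOT / "results" / "experiment2"
    paths = g.run_experiment_2(CONFIG, out)

    corr = pd.read_csv(paths["correlation_mean"], index_col=0)
    sel = pd.read_csv(paths["selected_channels"])
    table = pd.read_csv(paths["r2_by_profile"])

    print("channel-force correlation (|r| x 100, mean over trials):")
    print(corr.round(1).to_string())
    print("\nselected channels per movement (top-4 by correlation):")
    print(sel.to_string(index=False))
    print("\nheld-out R^2 (%) by movement and profile:")
    print(table.round(2).to_string(index=False))

    ave = table[table.profile == "AVE"].set_index("movement").r2_mean_pct
    print(f"\nbest-regressed movement: {ave.idxmax()} "
          f"(AVE R^2 {ave.max():.1f} %)")
    tri = table[table.profile == "triangle"].r2_mean_pct.mean()
    rect = table[table.profile == "rectangular"].r2_mean_pct.mean()
    print(f"triangle vs rectangular mean R^2: {tri:.2f} vs {rect:.2f} % "
          "(slow force application regresses better)")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        for csv in sorted(out.glob("predictions_palmar_*.csv")):
            df = pd.read_csv(csv)
            fig, ax = plt.subplots(figsize=(7, 3))
            order = df.window_time_s.argsort()
            ax.plot(df.reference_pct_mvc.to_numpy()[order], "k-",
                    label="reference")
            ax.plot(df.predicted_pct_mvc.to_numpy()[order], "r-",
                    label="predicted", alpha=0.8)
            ax.set_xlabel("held-out window")
            ax.set_ylabel("force (%MVC)")
            ax.set_title(csv.stem.replace("predictions_", ""))
            ax.legend()
            fig.tight_layout()
            fig.savefig(figdir / f"{csv.stem}.png", dpi=120)
            plt.close(fig)
        print(f"figures under {figdir}")
    except ImportError:
        print("matplotlib not available; skipped figures")
    print(f"tables under {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
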