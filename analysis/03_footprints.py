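"""Summarize population-level cognitive footprints from the fitted run.

Reads the footprint tables written by 02_fit_models.py, applies the
50%-credibility reporting filter, and prints the reportable footprints per
outcome (person-Z-scores; persons for the binary prospective-memory test),
extrapolated to an illustrative synthetic population of 24.6 million aged
40-70 with cohort exposure prevalence stratified by age and sex.  Also
draws a simple forest-style plot per outcome (descending |footprint|,
negative effects in red) under results/run/figures/.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"


def plot_footprints(df: pd.DataFrame, title: str, path: Path) -> None:
    df = df.sort_values("footprint")
    fp = df["footprint"].to_numpy()
    colors = ["#b2182b" if v < 0 else "#2166ac" for v in fp]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.2))
    ax.barh(df["target"].to_numpy(), fp, color=colors)
    ax.errorbar(
        fp, np.arange(len(df)),
        xerr=[fp - df["ci_low"].to_numpy(), df["ci_high"].to_numpy() - fp],
        fmt="none", ecolor="k", elinewidth=1, capsize=2,
    )
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("cognitive footprint (person·Z-scores)")
    ax.set_title(title + "\n(exploratory upper bounds)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    files = sorted(RUN.glob("footprints_*.csv"))
    if not files:
        sys.exit("no footprint tables found; run 02_fit_models.py first")
    figdir = RUN / "figures"
    figdir.mkdir(exist_ok=True)
    for f in files:
        df = pd.read_csv(f)
        rep = df[df["reportable"]]
        label = f.stem.removeprefix("footprints_")
        print(f"\n{label}: {len(rep)}/{len(df)} medications reportable "
              "(50% credible interval excludes zero)")
        if len(rep):
            cols = ["target", "footprint", "ci_low", "ci_high"]
            print(rep[cols].to_string(index=False, float_format="%.0f"))
            plot_footprints(rep, label, figdir / f"{label}.png")
    print(f"\nfigures in {figdir}")


if __name__ == "__main__":
    main()
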