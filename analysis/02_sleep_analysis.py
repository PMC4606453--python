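"""Score sleep/wake measures on the simulated recording and compare epochs.

Reads results/data/sleep_activity.csv, computes the six per-larva measures
for each day/night epoch, tests day-vs-night sleep by one-way ANOVA, and
writes the summary tables under results/.
"""

from pathlib import Path

import pandas as pd

from larvasleep import sleep_metrics as sm
from larvasleep import stats as lstats
from larvasleep.io_tracking import EpochSchedule, read_activity_table, write_summary

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    matrix = read_activity_table(DATA / "sleep_activity.csv")
    sched = EpochSchedule(start_day=5)
    summary = sm.summarize_all(matrix, sched)
    write_summary(summary, ROOT / "sleep_summary.csv")

    for epoch, g in summary.groupby("epoch"):
        print(
            f"{epoch}: sleep {g['sleep'].mean():.0f} ± {g['sleep'].sem():.0f} min, "
            f"{g['bout_count'].mean():.1f} bouts of {g['mean_bout_length'].mean():.1f} min, "
            f"waking activity {g['waking_activity'].mean():.1f} s/min"
        )

    nights = [g["sleep"].to_numpy() for e, g in summary.groupby("epoch") if e.startswith("night")]
    days = [g["sleep"].to_numpy() for e, g in summary.groupby("epoch") if e.startswith("day")]
    res = lstats.one_way_anova(days + nights)
    print(
        f"\nday-vs-night sleep, one-way ANOVA: F({res.df_between}, {res.df_within}) "
        f"= {res.f_statistic:.1f}, p = {res.p_value:.3g}"
    )
    write_summary(
        pd.DataFrame(
            [{"F": res.f_statistic, "df_between": res.df_between,
              "df_within": res.df_within, "p": res.p_value}]
        ),
        ROOT / "sleep_anova.csv",
    )


if __name__ == "__main__":
    main()
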