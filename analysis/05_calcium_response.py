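"""Stimulus-locked ΔF/F analysis of the simulated calcium trials.

Computes per-trial ΔF/F for the stimulated and control conditions,
aggregates per neuron and per condition, and tests the condition
difference with one-way ANOVA on trial values.
"""

from pathlib import Path

from larvasleep import calcium_dff as cd
from larvasleep import stats as lstats
from larvasleep.io_tracking import write_summary

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    trials = cd.read_calcium_table(DATA / "calcium_traces.csv")
    by_neuron = cd.aggregate_dff(trials, by="neuron")
    by_condition = cd.aggregate_dff(trials, by="condition")
    write_summary(by_neuron.table, ROOT / "dff_by_neuron.csv")
    write_summary(by_condition.table, ROOT / "dff_by_condition.csv")

    for _, row in by_condition.table.iterrows():
        print(
            f"{row['group']}: ΔF/F = {row['mean_dff_pct']:.1f} ± "
            f"{row['sem_dff_pct']:.1f} % (n = {row['n_trials']} trials)"
        )

    groups = {}
    for t in trials:
        groups.setdefault(t.condition, []).append(cd.dff_trial(t))
    res = lstats.one_way_anova(list(groups.values()))
    print(
        f"\ncondition difference, one-way ANOVA: F({res.df_between}, "
        f"{res.df_within}) = {res.f_statistic:.1f}, p = {res.p_value:.2g}"
    )


if __name__ == "__main__":
    main()
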