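"""Generate the synthetic study datasets every downstream driver consumes.

Writes one bundle per assay under scratch/synthetic/ in the same delimited
formats the package readers accept: a 2-night sleep recording, two tap
experiments with different planted arousal thresholds, one optogenetic
night with a transgenic and a wild-type group, and calcium trials for a
stimulated and a control condition.
"""

from pathlib import Path

from larvasleep import synthetic_data as sd
from larvasleep.calcium_dff import write_calcium_table
from larvasleep.io_tracking import (
    EpochSchedule,
    write_activity_table,
    write_plate_map,
    write_stimulus_log,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 20150901  # one seed for the whole worked analysis


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # sleep: 48 larvae, 2 full light/dark days starting day 5
    sched = EpochSchedule(start_day=5)
    m = sd.simulate_sleep_wake(
        sd.SleepSimParams(n_larvae=48, duration_h=48.0, schedule=sched, seed=SEED)
    )
    write_activity_table(m, OUT / "sleep_activity.csv")
    print(f"sleep: {m.n_larvae} larvae x {m.n_bins} min -> sleep_activity.csv")

    # arousal: sibling-control group (ETP50 3.1) vs mutant-like group (2.1)
    for offset, (name, etp50, top) in enumerate(
        [("sibling", 3.1, 0.34), ("mutant", 2.1, 0.43)]
    ):
        mt, log = sd.simulate_tap_experiment(
            sd.TapSimParams(etp50=etp50, top=top, seed=SEED + 1 + offset)
        )
        write_activity_table(mt, OUT / f"tap_activity_{name}.csv")
        write_stimulus_log(log, OUT / f"tap_events_{name}.csv")
        print(f"tap {name}: planted ETP50 {etp50}, top {top}")

    # optogenetics: ChR2 transgenics respond more and peak higher/earlier
    genotypes = {
        "wt": sd.OptoGenotypeParams(peak_rate=2.0, rise_time_min=15.0),
        "chr2": sd.OptoGenotypeParams(peak_rate=2.9, rise_time_min=12.0),
    }
    mo, logo, plate = sd.simulate_opto_night(
        sd.OptoSimParams(genotypes=genotypes, seed=SEED)
    )
    write_activity_table(mo, OUT / "opto_activity.csv")
    write_stimulus_log(logo, OUT / "opto_events.csv")
    write_plate_map(plate, OUT / "opto_plate_map.csv")
    print(f"opto: {mo.n_larvae} larvae, {len(logo.of_kind('light_on'))} light trials")

    # calcium: stimulated condition with 30% transients vs flat control
    trials = sd.simulate_calcium(
        sd.CalciumSimParams(condition="chr2", amplitude_pct=30.0, n_neurons=4, seed=SEED)
    ) + sd.simulate_calcium(
        sd.CalciumSimParams(condition="control", amplitude_pct=0.0, n_neurons=5, seed=SEED + 1)
    )
    write_calcium_table(trials, OUT / "calcium_traces.csv")
    print(f"calcium: {len(trials)} trials -> calcium_traces.csv")


if __name__ == "__main__":
    main()
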