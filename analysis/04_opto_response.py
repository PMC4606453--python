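"""Optogenetic light-response analysis of the simulated night.

Extracts baseline/response windows around each light trial, computes
baseline-normalized activity per larva, genotype percent-of-wild-type,
and the response dynamics (A, T_A) per genotype.
"""

from pathlib import Path

from larvasleep import optogenetic_assay as oa
from larvasleep.io_tracking import (
    read_activity_table,
    read_plate_map,
    read_stimulus_log,
    write_summary,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"


def main() -> None:
    matrix = read_activity_table(DATA / "opto_activity.csv")
    log = read_stimulus_log(DATA / "opto_events.csv")
    plate = read_plate_map(DATA / "opto_plate_map.csv")

    windows = oa.extract_windows(matrix, log)
    ratios = oa.normalize_light_activity(windows, matrix, plate)
    pct = oa.genotype_percent(ratios, "wt")
    dyn = oa.response_dynamics(matrix, windows, plate)

    write_summary(ratios, ROOT / "opto_ratios.csv")
    write_summary(dyn, ROOT / "opto_dynamics.csv")
    write_summary(pct.rename("percent_of_wt").reset_index(), ROOT / "opto_percent.csv")

    for _, row in dyn.iterrows():
        g = row["genotype"]
        print(
            f"{g}: normalized activity {pct[g]:.0f}% of wt, "
            f"A = {row['A']:.2f} s/bin, T_A = {row['T_A_min']:.1f} min"
        )
    print(
        f"\nchr2 vs wt activity change during blue light: "
        f"{pct['chr2'] - 100:+.0f}% over {len(windows)} trials"
    )


if __name__ == "__main__":
    main()
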