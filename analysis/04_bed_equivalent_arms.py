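"""Hypofractionation comparison across nominally BED-equivalent arms.

Five weekday schedules near BED = 60 Gy at alpha/beta = 10 Gy (25x2.0,
20x2.4, 15x3.0, 10x4.2, 5x7.0) are run on the D4 distribution (centered at
alpha/beta = 10 Gy) with 15%/day uniform repopulation.  Classical BED theory
calls these equivalent; with intratumoral heterogeneity, larger doses per
fraction kill more cells AND induce smaller resistance shifts — selection
penalizes protracted low-dose courses twice.

Writes results/bed_equivalent_arms.csv.
"""

from pathlib import Path

import pandas as pd

from lqhet import (
    FractionationSchedule,
    RepopulationModel,
    fixture_tumors,
    resistance_shift,
    simulate_course,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

ARMS = [(25, 2.0), (20, 2.4), (15, 3.0), (10, 4.2), (5, 7.0)]


def main() -> None:
    state = fixture_tumors()["D4"]
    model = RepopulationModel.uniform(0.15)

    rows = []
    for n, d in ARMS:
        sched = FractionationSchedule.weekday(n, d)
        traj = simulate_course(state, sched, model)
        shifts = resistance_shift(traj)
        rows.append(
            {
                "schedule": sched.to_spec(),
                "dose_per_fraction_gy": d,
                "total_dose_gy": sched.total_dose,
                "bed_gy_at_ratio_10": sched.bed(10.0),
                "end_day": sched.last_day,
                "end_survival": traj.final.total_cells / state.total_cells,
                "end_sf2_shift": float(shifts["sf2_shift"].iloc[-1]),
                "end_alpha_beta_shift": float(shifts["alpha_beta_shift"].iloc[-1]),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "bed_equivalent_arms.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    assert table["end_survival"].is_monotonic_decreasing
    assert table["end_sf2_shift"].is_monotonic_decreasing
    print(
        "\nDespite near-identical BED, end-of-course survival falls and the "
        "induced SF2 shift shrinks monotonically as dose per fraction grows: "
        "hypofractionation kills more and selects less."
    )


if __name__ == "__main__":
    main()
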