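"""Accelerated repopulation from resistance-coupled growth rates.

Compares survival trajectories under uniform 15%/day repopulation against
coupled models (mu = 0.3/day, theta = 5.5) in which either resistant or
sensitive cells repopulate faster, for a standard 25 x 2 Gy course and a
BED-equivalent hypofractionated 15 x 3 Gy course on the D4 tumor.  When
resistant cells grow faster, the survival curve rides above the uniform
curve and the effective growth rate rises as treatment selects for the
fast-growing resistant subsets — the signature of accelerated repopulation.
Shorter courses leave less time for this to develop.

Writes results/repopulation_modes.csv.
"""

from pathlib import Path

import pandas as pd

from lqhet import (
    FractionationSchedule,
    RepopulationModel,
    fixture_tumors,
    simulate_course,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

MODELS = {
    "uniform_15pct": RepopulationModel.uniform(0.15),
    "resistant_faster": RepopulationModel.resistant_faster(0.3, 5.5),
    "sensitive_faster": RepopulationModel.sensitive_faster(0.3, 5.5),
}
SCHEDULES = ["25x2.0:weekday", "15x3.0:weekday"]


def main() -> None:
    state = fixture_tumors()["D4"]

    frames = []
    for spec in SCHEDULES:
        sched = FractionationSchedule.from_spec(spec)
        for mode, model in MODELS.items():
            traj = simulate_course(state, sched, model)
            df = traj.to_frame()[["day", "total_cells", "mean_sf2"]]
            df.insert(0, "repopulation", mode)
            df.insert(0, "schedule", sched.to_spec())
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "repopulation_modes.csv", index=False)

    ends = (
        table.groupby(["schedule", "repopulation"])
        .last()[["total_cells"]]
        .unstack("repopulation")["total_cells"]
    )
    print(ends.to_string(float_format=lambda v: f"{v:.4g}"))
    for sched, row in ends.iterrows():
        assert row["resistant_faster"] > row["uniform_15pct"] > row["sensitive_faster"]
    long, short = ends.loc["25x2:weekday"], ends.loc["15x3:weekday"]
    print(
        "\nFaster-growing resistant cells push end-of-course survival above the "
        f"uniform curve by {long['resistant_faster']/long['uniform_15pct']:.1f}x over "
        f"the 25-fraction course but only {short['resistant_faster']/short['uniform_15pct']:.1f}x "
        "over the 15-fraction course: protraction amplifies accelerated repopulation."
    )


if __name__ == "__main__":
    main()
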