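"""Sensitivity of induced resistance to the distribution center and width.

Runs the standard 35 x 2 Gy weekday course over the named distributions:
D1-D4 vary the (alpha_c, beta_c) center at fixed widths (lowering alpha
moves the population into the dose range where selection is strongest),
while D5/D6 narrow/widen sigma_alpha at the fixed alpha/beta = 10 Gy center.
Reports end-of-course shifts in mean SF2 and mean alpha/beta, and end
survival.

Writes results/center_width_sweeps.csv.
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


def main() -> None:
    schedule = FractionationSchedule.weekday(35, 2.0)
    model = RepopulationModel.uniform(0.15)
    tumors = fixture_tumors()

    rows = []
    for name in ("D1", "D2", "D3", "D4", "D5", "D6"):
        state = tumors[name]
        traj = simulate_course(state, schedule, model)
        shifts = resistance_shift(traj)
        p = state.grid.params
        rows.append(
            {
                "distribution": name,
                "alpha_c": p.alpha_c,
                "beta_c": p.beta_c,
                "sigma_alpha": p.sigma_alpha,
                "center_ratio_gy": p.alpha_c / p.beta_c,
                "end_survival": traj.final.total_cells / state.total_cells,
                "end_sf2_shift": float(shifts["sf2_shift"].iloc[-1]),
                "end_alpha_beta_shift": float(shifts["alpha_beta_shift"].iloc[-1]),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "center_width_sweeps.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

    d3, d2 = table.set_index("distribution").loc["D3"], table.set_index("distribution").loc["D2"]
    d5, d6 = table.set_index("distribution").loc["D5"], table.set_index("distribution").loc["D6"]
    print(
        f"\nLowering alpha (D3 shift {d3.end_sf2_shift:.3f}) induces more resistance "
        f"than raising beta (D2 shift {d2.end_sf2_shift:.3f}): at 2 Gy the linear "
        "term dominates selection."
    )
    print(
        f"The wider distribution D6 (shift {d6.end_sf2_shift:.3f}, survival "
        f"{d6.end_survival:.2e}) ends more resistant and less depleted than the "
        f"tighter D5 (shift {d5.end_sf2_shift:.3f}, survival {d5.end_survival:.2e})."
    )


if __name__ == "__main__":
    main()
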