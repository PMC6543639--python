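"""Pre/post radiosensitivity summaries for the four fitted cell lines.

For each published pre-treatment distribution (identified by its alpha_c;
widths shared within each experiment) and its conditioning course, tabulate
mean +/- SD of the alpha/beta ratio and SF2 before and at the end of
treatment.  Selection alone — per-fraction LQ re-weighting of the
distribution, no repopulation — produces the characteristic drop in
alpha/beta and rise in SF2.

Writes results/assay_shift_table.csv.
"""

from pathlib import Path

import pandas as pd

from lqhet import FractionationSchedule, GaussianHeterogeneityParams, tabulate_shift

RESULTS = Path(__file__).resolve().parents[1] / "results"

LINES = [
    # (label, params, conditioning course)
    ("esophageal (alpha_c=0.40)",
     GaussianHeterogeneityParams(0.40, 0.020, 6.5e-2, 3.5e-3),
     FractionationSchedule.weekday(25, 2.0)),
    ("prostate alpha_c=0.43",
     GaussianHeterogeneityParams(0.43, 0.020, 1.0e-1, 3.5e-3),
     FractionationSchedule.weekday(5, 2.0)),
    ("prostate alpha_c=0.35",
     GaussianHeterogeneityParams(0.35, 0.020, 1.0e-1, 3.5e-3),
     FractionationSchedule.weekday(5, 2.0)),
    ("prostate alpha_c=0.30",
     GaussianHeterogeneityParams(0.30, 0.020, 1.0e-1, 3.5e-3),
     FractionationSchedule.weekday(5, 2.0)),
]


def main() -> None:
    rows = []
    for label, params, course in LINES:
        row = tabulate_shift(params, course).iloc[0].to_dict()
        rows.append({"line": label, "alpha_c": params.alpha_c, **row})
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "assay_shift_table.csv", index=False)
    with pd.option_context("display.width", 200):
        print(table.round(3).to_string(index=False))
    print(
        "\nEvery line shifts toward resistance: alpha/beta falls and SF2 rises "
        "by the end of its course, with the 25-fraction course producing the "
        "largest shift."
    )


if __name__ == "__main__":
    main()
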