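# lqhet

Radiotherapy response modelling for tumors with **heterogeneous innate
radiosensitivity**.  Classical radiobiology assigns one linear-quadratic
(LQ) parameter pair to a tumor; `lqhet` instead evolves a continuous
intratumoral distribution of (α, β) through a fractionated course and
quantifies what selection does to it.  It is aimed at radiobiology
modellers and medical physicists who want to ask: how much resistance does
a treatment schedule *induce*, and which nominally isoeffective schedule
induces least?

## The model

Survival of a subset with coefficients (α, β) after `n` fractions of dose
`d` follows the LQ law

    SF(d) = exp(−n d (α + β d)),

and the tumor is a bivariate Gaussian mixture of such subsets,

    f(α, β) = exp(−((α−α_c)²/2σ_α² + (β−β_c)²/2σ_β²)),

truncated at `f < 10⁻²` and normalized to 100% of the population.  Each
fraction re-weights the distribution by per-subset survival (selection);
each calendar day multiplies counts by a repopulation rate, either uniform
(default 15%/day) or coupled to resistance via
`p(α, β) = μ e^{θ·SF₂} / max e^{θ·SF₂}`.  Schedules are compared at equal
biologically effective dose, `BED = n d (1 + d/(α/β))`.

Consequences the package reproduces and tests: fractionation steadily
lowers the mean α/β ratio and raises the mean SF₂ (treatment-induced
radioresistance); an initially ~1% resistant subpopulation dominates the
tumor after a standard 70 Gy course; BED-equivalent schedules are *not*
equivalent under heterogeneity — larger doses per fraction kill more and
select less; and resistance-coupled growth reproduces accelerated
repopulation.

## Worked example

```python
from lqhet import (GaussianHeterogeneityParams, GridConfig, build_grid,
                   summarize, FractionationSchedule, TumorState,
                   RepopulationModel, simulate_course)

params = GaussianHeterogeneityParams(alpha_c=0.40, beta_c=0.020,
                                     sigma_alpha=6.5e-2, sigma_beta=3.5e-3)
grid = build_grid(params, GridConfig(cutoff=1e-2, resolution=201))
pre = summarize(grid)
print(f"pre-treatment: mean alpha/beta {pre.mean_alpha_beta_ratio:.1f} Gy, "
      f"mean SF2 {pre.mean_sf2:.3f}")

course = FractionationSchedule.weekday(35, 2.0)   # 70 Gy, 5-on/2-off
traj = simulate_course(TumorState(grid, 1e10), course,
                       RepopulationModel.uniform(0.15))
post = traj.final.summary
print(f"end of course (day {traj.final.day}): mean SF2 {post.mean_sf2:.3f}, "
      f"resistant (SF2>=0.55) fraction {post.bin_fractions[(0.55, 1.0)]:.3f}, "
      f"{traj.final.total_cells:.3g} cells remain")
```

prints

```
pre-treatment: mean alpha/beta 20.6 Gy, mean SF2 0.418
end of course (day 47): mean SF2 0.577, resistant (SF2>=0.55) fraction 0.836, 498 cells remain
```

— the tumor enters treatment with a mean α/β of 20.6 Gy and a 1.3%
resistant minority, and leaves it with that minority grown to 84% of the
surviving population: each further 2 Gy fraction is now markedly less
effective than the first ones were.

The same run from the shell:

```sh
lqhet simulate --params 0.40,0.02,0.065,0.0035 \
      --schedule 35x2.0:weekday --repopulation uniform:0.15 --outdir run/
```

Other subcommands: `compare-schedules` (BED-equivalent arm tables), `fit`
(clonogenic measurement CSV → distribution parameters), `generate`
(synthetic assays with ground truth), `summarize`, `run-config`.

## Analysis scripts

The numbered drivers under `analysis/` rebuild the package's headline
tables into `results/`:

| script | writes |
| --- | --- |
| `01_assay_shift_table.py` | pre/post α/β and SF₂ summaries for the four fitted cell lines |
| `02_standard_course.py` | composition trajectory of the 70 Gy standard course |
| `03_center_width_sweeps.py` | induced resistance vs distribution center and width |
| `04_bed_equivalent_arms.py` | five BED≈60 Gy arms: survival and shift orderings |
| `05_repopulation_modes.py` | uniform vs resistance-coupled repopulation curves |
| `06_parameter_recovery.py` | α_c recovery from noisy synthetic assays |

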