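# Methods

## Model

Clonogenic survival after `n` fractions of dose `d` (Gy) follows the
linear-quadratic (LQ) law

    SF(d) = exp(-n d (alpha + beta d)),

with radiosensitivity coefficients `alpha` (Gy^-1) and `beta` (Gy^-2).
Instead of a single (alpha, beta) pair per tumor, the package models an
*intratumoral distribution* of pairs: an axis-aligned bivariate Gaussian
weight

    f(alpha, beta) = exp(-((alpha - alpha_c)^2 / (2 sigma_alpha^2)
                          + (beta - beta_c)^2 / (2 sigma_beta^2)))

with peak value 1 at the center (alpha_c, beta_c).  Support is truncated
where `f < 1e-2` — i.e. outside the level-set ellipse of standardized
squared radius `2 ln 100` — and the surviving weights are renormalized to
sum to 1 so the distribution represents 100% of the tumor cell population.
The truncation is applied exactly once, at construction; treatment
re-weighting never re-applies it.

Each radiation fraction is instantaneous and multiplies every subset's
absolute cell count by its own `SF(d)`; no transition between subsets ever
occurs, so all change in composition is selection.  Between fractions the
tumor repopulates once per calendar day (weekends included), either

- **uniform**: every subset grows by a fixed rate (default 15%/day).  This
  is a pure scaling of absolute counts — composition trajectories are
  provably identical across uniform rates, which the suite asserts; or
- **coupled**: `p(alpha, beta) = mu exp(theta SF2) / max exp(theta SF2)`,
  so the most resistant subset on the support grows at exactly `mu`/day
  (resistant-faster mode), or the same with `1 - SF2` in the exponent
  (sensitive-faster mode).

Growth is unbounded exponential (no carrying capacity), counts are
continuous expected values with no extinction threshold, and irradiation is
spatially homogeneous.  Biologically effective dose uses the standard
isoeffect formula `BED = n d (1 + d / (alpha/beta))`.

## Numerical choices

- **Grid**: uniform 201 x 201 lattice over the bounding box of the cutoff
  ellipse; cell weights are point evaluations of `f` (midpoint quadrature),
  zeroed below the cutoff, renormalized.  Doubling the resolution changes
  mean alpha/beta and mean SF2 by far less than 0.5% at all parameter sets
  used here (asserted by test), and a seeded rejection-sampling Monte-Carlo
  oracle with >= 1e6 draws agrees with grid summaries within 3 standard
  errors.
- **Mean alpha/beta** is the expectation of the per-cell ratio,
  E[alpha/beta], not the ratio of expectations.  At the esophageal-line
  parameters E[alpha/beta] = 20.64 Gy while E[alpha]/E[beta] = 20.0 Gy; the
  former matches the published derived statistics, and also matches the
  second-order delta-method value (alpha_c/beta_c)(1 + sigma_beta^2/beta_c^2).
- **beta > 0** is required on the whole support (construction fails
  otherwise, since alpha/beta would be undefined); alpha may graze zero at
  the widest published spread (alpha_c = 0.30, sigma_alpha = 0.1 gives a
  minimum grid alpha of -0.0035), which is harmless in the vectorized grid
  math and faithful to the stated distribution.
- **Calendars**: day 1 is a treatment day (a Monday); the weekday pattern
  treats days 1-5 of each 7-day week, so a 35-fraction course ends on day
  47.  Repopulation runs on every calendar day including weekends; under
  uniform repopulation this choice only rescales absolute counts.
  End-of-course is the last fraction's day after that day's repopulation.
- **SF2 composition bins** default to edges {0, 0.24, 0.47, 0.55, 1}: the
  two interior bands are the canonical "sensitive" ([0.24, 0.47)) and
  "resistant" (>= 0.55) subsets; intervals are half-open except the last,
  closed at 1.  Edges are user-configurable since finer compositions are
  study-specific.
- **Selection without repopulation commutes**: per-fraction re-weightings
  are multiplicative, so fitting evolves a course in one step using the
  product of per-fraction survival weights (log-domain accumulation).

## Fitting

The objective is least squares in **log** surviving fraction, pooling pre
and post arms under one shared parameter set — clonogenic noise is
multiplicative, and the post arm is a deterministic selection transform of
the pre-treatment distribution.  Repopulation is excluded during fitting
(a uniform rate cancels from surviving-fraction ratios).  Optimization is
bounded Nelder-Mead from the user's start plus jittered multi-starts
(default 5, lognormal jitter with SD 0.15, seeded); convergence tolerances
are `xatol = 1e-5`, `fatol = 1e-6`, chosen so that tightening them further
changes fitted centers by < 1e-4.  The default free set is `alpha_c` alone,
mirroring how published multi-line experiments vary only the center while
sharing the widths; any subset of the four parameters can be freed.
Under-determined problems (fewer measurements than free parameters) are
rejected.  Out-of-domain trial points (e.g. a beta support crossing zero)
receive a large finite penalty rather than an exception.

## Synthetic data

The generator emulates a two-arm clonogenic experiment: noiseless model
predictions at doses 2-10 Gy for the pre-treatment line and for a line
evolved through a conditioning course, times lognormal noise
(`exp(eps)`, `eps ~ N(0, 0.05)` on log SF by default) with 3 replicates,
clamped to (0, 1].  All draws derive from one seeded generator, so output
is byte-identical under a fixed seed.  Defaults (noise SD 0.05, 3
replicates) were chosen to make recovery non-trivial but feasible at the
published parameter scales.  What the generator does **not** emulate:
colony-count Poisson statistics, plating efficiency, dose-rate effects, or
inter-experiment batch shifts — so passing recovery tests demonstrate
identifiability under idealized multiplicative noise, not robustness to
real assay systematics.

The fixture library exposes the six named distributions D1-D6 (D1 the
esophageal-line fit; D2-D4 center variations at fixed widths; D5/D6
width variations at the alpha/beta = 10 Gy center), plus a homogeneous
point-mass control and a hand-checkable two-subset toy.

## Study sizes

The recovery study fits `alpha_c` on 100 seeded synthetic assays (the
analysis driver defaults to 25 for a quick look, `--n-repeats 100` for the
full study); the Monte-Carlo oracle uses 1.1e6 proposal draws (~99%
acceptance).  Both sizes give standard errors comfortably below the effects
being measured.

## Known limitations

- The initial distribution is a single axis-aligned Gaussian; multimodal or
  correlated (alpha, beta) spreads are out of scope.
- No cell-cycle redistribution, reoxygenation, sublethal-damage repair, or
  stochastic birth-death dynamics; results are expectations.
- Published post-course summaries for the 5-fraction prostate courses are
  reproduced to ~1 Gy in mean alpha/beta rather than exactly; these
  post-course statistics are sensitive to truncation handling, and only the
  25-fraction line's post row reproduces to printed precision.
- BED comparisons use the plain LQ isoeffect formula, with no overall-time
  or incomplete-repair corrections and no high-dose LQ modification.
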