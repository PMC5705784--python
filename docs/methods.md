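# Methods

## The measurement the package models

A saturating BrdU pulse labels cells in S-phase in the dentate gyrus. Animals
are sacrificed 2 h, 2 d, 4 d, 10 d or 30 d later (cross-sectional design: each
animal contributes one timepoint) at ages 1, 2, 6 and 12 months, and BrdU⁺
cells per hippocampus are counted. At 2 d the labelled cohort peaks (cell-cycle
completion plus further divisions net of apoptosis); afterwards it declines by
net death. At 30 d survivors are phenotyped in adjacent sections as NeuN⁺
neurons or GFAP⁺ astrocytes, so the two marker percentages are measured
independently and need not sum to exactly 100%.

The package deliberately treats proliferation, apoptosis and differentiation
as a single "end-point" black box of net survival: it models observed counts,
not the underlying compartment kinetics.

## Marsaglia polar sampler (`marsaglia`)

The polar transform, rejection loop (reject `s = u² + v² ≥ 1` or `s = 0`),
spare-deviate cache and interval truncation are implemented in the package;
only the raw uniform stream is delegated to a seeded 128-bit PCG64 generator,
buffered in blocks of 8192 for speed. The spare cache is fed exclusively from
accepted pairs. Truncation is by redraw-until-inside rejection; an interval
whose acceptance mass (from the normal CDF) falls below `min_mass` (default
10⁻⁶) raises an infeasibility error rather than stalling.

## Synthetic cohort generator (`synthetic`)

Each animal's count is the cascade product `mu_2h · expansion · ∏ surv`
truncated at its sacrifice timepoint, with a multiplicative log-normal factor
of unit mean and CV `noise_cv` applied independently at every step, rounded
half-up and floored at 0. The 2 h base count is N(`mu_2h`, `sigma_2h`)
truncated at 0. Later timepoints therefore accumulate variance, as real
cohorts do. The per-animal variance structure is a modelling choice — only
group means and SDs are observable in this design — and log-normal
multiplicative noise was chosen because counts are positive and
heteroscedastic.

30 d marker fractions are jittered per animal (normal, CV = `noise_cv`,
truncated to [0, 1]) and applied to the animal's latent count; each marker
count is clipped to the total independently (adjacent-section scoring). Ki67
at 2 d is binomial with configurable `p_ki67` (default 0.35) and is carried
in the data model only; no analysis consumes it.

Seeding: one master seed; each (age × timepoint) group derives an independent
stream via CRC32 of the group label combined with the master seed in a
`SeedSequence`, so groups are reproducible in isolation.

### The stated default world

Ages 1/2/6/12 m. 2 h means decay transversally with a 53 d half-life anchored
at 8000 cells/hippocampus at 1 m (a realistic whole-hippocampus magnitude for
a multi-injection paradigm; absolute scale does not affect any fitted rate).
Net 2h→2d expansion 1.7 at all ages. Interval survivals (2d→4d, 4d→10d,
10d→30d) are derived from plateau-decay laws: half-life 2.75 d with an 11.5%
plateau for young ages, 1.1 d with a 25% plateau for mature ages. 30 d marker
splits (NeuN/GFAP): 0.80/0.18, 0.79/0.19, 0.56/0.40, 0.51/0.44 — a niche
shifting from ~4.4:1 neurogenic to ~1.2:1 mixed output. `noise_cv` = 0.12,
5 animals per group. These defaults are fixed; tests measure recovery against
them, they are not tuned to test outcomes.

What a green test establishes: that the estimators recover a world with
exactly this generative structure. Real data add features the generator
omits — non-normal group distributions (2 of 24 populations in typical
datasets fail normality), litter effects, counting error correlated across
timepoints within a batch, and septal/temporal heterogeneity.

## Constrained cohort simulation (`cohort`)

Sequential forward rejection: draw `n2h ≥ 0`; redraw `n2d` until `≥ n2h`;
then each later timepoint until `≤` its predecessor (and `≥ 0`). This
preserves each marginal's shape conditionally on the constraint and is the
simplest mechanism consistent with a constrained-redraw reading of the
restrictions; a joint-rejection mode (draw the whole vector, discard on any
violation) is available as `mode="joint"` for sensitivity analysis. An
extreme early draw can leave a later step with almost no acceptance mass
(e.g. a 2-sigma-low 10 d draw under a mature-age plateau where the 10 d and
30 d laws nearly coincide); steps with conditional mass < 10⁻³ abandon the
vector, which is redrawn whole (cap 1000 restarts). This re-weights the
constrained distribution by at most ~10⁻³ per replicate.

Counts stay real-valued inside the simulation (populations of magnitudes);
rounding is display-only. Marker locking: the locked fraction is drawn from
its percentage law truncated to [0, 1] and the other marker takes the exact
30 d remainder, so `n_gfap + n_neun = n30d` holds identically per record.
"1000 pseudorandom cells per age" is interpreted as 1000 replicate nested
vectors (virtual animals), since marker fractions are drawn per replicate.

The deviation score is the mean over all (age × population) cells of
`|simulated mean − experimental mean| / experimental mean × 100`, populations
being the five total-count timepoints plus the 30 d marker counts; cells with
zero experimental mean are excluded with a warning. The exact deviation
formula is not externally standardised; this mean absolute relative deviation
is the package's declared definition.

## Decay fitting (`decay`)

Bounded least squares (`scipy.optimize.curve_fit`, trust-region reflective)
with the plateau model parametrised as `plateau + amp·exp(−K(t−2))`,
`amp, plateau ≥ 0`, which enforces `plateau ≤ Y0 = plateau + amp` by
construction; `K ≥ 10⁻¹²`. Initialisation: `Y0 ← max(y)`,
`plateau ← min(y)`, `K ← ln2/(t_range/4)`; up to 5 deterministic jittered
restarts on non-convergence. Longitudinal fits use t ∈ [2, 30] d only — the
2 h point precedes the peak and belongs to the expansion phase, not the
decay. Fits accept per-animal points or group means; the mode is recorded in
the result (`fit_target`).

Ages convert at 1 month = 30.44 days. A transversal fit whose decay over the
observed span is below 0.1% (`k·span < 10⁻³`) is flagged as having infinite
half-life rather than reporting a meaningless finite number. AICc uses
K′ = free parameters + 1 (error variance counted), matching common
curve-fitting software; a fit with too few points for the correction carries
NaN and is rejected by the comparison, not by the fit itself.

Curve validation against independent timepoint means uses observed −
predicted residuals and a two-tailed one-sample t-test against zero (p = 1
when all residuals vanish within 10⁻⁹). The t-test is a declared choice; the
residual table is returned so any other location test can be applied.

## Yields and scenarios (`metrics`, `scenario`)

Yields are computed on group means, matching figure-level presentation
(per-animal resampling is available for uncertainty, exercised in the test
suite). The neuron-to-astrocyte ratio inherits the shared 2 h denominator and
reduces exactly to the 30 d marker count ratio.

The extra-survival decomposition anchors the baseline on the 2 d peak (the
age's 2 d count times the reference age's 2d→30d survival), because interval
survivals are expressed relative to the 2 d peak; the reference age's marker
split partitions the baseline. The allocation search keeps the iterative
midpoint (bisection) procedure — initial pair 50:50 and 0:100, bracket
expansion in 0.25 steps to [−1, 2], negative neuron allocations permitted —
and every answer is cross-checked against the closed form; disagreement
beyond 2× tolerance is an internal error. Convergence requires both the
ratio residual and the bracket half-width to be ≤ tolerance (default 10⁻⁶),
so the returned `p` itself is accurate, not just its ratio. Past the
denominator pole the ratio is treated as +∞ for bracketing purposes.

## Pipeline (`pipeline`, `cli`)

`run_full_pipeline` executes summaries → longitudinal fits → transversal
fits → direct mean-rate simulation with cross-age regression → Marsaglia
simulation under both strategies with deviation scores → yields → scenario
search, embedding the seed, config hash and package version in the report.
Stage failures raise `PipelineError` naming the stage. The CLI subcommands
(`synth`, `simulate`, `fit`, `metrics`, `scenarios`, `validate`, `run-all`)
are thin wrappers over the library.

## Known limitations

- The generator's log-normal noise and per-animal fraction jitter are
  stand-ins for an unobserved per-animal variance structure.
- Sequential rejection changes later-timepoint marginals conditionally on
  earlier draws; the joint mode is provided precisely because the redraw
  mechanism is a modelling choice, not a measured fact.
- The scenario search reports point allocations only; no uncertainty
  intervals on `p`.
- No compartmental (NSC/TAP), cell-cycle or apoptosis-rate modelling, no
  septal/temporal subdivision, and no hypothesis-testing layer (normality,
  ANOVA, posthoc tests belong to standard statistical software).
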