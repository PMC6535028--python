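# Methods

## Radiocarbon conventions

Δ¹⁴C (‰) is converted to fraction modern with a decay correction from the
collection year back to the 1950 reference, `F = (Δ/1000 + 1)·exp(λ·(y −
1950))` with λ = 1/8267 y⁻¹, and conventional ages use the Libby mean life,
`age = −8033·ln F` (y BP, negative for post-bomb samples). This is the only
standard convention that reproduces the four benchmark ages (2,400 / 1,700 /
6,700 / 24,800 y BP from −261 / −197.5 / −567.5 / −954.8 ‰) simultaneously.
Summary-level conversions default to collection year 2010, the midpoint of
the 2003–2013 record; the exact year matters little (2008–2012 change the
ages by < 40 y, below the 100-y reporting precision). Per-sample conversions
use each sample's own year. Calendar calibration (IntCal) and reservoir
corrections are out of scope: ages here are conventional ages only.

## Flux weighting

Isotope observations are weighted by the instantaneous DOC or POC flux at
sampling so that high-export periods dominate summaries. The weighted SD
uses the frequency-weight (Σw-normalised) convention with a reliability
correction through the Kish effective sample size n_eff = (Σw)²/Σw², which
reduces exactly to the unbiased sample SD for equal weights. The weighted
two-sample t test combines weighted means and variances with effective
sample sizes and Welch–Satterthwaite degrees of freedom — conservative, and
identical to Welch's t test at unit weights. Weighted quantiles invert the
weighted empirical CDF (numpy's `inverted_cdf` method). Degenerate t-test
inputs: when both groups have zero variance the statistic is 0/0 and an
error is raised if the means are also equal; with differing means the test
returns t = ±inf, p = 0, which the sensitivity bisection relies on.

## Endmembers and scenarios

Four literature-constrained pools (Δ¹⁴C mean ± SD, n): recent terrestrial
primary production 97.0 ± 124.8 (58), active layer −197.5 ± 148.4 (60),
Holocene deposits −567.5 ± 156.7 (138), Pleistocene Ice Complex deposits
−954.8 ± 65.8 (329). The database is user-editable YAML so new literature
compilations can replace the defaults; δ¹³C values are stored for reference
but never used in the apportionment.

The composite PP-C endmember treats all fractional combinations of the
contributing pools as equally likely: weights φ ~ Dirichlet(1,…,1), pool
realisations Xₖ ~ Normal(μₖ, σₖ), draw = Σφₖ Xₖ. This is the unique
"least-biased" choice on the simplex; it preserves the arithmetic mean of
the pool means while inflating the spread with compositional uncertainty
(for two pools, Var = (σ₁² + σ₂²)/3 + (μ₁ − μ₂)²/12, so the western
composite is −382.5 ± 164 ‰). Scenarios: *best_estimate* uses active layer
+ Holocene (Ob, Yenisey) and additionally Pleistocene (Lena, Kolyma, where
Ice Complex deposits are abundant); *maximum* uses only the youngest pool
(active layer), *minimum* only the oldest (Holocene west, Pleistocene
east).

Pool draws are deliberately **not** truncated at the −1000 ‰ physical
floor: truncating the Pleistocene pool there would raise its mean by ≈27 ‰
and destroy the defining same-mean property of the composite. The small
sub-floor tail is treated as part of the endmember uncertainty model, not
as physical carbon.

## MCMC apportionment

Prior f ~ Uniform(0,1); likelihood Normal(f·Δ_pp + (1−f)·Δ_rec, σ_obs),
with the product taken over all observations when a group is pooled under
one f. σ_obs defaults to 10 ‰ (typical AMS measurement uncertainty) and is
configurable; synthetic-recovery runs set it to the generator's noise SD.
At each iteration the endmember pair is redrawn (recent from its Normal,
PP-C by resampling the composite's Monte-Carlo draws), marginalising
endmember variability, and f is updated by a Gaussian random walk
(proposal SD 0.05) reflected at the [0,1] boundaries — reflection keeps the
proposal symmetric. Defaults are 10⁶ iterations, 10⁴ burn-in, thinning 10
(99,000 retained draws); the desk-scale switch caps iterations at 10⁵,
which our coverage tests show is ample for single-f targets. Acceptance
rates outside [0.05, 0.95] are logged as warnings. With degenerate
endmembers the scheme is exact MH on f and matches 1-D grid integration of
the posterior to < 0.02 in the mean (tested on 20 observations spanning
the mixing range).

Granularity is per sample by default, with flux-weighted aggregation to
river × season × analyte groups (each group draw is the flux-weighted mean
of one draw per member posterior); pooling all of a group's observations
under a single f in one likelihood is available as the `group` mode and is
what the parameter-recovery tests exercise. Because endmember uncertainty
dominates measurement noise, group posteriors are wide and honestly so:
95% credible intervals covered the true fraction in 40/40 synthetic cells
in the shipped acceptance test.

## Flux partitioning

Total seasonal DOC/POC fluxes per river are inputs (load-regression
outputs, mean ± SD in Tg C); estimating them from discharge and
concentration is out of scope. Per Monte-Carlo replicate (default 10⁴) a
fraction is drawn from the cell's posterior and a flux from a Normal
truncated at zero (the load estimates come with no distributional
statement, and truncation enforces nonnegativity); their product is the
cell's PP-C flux. Fractions and fluxes are treated as independent since
they derive from disjoint data. All sums and shares (carrier phase,
season, recent = total − PP-C) are formed within replicates, so shares sum
to exactly 100% per replicate and PP-C never exceeds the total; reported
values are means ± SDs across replicates, which therefore include both
fraction and flux uncertainty.

## Sensitivity to changed PP-C release

Scaling the PP-C flux by `s` at constant recent-carbon flux gives
`f′ = s·f/(s·f + 1 − f)` — the unique two-pool mass balance with that
property — and a Δ¹⁴C shift `(f′ − f)(Δ_pp − Δ_rec)`. For s = 2 this is
`−f(1−f)/(1+f)·(Δ_rec − Δ_pp)`, maximised at f* = √2 − 1 (the closed form
is used as the test oracle; the package searches a 10⁻⁴ grid). With western
Best-Estimate endmembers the maximum decrease is 82 ‰ at a baseline of
about −102 ‰; halving produces a symmetric increase. The minimum resolvable
change shifts every observation by its posterior-mean fraction (a
full-posterior variant can be built from the draws), compares shifted and
baseline records with the flux-weighted t test, and bisects on s (tolerance
10⁻³) for the smallest significant increase at α = 0.05; records whose
scatter swamps any shift up to s = 100 are reported as not resolvable.
The eastern-river variant of the maximum shift depends on an endmember
weighting that published summaries leave ambiguous, so only the western
value is asserted in tests.

## Synthetic data

The generator emulates exactly the structure the model assumes: per
observation, one realisation of each endmember mixed at a known true
fraction plus Normal(0, 15 ‰) observation noise, dates drawn within the
hydrological seasons (May–Jun spring, Jul–Oct summer/fall, Nov–Apr
winter), and lognormal flux weights (σ_log = 0.6) with seasonal multipliers
peaking in the spring freshet (4 / 1.5 / 0.4). Default true fractions echo
the observed regimes — POC ≈ 0.60–0.65 year-round, DOC rising from 0.06
(spring) to 0.22 (winter) — and the default flux table uses the published
annual river totals (4.7 / 4.9 / 6.5 / 0.9 Tg C y⁻¹), a 50/38/12% seasonal
split and 90% DOC share with 10% relative SDs. Observations are rejected
and redrawn if they fall at or below −1000 ‰. What the generator does *not*
emulate: hydrograph structure within seasons, serial correlation between
revisits, δ¹³C process signals (a fixed Normal fills the schema column),
inter-annual trends, and any mismatch between the real sources and the
assumed endmember distributions — so passing recovery tests demonstrate
internal consistency of the inference, not the realism of the endmember
database itself.

## Numerical and testing choices

Default test problem sizes (10⁵-iteration chains, 10⁵–2·10⁵ endmember
draws, 10³–10⁴ Monte-Carlo replicates) were chosen so every Monte-Carlo
tolerance is a multiple of the corresponding standard error; the full-scale
10⁶-iteration settings remain the library defaults. All samplers are
deterministic given a seed (randomness is pre-generated from
`numpy.random.default_rng`); per-sample runs derive child seeds through
`SeedSequence.spawn`. Known limitations: two-source unmixing only (the
composite construction reduces multi-pool problems to two endmembers before
inference); no δ¹³C in the likelihood; no calendar-age calibration; flux
tables must cover every cell being partitioned, and incomplete
season/analyte coverage is a hard error rather than a renormalisation.
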