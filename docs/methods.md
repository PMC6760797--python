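# Methods

`phenotherm` models the temperature dependence of an insect life cycle —
developed for, and bundled with reference data on, the African edible
cricket *Scapsipedus icipe* — and turns stage-specific thermal-response
curves into cohort life tables and climate-suitability maps. This note
records the model, its assumptions, the parameter choices, and the known
limitations.

## Thermal-response curves

All temperatures are °C; rates are per day. The curve families are:

| process | family | form |
|---|---|---|
| development (sub-optimal range) | linear degree-day | r(T) = a + bT, with Tmin = −a/b, K = 1/b degree-days |
| development (full range) | Logan 1 | r(T) = Y·(e^{pT} − e^{p·Tmax − (Tmax−T)/v}) |
| development (full range) | Allahyari | r(T) = P·xⁿ(1 − xᵐ), x = (T−Tmin)/(Tmax−Tmin), zero outside [Tmin, Tmax] |
| stage mortality | Wang, two-sided | m(T) = 1 − exp(−H·(1+e^{−(T−Tl)/B})(1+e^{−(Th−T)/B})) |
| stage mortality | Wang, symmetric | as above with Topt on both flanks; minimum 1 − e^{−4H} exactly at Topt |
| lifetime fecundity | Wang 7 | product of two opposing logistics in (T−Topt)/B1 and (Topt−T)/Bh, normalised so f(Topt) = Fmax |
| oviposition timing | exponential-cubic CDF | O(E) = 1 − e^{−(aE + bE² + cE³)} over normalised adult age E |
| adult senescence | Hilbert–Logan 3 | s(T) = trid·((T−Tmin)²/((T−Tmin)² + D) − e^{−(Tmax−(T−Tmin))/Dt}) |
| adult senescence | exponential simple | s(T) = b1·e^{b2·T} |

Rates are clipped at zero when used biologically; every evaluator exposes
`clip=False` so fitting can see (and penalise) out-of-domain negativity.
The normalisation of Wang 7 anchors f(Topt) = Fmax; with unequal widths
B1 ≠ Bh the true maximiser sits slightly off Topt (≈0.6 °C for the
bundled fit), which is why tests locate the optimum to within 1 °C rather
than exactly.

Cardinal temperatures: for the linear family, Tmin and K are closed-form.
For Logan 1 and Allahyari, Topt is always *derived* by bounded
maximisation — never a free parameter — and Logan 1's Tmin is the lower
zero-crossing of the raw rate, reported as undefined when the curve stays
positive down to 0 °C (true of the bundled egg fit).

## Fitting

Development rates are reciprocals of the per-temperature *median*
development time of stage completers (midpoint convention for even n);
censored individuals contribute only to mortality fractions, never to
rate medians. The linear degree-day model is fit by OLS on an explicit
sub-optimal window (defaults 15–35 °C for eggs, 20–35 °C for nymph and
pre-adult, excluding the supra-optimal 37 °C point); the window is a
logged configuration value because the choice materially moves Tmin.

Nonlinear families are fit by bounded damped least squares
(`scipy.optimize.least_squares`, trust-region reflective) from 25
Latin-hypercube starts inside per-family parameter boxes, with a final
polish at 1e−13 tolerances; the multi-start is deterministic given its
seed. Model choice uses AIC = n·ln(RSS/n) + 2k (constants dropped, k =
free parameters), ties broken by higher R², then parsimony.

**Identifiability.** These curve families are weakly identified: scale
and shape parameters trade off almost perfectly (fits of the reference
data produce the same near-singular behaviour as the published estimates,
e.g. p = 0.199 ± 7.375). The package therefore reports Jacobian-based
standard errors and condition numbers, and its recovery tests score
*curve-level* agreement (predicted values wherever the curve exceeds 10%
of its peak) rather than raw parameter vectors, except on noiseless data
where exact recovery is required and achieved.

## Life tables

A phenology model = ordered immature stages (egg, nymph, pre-adult), each
with a development curve, a lognormal development-time sigma and a
mortality curve; plus female/male senescence, fecundity, the oviposition
CDF and a female ratio (default 0.5).

The deterministic schedule at constant T uses 1-day steps: stage
durations are 1/r(T) rounded to days; survivorship drops by the stage
mortality at each stage completion (a per-stage Bernoulli, not a daily
hazard — mortality curves are defined per stage); adult females decay
exponentially at s(T); daughter eggs f(T)·(female ratio) are spread over
adult ages by the oviposition CDF on age normalised by the mean adult
lifespan 1/s(T). From the lx/mx schedule: Ro = Σlx·mx, GRR = Σmx, rm
solves Σe^{−rm·x}lx·mx = 1 by bisection on a geometrically widened
bracket (tolerance 1e−12), T = ln(Ro)/rm, λ = e^{rm}, Dt = ln 2/rm.
Schedules with Ro = 0 carry rm = −∞ as a sentinel. The default horizon is
1500 days; a cohort whose immature development exceeds the horizon is
flagged non-viable.

The stochastic cohort draws, per egg: Bernoulli stage survival, lognormal
stage durations (median-preserving, per-stage sigma, default 0.1 — the
source experiments' individual variability is not published, so sigma is
re-estimated from data when fitting), and an exponential adult lifespan.
Its empirical schedule has the deterministic one as its expectation;
exact equality holds only in the fully degenerate case (zero sigma,
vanishing mortality, senescence rate clipped to zero), which is how the
degenerate-randomness test is constructed. The replicated design (100
eggs × 6 temperatures × 6 replicates) spawns all seeds from one base
seed.

Adult males are carried for longevity reporting only; the life table is
female-based.

## Spatial indices

Grids are 12 monthly mean-temperature layers (tmin/tmax carried but
unused) on one shared geometry, read and written as ESRI ASCII rasters;
no reprojection or resampling is performed — misaligned inputs are an
error. Monthly values are interpolated to 365 daily values through
periodic linear interpolation between month midpoints (no leap days).

Per cell:

- **ERI** (establishment risk, 0–1): mean over months of the product over
  immature stages of (1 − m(T_month)).
- **GI** (generations/year): Σ over days of 1/(immature duration +
  maturation) at that day's temperature, where maturation is the age at
  50% cumulative oviposition (E50·mean adult lifespan).
- **AI** (activity index): log10 of yearly finite growth,
  Σ rm(T_month)·days/ln 10. Months where no generation is viable
  contribute a *decline* at the female senescence rate (a population can
  only die there); this choice keeps AI finite and monotone in habitat
  quality.

Cell evaluations are cached at 0.01 °C resolution, so constant-temperature
grids reproduce point computations exactly. A warming scenario is a
uniform ΔT added to every defined cell (mask unchanged); offsets compose
additively.

## Synthetic experiments

The generator emulates the reference design: 100 individually-followed
eggs at each of nine constant temperatures (10–40 °C), 20 oviposition
pairs and 50 adults per sex per temperature. Non-survivors are censored
at a uniform fraction of their would-be stage duration (within-stage
death times are not published). Daily egg counts are negative-binomially
overdispersed (size 5 by default — only means ± SE are published, so an
overdispersed count model is the safe default). Identical seeds reproduce
byte-identical files; sub-seeds are spawned from the experiment seed.

What the generator does *not* emulate: temperature-biased sex ratios
(the female ratio is a constant, default 0.5), fluctuating temperatures,
density dependence, body-size covariates, and within-day event timing.
Passing recovery tests therefore show the pipeline is consistent with its
own generative assumptions at realistic sample sizes — not that those
assumptions hold for any particular rearing dataset.

## Bundled reference data

`phenotherm.data` ships the published summary tables (stage development
times — with the nymph instars pooled by summation, reproduction and
longevity, and simulated life-table parameters) and a parameter bundle:
published development-curve estimates; package-made least-squares fits of
fecundity (to the lifetime totals, optimum pinned at 30 °C) and of
senescence (to reciprocal mean longevities); and *synthetic stand-in*
mortality curves, chosen once to respect the reported viability limits
(no egg hatch at 10 or 40 °C, full development at 20–37 °C), because the
original mortality fits are unpublished. The oviposition CDF
(a=0.3, b=1.7, c=0.3) puts 50% egg-lay near normalised age 0.55,
matching the reported half-lay point.

With this bundle the deterministic life table lands close to the
published simulation at the optimum (rm(30 °C) = 0.078 vs 0.075;
λ = 1.081; Dt = 8.9 d vs 9.26 d) without any tuning toward those values.

## Numerical choices and limitations

- Time step 1 day everywhere; sub-day observation cadence is not resolved.
- Median-based rates make the linear threshold robust but mean the
  bundled Table-derived threshold (from printed means) is only expected
  to agree with the published one to ~2%.
- The Hilbert–Logan 3 family *decreases* at high temperature by
  construction, so it cannot reproduce the sharp female senescence
  spike observed at 37 °C; the bundled female fit underestimates it.
- AIC assumes homoscedastic Gaussian errors on the (small) per-temperature
  summary points.
- Suitability classes ("optimal", "marginal") are not defined; the maps
  carry continuous indices only.
- Test-suite problem sizes: the full-loop recovery runs 25 seeds at the
  reference design with 10 multi-starts per fit; the model-selection
  study uses 6 starts; the convergence check compares cohorts of 100 and
  10,000 eggs over three seeds.
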