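# Methods

## Model

The package models co-cultures of a cisplatin-sensitive and a
cisplatin-tolerant NSCLC line, each carrying a fluorescent label (red =
sensitive-seeded, green = tolerant-seeded). Cells interconvert between
the two phenotypes by first-order exchange while keeping their label, so
the state is the four-way split `(Rs, Rt, Gs, Gt)` plus two hidden
variables: the stress level `C_str` and the drug-exposure memory `AUC`.
Within each label L:

```
dLs/dt = −Ka·Ls + Kb·Lt + K_GS·Ls − deathS·Ls
dLt/dt = +Ka·Ls − Kb·Lt + K_GT·Lt − deathT·Lt
```

and `dC_str/dt = K_str·S − K_str,d·T` over phenotype totals. Summing
labels recovers the two-variable phenotype model exactly (tested to
machine precision). Assumptions inherited from the model's design:
switched and native cells of a phenotype are dynamically identical; the
effective growth rates fold proliferation and death together and may go
negative; there is no explicit carrying-capacity term — growth
saturates, when it does, through stress.

### Units and parameters

Time is in days: the fitted growth-rate magnitudes (e.g. K_Gs0 ≈ 0.71)
are consistent with the observed ~8-fold growth over 96 h only on a
per-day scale. AUC is kept in µM·h (AUC_5 ≈ 239 ≈ 5 µM × 48 h), so
`dAUC/dt = 24·conc` with concentration in µM. The nine drug-free
parameters are the switch equilibrium baseline K_0 and its stress slope
g, the fixed back-switch rate K_b, baseline growth rates K_Gs0/K_Gt0
with stress slopes a/b, and the stress production/removal rates
K_str/K_str,d. The drug block adds AUC_5/AUC_95/SCALE per phenotype and
the S_drug constant. All defaults are the published point estimates;
fitting searches the published ranges.

### Stress coupling

Growth decreases and the switch equilibrium increases with stress;
linear maps are the default. A sigmoidal variant replaces each linear
map with a rescaled-logistic (tanh) form matching the linear law's value
and slope at zero stress and saturating at one baseline unit by default
(`saturation` configurable); it preserves the monotone contracts and is
available everywhere via `coupling="sigmoidal"`.

Stress is a physical pool and cannot go negative: the removal term
saturates at `C_str = 0` (the derivative is floored there). Without the
floor, tolerant-majority cultures would accumulate *negative* stress and
super-baseline growth, violating the state invariants. The floor lowers
the tolerant-lineage switched-fraction maximum of the heterotypic panel
from ~95% to ~93%; both are below the model's stated ~97% ceiling.

### Drug response and exposure memory

Kill rates are `SCALE × sigmoid(AUC)` with the logistic anchored at 5%
and 95% of maximal effect (the ln 19 slope constant makes the anchors
exact). The kill term is gated on `AUC > 0`, so a never-treated culture
is *exactly* a drug-free one rather than paying the sigmoid's ~1% left
tail. After washout, AUC is held constant by default (the literal
memory-effect reading); exponential decay with a configurable half-life
and reset-at-washout are provided as alternatives and recorded in the
trajectory. Under cisplatin the community-cooperation machinery is
locked off when fitting or simulating drug conditions: K_b = 0 (hence
Ka = 0), K_str,d = 0, and the sensitive stress slope a is unused.

### Numerics

The reference integrator is LSODA (stiff-safe, adaptive) at
rtol = atol = 1e-8, restarted at every dosing-episode boundary so the
piecewise-constant concentration never sits inside a solver step.
Reported counts are floored at zero (round-off clamp). The fitting path
uses a vectorised fixed-step RK4 engine that advances the whole GA
population and every series of a panel simultaneously (3 substeps per
2-h reporting interval; agreement with LSODA better than 1e-4 relative,
far below the σ = 0.05 noise floor — asserted in the suite). Runaway
candidates are capped at ±1e30 and penalised rather than allowed to
produce NaNs.

## Fitting

Counts are fitted on the log scale with Gaussian errors — equivalently,
lognormal multiplicative count noise, chosen because imaging counts span
orders of magnitude and stay positive. The noise SD σ is profiled out
analytically (its MLE is plugged in), so the objective is
`n/2·(log(2π·SSE/n)+1)`; a fixed-σ variant exists for diagnostics.
Simulated counts that hit zero at an observation time incur a large
finite penalty (1e8 per point), never NaN. When a dataset carries
seeding metadata (synthetic studies; plated experiments where the
inoculum is known by design), series are initialised from the exact
seeded counts; otherwise from the observed t = 0 counts, which slightly
inflates the apparent σ.

The global optimiser is a real-valued genetic algorithm written for this
package: tournament selection (size 3), BLX-α blend crossover (α = 0.5,
rate 0.8), per-gene Gaussian mutation (rate 0.1, SD 10% of each bound
range), elitism (5), defaults mirroring common real-valued GA packages;
fully reproducible under a seed, with a monotone best-so-far trace. The
best-of-run is polished by bounded L-BFGS-B using a batched
forward-difference gradient (one vectorised objective call per
gradient), which resolves the optimum to well below the χ² resolution
profile intervals need.

Profile-likelihood 95% intervals use the χ²(1) cutoff
(2·ΔNLL ≤ 3.84): each grid value pins the profiled parameter and
re-optimises the rest (short warm-started GA + polish); crossings are
linearly interpolated, and a profile that never clears the cutoff is
flagged flat (not identifiable). Whether a single value lies in the CI
is decided pointwise (`profile_point`), which the coverage experiment
uses directly. The method of the published "±" intervals is not stated,
so no numeric equality with them is claimed.

Each cohabitation condition (monotypic, immediate-mix, three-week
co-culture, with/without cisplatin) is fitted independently with its own
parameter set, reflecting the premise that cohabitation history changes
the phenotypes; drug conditions use the 16-parameter model under the
locking mask above.

## Payoff extraction

Per-capita growth rates are central finite differences of log counts.
Within a window the competitive Lotka–Volterra per-capita rate is linear
in `(r, r/Kc, r·α/Kc)`, so each species is solved by exact linear least
squares; only when that solution leaves the admissible box (r ∈ [0,5]
/day, Kc ∈ [10, 1e7] cells, α ∈ [−10, 10]) does a bounded trust-region
refinement run from three deterministic starts (clipped linear solution,
interaction-free logistic solution, mid-box). This replaces seeded
multi-starts: for this objective the linear solution *is* the global
optimum of the unconstrained problem, and the procedure is deterministic
end to end. LV species default to the observable label channels (what
the experiment measures); phenotype totals are a config switch.

Degenerate windows are first-class outcomes: too few samples or a
near-extinct channel → flagged missing; no density dependence (pure
exponential growth) → α fixed at 0 with Kc at the upper bound, flagged
unidentified; an α pegged at the box edge → flagged `at_bound`
(the LV form cannot represent that window, e.g. a per-capita rate that
*rises* as the phenotype mix equilibrates). After the phenotype mix
equilibrates, the two label channels grow proportionally, and the fit
resolves the shared density dependence toward α12 ≈ −N1/N2 — the
interaction term offsetting the self-limitation term — which reads as
strong tolerant→sensitive cooperation and scales with the seeding
ratio; the reverse coefficient is correspondingly small. Summaries
should be made over non-flagged cells.

Window-length selection: in-sample least-squares residuals necessarily
shrink as windows shrink, so the landscape also reports a one-stride-
ahead forecast RMSE and the overfit ratio forecast/fit. On the standard
panel the 12-h windows fit near-perfectly in-sample but generalise an
order of magnitude worse than they fit (overfit ratio ≈ 11 vs ≈ 1.6 at
4 days), while 6-day windows have the worst in-sample residual
(time-varying interactions averaged out). The default window is 4 days
with a 12-h stride.

## Therapy simulation

Protocols follow the in-vitro regimens: continuous drug for the whole
horizon; intermittent-1 = one 2-day exposure; intermittent-2 = the
2-day exposure plus one extra 4-day dose, placed on days 3–7 by default
(the published protocol gives only partial day-level detail; boundaries
are config). The comparison seeds 4:1 sensitive:tolerant, 50,000 cells,
uses the cisplatin-condition parameter set with the locking mask for
*all* arms (so arms differ only in schedule), holds AUC after washout,
and runs 10 days — the span of the in-vitro ratio measurements — at
tightened tolerances (rtol 1e-10, atol 1e-12), because without a
carrying capacity the tolerant channel decays over many decades at this
seeding density. Regimen comparisons are best read around day 4: by then
all arms have diverged, while later the tolerant channel falls below
numerically meaningful levels and ratios degenerate to ties at zero.
Passaging can be modelled as instantaneous rescale events but is off by
default, again because the model has no confluence term.

## Synthetic study

The default study mirrors the calibration dataset's structure: four
conditions (monotypic red, monotypic green, heterotypic immediate-mix,
heterotypic 3-week), seeding ratios 1:1–8:1 at 5000 total cells,
sampling every 2 h over 144 h, two replicate wells, lognormal
multiplicative noise with σ = 0.05 — 2628 records, on the order of the
~2900 observations the model was calibrated against. Generating
parameters default to the published heterotypic rows; the monotypic
wells reuse the immediate-mix row as ground truth (the published table
prints no monotypic rows), seeding a single lineage. Ground truth,
schedules and exact seedings travel in the dataset's metadata, and two
small registered fixtures (`tiny-heterotypic`, `drug-panel`, ≤ 200
records each) support fast tests. What the generator does *not* emulate:
confluence and contact inhibition, segmentation artifacts, well-position
effects, replicate-level batch structure — so passing recovery tests
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to real-data misspecification.

The recovery experiment fits 20 independently seeded replicates of the
heterotypic panel (GA population 64, 60 generations + polish — sized so
the whole experiment runs in a few minutes on one CPU) and checks that
the profile 95% intervals for K_Gs0 and K_Gt0 cover the generating
values in ≥ 80% of replicates. Only these two rates are so checked: the
switching block is only weakly identified from smooth growth curves
(e.g. K_0·K_b and the stress rates trade off), which the profile
machinery reports as wide or flat profiles rather than false precision.

## Known limitations

* No carrying capacity: long drug-free extrapolations at high seeding
  densities are exponential absurdities; the model is meant for the
  ~6-day growth-curve regime it was calibrated on.
* The stress variable is unobserved and its units are internal; only
  stress-coupled combinations are interpretable.
* The exact functional forms of the stress couplings beyond monotonicity
  (and the original sigmoidal variant) are not published; the linear and
  tanh forms here satisfy all stated qualitative contracts.
* The role of S_drug is undocumented in the source material; it is
  stored for config round-trip fidelity and optionally couples as a
  drug-on stress source, off by default.
* Windowed LV payoffs on proportionally growing channels are
  intrinsically under-determined; the flags exist precisely because
  those cells should not be over-interpreted.
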