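# psmsr

Population dynamics of drug-sensitive and drug-tolerant cancer cells with
stress-driven phenotypic switching.

Non-genetic drug tolerance is a major route to chemotherapy failure in
non-small-cell lung cancer: a slow-cycling, cisplatin-tolerant
subpopulation survives treatment and can reversibly switch phenotype.
`psmsr` implements the **P**henotypic **S**witch **M**odel with **S**tress
**R**esponse — an ODE model of two-channel (red = sensitive-seeded,
green = tolerant-seeded) co-culture growth curves — together with
everything needed to work with it:

* forward simulation over seeding panels and cisplatin dosing schedules,
  with lineage-resolved bookkeeping (which label currently carries which
  phenotype);
* parameter estimation from growth-curve tables by a real-valued genetic
  algorithm with quasi-Newton polish, and profile-likelihood 95%
  confidence intervals;
* time-resolved game-theoretic payoff extraction: competitive
  Lotka–Volterra coefficients fitted over moving time windows;
* continuous vs intermittent therapy-regimen comparison;
* a synthetic-data generator that emulates the live-imaging study design
  (monotypic and heterotypic wells, seeding ratios 1:1–8:1, 2-hourly
  sampling over 144 h, multiplicative lognormal count noise).

## The model

Sensitive (S) and tolerant (T) phenotype totals evolve as

```
dS/dt = −Ka·S + Kb·T + K_GS·S − SCALE_s·sigmoid(AUC)·S
dT/dt = +Ka·S − Kb·T + K_GT·T − SCALE_t·sigmoid(AUC)·T
dC_str/dt = K_str·S − K_str,d·T
```

with first-order phenotype exchange (equilibrium constant K = Ka/Kb), a
hidden stress variable `C_str` generated by sensitive cells and removed
by tolerant cells, and stress-coupled rates (linear by default):
`K_GS = K_Gs0 − a·C_str`, `K_GT = K_Gt0 − b·C_str`, `K = K_0 + g·C_str`.
Cisplatin acts through the exposure memory `AUC` (concentration × time,
µM·h); the kill term is a logistic in AUC anchored at 5% of maximal
effect at `AUC_5` and 95% at `AUC_95`, scaled by a per-phenotype maximal
death rate. Time is in days; rates in 1/day. The package integrates the
*lineage-resolved* version of these equations (each label split by
phenotype), whose label sums reproduce the two-variable model exactly.

Published point estimates for the co-culture conditions ship as presets
(`psmsr.PRESETS`, `psmsr.DRUG_PRESETS`) together with the fitting search
ranges (`psmsr.SEARCH_BOUNDS`).

## Worked example

Simulate the drug-free heterotypic panel (5000 cells, sensitive:tolerant
seeding ratios 1:1–8:1, 144 h) and look at how much of each lineage has
switched phenotype:

```python
import numpy as np
from psmsr import PRESETS, SeedingDesign, run_seeding_panel, switched_fractions, ts_ratio

panel = run_seeding_panel(PRESETS["heterotypic"], SeedingDesign())
for traj in panel:
    sf = switched_fractions(traj)
    print(f"{traj.ratio[0]}:{traj.ratio[1]}  green->sensitive max {100*np.nanmax(sf.gs_frac):.1f}%   "
          f"red->tolerant max {100*np.nanmax(sf.rt_frac):.1f}%   T:S at 144 h {ts_ratio(traj, 6.0):.3f}")
```

prints

```
1:1  green->sensitive max 92.9%   red->tolerant max 11.3%   T:S at 144 h 0.993
2:1  green->sensitive max 92.5%   red->tolerant max 11.3%   T:S at 144 h 0.497
4:1  green->sensitive max 92.0%   red->tolerant max 11.3%   T:S at 144 h 0.248
8:1  green->sensitive max 91.4%   red->tolerant max 11.3%   T:S at 144 h 0.124
```

The tolerant-seeded (green) lineage switches almost entirely to the
fast-growing sensitive phenotype within the first days, while the
sensitive-seeded (red) lineage maintains a small tolerant reserve —
about 11%, the level pinned by the stress production/removal balance
`K_str/K_str,d`. That reserve is what pays off under treatment: tolerant
cells neutralise growth-suppressing stress for the whole community, and
under cisplatin they are the surviving fraction.

A command-line surface wraps the same functionality
(`psmsr simulate|fit|profile|payoff|therapy|synth`); every run writes a
provenance stamp (config hash, seed, package version) next to its
outputs.

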