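# rnapalloc

Resource allocation with split T7 RNA polymerase: equilibrium
competition of σ fragments for a shared core-fragment pool, dynamic
allocation simulation, and the reporter-assay analysis chain used to
characterise such a system.

## The problem

Fragmenting T7 RNAP into a catalytic **core fragment** and a
promoter-binding **σ fragment** turns the polymerase into an allocatable
resource, mimicking how bacterial σ factors share host RNAP.  The core
level sets the total transcriptional budget; orthogonal σ-fragment
variants (T7, T3, K1FR, CGG) direct that budget to different promoters.
Because every σ fragment competes for the same pool by mass action,
total activity is capped at the core budget regardless of how many
outputs are on — the architecture's guarantee against transcriptional
overload.  A catalytically dead **null fragment** sequesters core
(negative regulation), and splitting the core again into an **α
fragment** plus **β core** makes the budget inducible (positive
regulation).

The package is aimed at synthetic biologists designing or analysing
such allocator circuits: it provides the equilibrium model, time-course
simulation of controller schedules, a seeded synthetic-assay generator
with realistic flow-cytometry measurement structure, and the
normalisation/regression/fitting chain for endpoint reporter data.

## The model

For σ fragments with totals $S_i$ and dissociation constants $K_i$
competing for active core $C$, the unique equilibrium satisfies

$$\mathrm{complex}_i = \frac{S_i F}{K_i + F},\qquad
  F\Bigl(1 + \sum_i \frac{S_i}{K_i + F}\Bigr) = C,$$

solved by bracketed root finding on the free core $F$.  Promoter
activity is linear in bound polymerase.  In the saturated regime
($\sum_i S_i \gg C$, common tight $K$) the bound-core shares reduce to
the relative expression levels $x_i / \sum_j x_j$; a two-σ competition
normalised to "fraction core utilized" then follows
$x/(x+s)$ and $s/(x+s)$ with a single free parameter $s$, the constant
competitor's relative expression.  α activation is a prior two-species
binding equilibrium.  See `docs/methods.md` for assumptions, defaults,
and limitations.

## Worked example

```python
import numpy as np
from rnapalloc import (default_system, equilibrate, promoter_activities,
                       saturated_shares, generate_competition, promoter_activity,
                       fraction_core_utilized, sum_constancy,
                       fit_relative_expression, ExpressionCalibration)
from rnapalloc.synthetic import GeneratorConfig

# T3 (3.0 AU) and K1FR (1.5 AU) compete for 1.0 AU of core
system = default_system().with_sigma_totals(
    {"T7": 0.0, "CGG": 0.0, "T3": 3.0, "K1FR": 1.5})
state = equilibrate(system)
print("bound complexes:", {k: round(v, 4) for k, v in state.complexes.items() if v})
print("free core:      ", round(state.free_core, 6))
print("activities:     ", {k: round(v) for k, v in promoter_activities(state, system).items()})
print("saturated shares:", saturated_shares({"T3": 3.0, "K1FR": 1.5}))
```

```
bound complexes: {'T3': 0.6648, 'K1FR': 0.3324}
free core:       0.002847
activities:      {'PT7': 0, 'PT3': 76448, 'PK1FR': 39886, 'PCGG': 0}
saturated shares: {'T3': 0.6666666666666666, 'K1FR': 0.3333333333333333}
```

At a 2:1 expression ratio the fragments bind 66.5% and 33.2% of the
core — within half a percent of the saturated-shares prediction (2/3,
1/3); the shortfall is the 0.28% of core left free at `kd = 0.01`.
Reporter activities are the complexes scaled by each fragment's
transcription efficiency (AU of fluorescence per bound polymerase).

The same model drives a full synthetic competition assay (12-point IPTG
grid, triplicates, 10% lognormal noise), which the analysis chain then
inverts:

```python
table = generate_competition(GeneratorConfig(seed=1))   # K1FR constant, T3 induced
acts = promoter_activity(table)                         # geomean - white cell
sat = acts[acts.condition.str.startswith("saturation_")]
refs = dict(zip(sat.promoter, sat.activity_au))
comp = acts[acts.condition == "competition"]
frac = fraction_core_utilized(comp, refs)
mean_sum, cv = sum_constancy(comp)
print("sum of activities: mean %.0f AU, cv %.3f" % (mean_sum, cv))

cal = ExpressionCalibration(np.array(table.extra["calibration"]["iptg_uM"]),
                            np.array(table.extra["calibration"]["expression_au"]))
fi = frac[frac.promoter == "PT3"].sort_values("iptg_uM")
fc = frac[frac.promoter == "PK1FR"].sort_values("iptg_uM")
res = fit_relative_expression(cal(fi.iptg_uM.to_numpy()), fi.fraction.to_numpy(),
                              fc.fraction.to_numpy(), seed=1)
print("fitted competitor expression s = %.3f  (95%% CI %.3f-%.3f; truth 1.5)"
      % (res.parameters["s"], *res.bootstrap_ci["s"]))
```

```
sum of activities: mean 115299 AU, cv 0.042
fitted competitor expression s = 1.498  (95% CI 1.412-1.570; truth 1.5)
```

The summed activity of the two competing promoters stays flat across
the induction series (cv 4%, pure measurement noise) — the conserved
budget — and the one-parameter competition fit recovers the constant
fragment's expression level from the normalised curves alone.

## Command line

```sh
rnapalloc generate --kind competition --seed 7 --out run/
rnapalloc analyze --measurements run/measurements.csv --metadata run/metadata.json \
                  --mode sums --out analysis/
rnapalloc fit     --measurements run/measurements.csv --metadata run/metadata.json \
                  --seed 7 --out fit/
rnapalloc simulate --config sim.yaml --out traj/
```

Subcommands: `generate` (synthetic assays: titration, competition,
regulator), `analyze` (modes: activity, fold, fractions, sums,
regression, orthogonality), `fit` (the one-parameter competition
model), `simulate` (allocated/unallocated time courses with
threshold-crossing reports).  Every run writes a `manifest.json` with
the seed, package version, and SHA-256 digests of inputs and outputs;
exit codes are 0 (ok), 2 (validation), 3 (numerical failure).

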