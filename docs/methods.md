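# Methods

## The model

Split T7 RNA polymerase separates promoter recognition from catalysis.
A C-terminal "σ fragment" carries the promoter-specificity loop and
binds an N-terminal "core fragment" to reconstitute an active
polymerase; variants of the σ fragment (T7, T3, K1FR, CGG) direct the
same core to different, mutually orthogonal promoters.  The core pool
is the shared, limiting resource: its level sets the total
transcriptional budget, and the relative expression of σ fragments sets
how the budget is divided.  Two further regulators act on the same
pool: a catalytically dead "null" σ fragment that sequesters core
without transcribing, and an α/β split of the core in which the short α
fragment must bind the β core before the core can accept a σ fragment.

### Equilibrium allocation

Binding of every σ fragment *i* (total `S_i`, dissociation constant
`K_i`) to active core (total `C`) is simultaneous bimolecular
association.  At equilibrium with free core `F`:

    complex_i = S_i · F / (K_i + F)
    F · (1 + Σ_i S_i / (K_i + F)) = C

The left side is strictly increasing in `F`, so the equilibrium is
unique.  `rnapalloc.model.equilibrate` solves it with Brent's method on
the bracket `[0, C]` (xtol `1e-18·C`, machine-precision rtol) followed
by two Newton polish steps; the conservation residual
`|F + Σ complex_i − C|` is verified to `1e-9·C` and typically sits at
machine precision (~1e-16 relative).  Promoter activity is assumed
linearly proportional to bound polymerase:
`activity(p) = basal_p + Σ_i eff_i · crosstalk[i,p] · complex_i`, with
the crosstalk matrix defaulting to the identity (the four fragments are
orthogonal).

α activation is modelled as an independent *prior* equilibrium
(sequential assembly: α binds β, the α:β complex then competes for σ
fragments).  The assembly order is not experimentally determined; the
sequential form was chosen because it separates cleanly into the
two-species association quadratic plus the ordinary allocation problem,
and each stage is independently testable.  The α:β complex is the
smaller root of the association quadratic, evaluated in the
cancellation-free form `2ab / (a + b + K + sqrt((a+b+K)² − 4ab))`.

**Titration limit (`K = 0`).**  `kd_core = 0` is accepted as the exact
tight-binding limit: fragments bind stoichiometrically while core
remains, and once `Σ S_i > C` the pool is split in proportion to totals
(the limit of the finite-`K` solution as a common `K → 0`).  In this
limit the bound-core shares equal `S_i / Σ_j S_j` — the
relative-expression closed form in `saturated_shares` — and the summed
budget is conserved exactly, which is the idealisation behind the
constant-sum behaviour of competing reporters.  Mixing zero and
non-zero `K` in one system is rejected: the limit is only well defined
when all affinities vanish together.  Note the closed form requires a
*common* affinity (or the limit thereof); with heterogeneous finite
`K_i` the partition depends on the `K_i` even when all are small,
because the free-core concentration is itself of the order of the
largest `K`.

### Units and identifiability

All concentrations and activities are in arbitrary units (AU).  The
model is scale-free: endpoint reporter assays identify only ratios
(shares, fold changes, slopes), so absolute affinities and expression
levels are conventions.  Defaults put the core total at 1 AU and
`kd_core = 0.01` AU — deep saturation, the regime the SynZIP-fused
fragments operate in.  The no-SynZIP variant is modelled as the same
system with `kd_core` raised 100-fold; over the induction range it then
binds weakly enough that activity keeps climbing where the tight
variant has been flat since half-maximal induction (it still reaches
~84% occupancy at the top of the grid — "weak" is relative to the
SynZIP case, not negligible binding).

## Dynamics

Species totals follow production/dilution kinetics
`d total/dt = production(t) − δ·total` with dilution δ = 0.69/h (1-h
doubling) and piecewise-constant production schedules.  The core pool
starts at its steady level `core_production/δ` (the allocator is
constitutive); σ totals start at zero.  Integration is fixed-step RK4
(default 0.01 h) with all stages sampling the production rate at the
step's left endpoint, which is exact for piecewise-constant rates and
keeps events from acting half a step early.

Because the SynZIP-fused fragments bind much faster than they dilute,
the core/σ partition is re-equilibrated algebraically at every step
(quasi-equilibrium).  An explicit-kinetics mode
(`quasi_equilibrium=False`) integrates the binding/unbinding reactions
with a stiff solver (LSODA, piecewise between schedule events) at
on-rate `1e4 /AU/h`; with `kd_core = 0.01` the off-rate is 100/h versus
δ = 0.69/h, a ~150-fold separation, and the two modes agree to ~0.3%
(tested at 2%).

In **allocated** mode every output is a σ fragment, so total bound
polymerase can never exceed the instantaneous active core total — the
structural guarantee of the architecture, asserted for random
schedules.  In **unallocated** mode every output is a complete
polymerase (`activity_i = eff_i · total_i`); activities superpose and
simultaneous outputs can cross a toxicity threshold that no single
output reaches.  Threshold crossings are reported as maximal intervals
of *strict* exceedance at the sampling resolution of the trajectory.

The time-course defaults are qualitative by design: no kinetic
constants for the circuit are available, so the point of the simulator
is the allocated/unallocated contrast and the threshold logic, not
curve-exact reproduction of any particular trajectory.

## Measurement model and inference

**Promoter activity.**  The geometric mean of replicate fluorescence
values minus the batch white-cell (autofluorescence) value.  Replicates
are per-sample summary values — event-level cytometry is not modelled,
so "geometric mean" here is over replicates rather than cytometry
events.  Negative background-subtracted activities are retained, not
floored.  A replicate of exactly zero gives a geometric mean of zero
(log-undefined values cannot occur because fluorescence is validated
non-negative).

**Fold induction** = white-cell-corrected activity over the
white-cell-corrected reporter-only (no polymerase) activity; undefined
when the denominator is non-positive.

**Fraction core utilized** = activity divided by the promoter's
single-σ saturation activity under the same allocator level.  In the
saturated noiseless model this equals the bound-core share exactly;
noisy values may exceed 1 and are not clipped.

**Sum constancy** reports the mean and coefficient of variation
(sample sd / mean) of per-induction-point activity sums over competing
promoters.  The cv is exactly zero only for the idealised conserved
budget — titration-limit affinities *and* equal transcription
efficiencies of the competing pair; with the realistic defaults
(`kd = 0.01·C`, K1FR/T3 efficiency ratio 1.04) the noiseless cv is at
the percent level and the noisy cv (10% replicate noise, triplicates)
is ~0.04.

**Core-ratio regression.**  Low-allocator activities regressed on their
paired high-allocator activities through the origin,
`slope = Σxy / Σx²`, unweighted.  The CI is a paired nonparametric BCa
bootstrap (scipy), default 1,000 resamples, seeded.  At the default
noise settings the 95% interval covers the true ratio in ≈93% of runs
(measured over 100 simulations); plain percentile intervals
under-covered (~85%) at n = 24 points, which is why BCa is used.

**One-parameter competition fit.**  With the pool saturated, the
induced fragment's bound fraction at expression `x` is `x/(x+s)` and
the constant competitor's is `s/(x+s)`; `s`, the competitor's relative
expression in the units of the calibration series, is the only free
parameter.  Both normalised curves are fitted jointly by least squares
on the fraction scale (the space in which the data are plotted), with
`s` log-parametrised to enforce positivity; the bootstrap resamples
induction points with their replicate rows.  Whether to fit one curve
or both jointly was an open choice; joint fitting uses all the data and
is self-consistent (the two residual sets share the single parameter).
Inducer-to-expression calibration uses piecewise-linear interpolation
of a measured series when one is available, with a Hill-model fit as a
smooth fallback.

**α copy-number compensation.**  For backbones differing in copy
number, the α dose is `strength × copy_number` and the required α total
for a target activity is found by 1-D root finding; strengths therefore
come out exactly inversely proportional to copy number.  The reporter
cassette also scales with copy number, but with polymerase limiting the
readout tracks bound polymerase rather than promoter dosage, so
reporter scaling drops out.  A full-length core (no α requirement)
offers no compensation knob and is reported infeasible.

## Synthetic data generator

The generator is a forward evaluation of the allocation model plus a
measurement layer:

    fluorescence = (activity + white_cell) × LogNormal(mean 1, cv)

Noise is multiplicative lognormal because reporter signals span four
orders of magnitude; additive noise would misrepresent low signals.
Noiseless generation (`noise_cv = 0`) is the exact forward model, which
the regression tests pin.  All randomness flows from one recorded seed;
identical seed and config give byte-identical CSV output.

Defaults encode the characterised study conditions, chosen once:

| parameter | default | basis |
| --- | --- | --- |
| IPTG grids (μM) | saturation 0…1000 (12 pts); competition 0…32 (12 pts); null 0…1000 (8 pts); α 0…40 (7 pts) | the assay grids of the characterisation experiments |
| replicates | 3 | three independent assays on different days |
| noise_cv | 0.1 | consistent with the small error bars of the assays; the true replicate scatter lives in source data not reproduced here |
| white_cell_mean | 40 AU | autofluorescence scale vs a 100 AU reporter-only baseline |
| core total / kd_core | 1.0 / 0.01 AU | deep-saturation (SynZIP) regime; ×100 kd without SynZIP |
| efficiencies (AU/complex) | T7 4.0e5, CGG 2.4e5, K1FR 1.2e5, T3 1.15e5 | <4-fold strongest/weakest spread; T7 plateau / reporter-only ≈ 4,000-fold; near-equal K1FR/T3 so competing raw sums stay near-constant |
| full-length control | 4× split plateau, flat in σ induction | split polymerase has about one quarter the full-length activity |
| induction | Hill, k½ = 10 μM, n = 2, 2% leak | P_Tac/P_Tet-style dose response; leak matches uninduced activity being non-zero |
| σ vmax / constant K1FR / null vmax / α vmax | 6.0 / 1.5 / 45 / 2.0 AU | saturating induced fragment; leaky constant competitor; ≥10-fold null suppression at full induction net of the 2% leak ((3+45)/(3+0.9) ≈ 12.3); α spanning sub- to super-stoichiometric |
| core_ratio | 0.36 | the measured low/high allocator activity ratio, used as the generator's truth for recovery studies |

What the generator does *not* emulate: event-level cytometry
distributions and gating, day-to-day batch effects (a single
multiplicative batch factor is available but defaults to 1), growth/OD
effects, and plasmid-context effects beyond copy-number scaling.
Passing tests therefore demonstrate correctness of the model and
inference chain under the stated noise model, not robustness to every
artefact of real cytometry data.

## Verification

The equilibrium solver is checked against an independent oracle —
integration of the mass-action binding ODEs (`kinetic_steady_state`,
stiff Radau solver, per-fragment on-rates `1/K_i` so all off-rates are
1/h and 60 time units suffice for relaxation).  Agreement over 200
randomised systems (1–6 fragments, `K` spanning `1e-4–1e2 × C`) is
~1e-13 relative, asserted at 1e-6.  Conservation is audited on 1,000
randomised systems (asserted 1e-9 relative; measured ~4e-16), and the
saturated-shares closed form on 200 systems with a common
`K ≤ 1e-4·C` and `ΣS ≥ 2C` (asserted 1e-3; measured ~2e-5).

Parameter-recovery studies run 20 seeds per condition: through-origin
slope recovery at core ratios {0.2, 0.36, 0.5, 0.8} (median relative
error ≤5%, CI coverage ≥90%) and one-parameter fit recovery at
s ∈ {0.2, 1, 5} (exact noiseless to 1e-6; median error ≤10% at 10%
noise).  Problem sizes (200/1,000 random systems, 20 seeds, 12-point
grids, 999 bootstrap resamples) are the package's verification
defaults; the whole audit runs in under a minute on one CPU.

## Known limitations

- Affinities, efficiencies, and expression levels are conventions in
  AU; only their ratios are meaningful, and none are fitted to real
  measurements.
- The saturated-shares model (and therefore the one-parameter fit)
  assumes a common σ:core affinity; heterogeneous affinities would bias
  the recovered relative expression.
- σ fragments are assumed to remain core-bound during transcription; no
  free/elongating distinction, no transcription-elongation kinetics, no
  SynZIP thermodynamics beyond an effective dissociation constant.
- The toxicity threshold is reported, not enforced: no growth-rate
  feedback couples total activity back onto dilution.
- Dynamic simulations are deterministic (no stochastic gene
  expression); the trajectories are smooth population averages.
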