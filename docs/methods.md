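# Methods

## The model

`phagedyn` implements a deterministic, well-mixed three-population model of
temperate-phage infection in batch culture.  The state is (E, E*, λ):
uninfected bacteria, lysogens, and free infectious phage, all as
concentrations.  Uninfected cells grow logistically (rate μ, capacity K);
lysogens have their own analogous parameters μ\*, K\*.  Phage adsorb to
cells by mass action with rate constant k_i.  A fraction f of infections is
lytic, destroying the cell and releasing a burst of b phage; the remainder
lysogenize.  Lysogens are immune to productive superinfection but still
adsorb phage, which only depletes the free pool.  Spontaneous induction of
lysogens into lysis occurs at rate k_s, zero by default.

All computation uses the non-dimensional form: τ = μt, populations divided
by K, giving

    dE/dτ   = E(1 − E) − κEλ
    dE*/dτ  = μ_r E*(1 − E*/K_r) + (1 − f) κEλ − σE*
    dλ/dτ   = f b κEλ − κEλ − κE*λ + b σE*

with κ = k_i K/μ, μ_r = μ\*/μ, K_r = K\*/K, σ = k_s/μ.  These right-hand
sides are the minimal system consistent with the mechanisms above:
per-population logistic self-limitation, mass-action removal of uninfected
cells, instantaneous burst (no latent-period class — the model has exactly
three populations), adsorption losses from both cell types, and induction
releasing the same burst size b.  Whether lysogens self-limit against their
own capacity or against the total bacterial population is genuinely open;
the default is self-limitation (the simplest reading of "separate
parameters"), and `NondimParams(shared_capacity=True)` switches to the
shared-resource variant.

### Key parameters

| symbol | meaning | default | why |
|---|---|---|---|
| κ (`k_i`) | scaled infection rate k_i·K/μ | 1.0 | center of the grid range producing realistic dynamics |
| b | burst size (phage per lysis) | 28 | reference infection point |
| f | lytic fraction | 0.75 | reference infection point |
| μ_r, K_r | lysogen growth/capacity ratios | 0.7 | standard fixed value for all simulations |
| σ | scaled induction rate | 0 | negligible without DNA-damaging stress |
| E0 | initial population (units of K) | 0.02 | fitted jointly with experimental-style logistic fits |
| MOI | phage per bacterium at inoculation | 2×10⁻⁴ | 15 µl of 10⁴ pfu/ml onto 15 µl of 0.1 OD cells |
| τ_end, n_out | horizon, grid | 12, 200 | covers the ~8–11 τ span of plate-reader runs |

### Numerical choices

Integration is adaptive RK45 (`scipy.integrate.solve_ivp`) with rtol=1e-3.
The absolute tolerance is 1e-8 rather than the conventional 1e-6: during
the lysis crash E passes through zero steeply, and at atol=1e-6 the
undershoot can reach ≈ −1.6e-6; atol=1e-8 bounds it near −1e-8 at no
measurable cost.  Negative values are clipped to zero only at reporting
(`clip=False` exposes raw solver output).  `simulate` accepts rtol/atol
overrides; closed-form comparisons (e.g. the κ=0 logistic limit) are made
at rtol=1e-10, which tests the equations rather than the routine solver
settings.  `overtake_time` ignores per-step declines below 1e-5, the scale
of solver wiggle on the logistic plateau.

## Curve pipeline

Raw plate-reader curves (OD600 vs hours) are processed exactly as an
infection screen would be analysed:

1. **Background fit** — the closed-form logistic (K, μ, E0) is fitted by
   least squares to a strain's uninfected replicates jointly (pooled
   points).  Baseline (media blank) is subtracted first; when no blank is
   supplied it is estimated as the minimum of the well's first three
   readings.  Flat curves (range < 0.01 OD) raise an error naming the
   strain.
2. **Non-dimensionalization** — τ = μt, y = (A − baseline)/K, floored at 0.
   This removes background growth-rate and capacity differences between
   knockout strains so that clustering sees the infection response, not the
   growth phenotype.
3. **Replicate averaging** — linear interpolation to a shared τ grid, then
   the pointwise mean.
4. **Smoothing** — robust lowess, window 0.1 of the points, 5 reweighting
   passes.
5. **Derivative profile** — a cubic smoothing spline is fitted and its
   analytic derivative evaluated on a 100-point grid common to the dataset
   (the intersection of strain τ ranges).

The spline stiffness is chosen by the discrepancy criterion: the residual
sum of squares is matched (by bisection on log λ) to n·σ̂², where σ̂² is a
third-difference noise estimate.  Generalized cross-validation was
evaluated and rejected: on replicate-averaged infection curves whose lysis
crash spans only 2–3 reader cycles, GCV systematically under-smooths, and
the resulting derivative spike varies enough between noise realizations to
push same-strain profiles up to ≈0.26 apart in cosine distance — past the
0.16 cluster cut.  The discrepancy rule holds same-strain profile distances
below ≈0.1 while leaving between-phenotype distances (≳0.4) untouched.  For
effectively noiseless input the rule degrades gracefully (third differences
cancel smooth trends to O(h³)) and GCV is used as the fallback.

## Clustering

Profiles are compared with the cosine distance 1 − cos θ, θ the angle
between derivative vectors: strains whose populations change in the same
direction at the same scaled times are close, regardless of magnitude.
The source describes this metric as "cosine distance ... 1−θ"; 1 − θ is
not a bounded similarity-derived distance, so 1 − cos θ is implemented.
Agglomeration is average linkage (`scipy.cluster.hierarchy`); flat
clusters are subtrees merged below 0.16.  scipy's linkage is deterministic,
which is what reproducibility requires; no custom tie-break rule or
leaf-reordering is layered on top.  Dendrograms export to Newick with
branch lengths equal to merge-height gaps.

## Simulation study

`run_grid` sweeps κ ∈ {0, 0.25, 0.75, 2, 5}, f ∈ {0, 0.5, 0.75, 0.95, 1},
b ∈ {0, 10, 20, 50, 100} (125 combinations, lexicographic order, μ_r = K_r
= 0.7 fixed).  Each trajectory is labeled:

- **Infectivity** — sup-norm deviation of total population from the
  uninfected reference; `none` below 0.05; `high` when the population
  clears (falls below 0.5 of its maximum after growth first turns to
  decline — measured from the decline onset, because lysogen regrowth can
  later exceed the pre-crash peak); otherwise `low`.  Both thresholds are
  soft and configurable.
- **Phage phase region** — λ constant → `no-adsorption` (κ=0); monotone
  declining → `no-production` (b or f effectively 0); rising without
  bacterial clearance → `low-production-accumulation`; rising with
  clearance → `productive-lysis`.

`parameter_effect_summary` tabulates overtake time (first decline of the
total population) and lysogen regrowth E*(τ_end); across overtaken grid
members the Spearman correlation between b·κ and overtake time is strongly
negative, while f controls lysogen regrowth.

`fit_parameters` fits (f, b·κ) to an observed normalized curve by bounded
Nelder–Mead from five fixed multi-starts over f ∈ [0,1] and log₁₀(b·κ) ∈
[−3, 3].  Only the product b·κ is reported: splitting one product across
alternate (b, κ) pairs changes the RMS loss by well under 1% of the curve
scale (the identifiability ridge), so b and κ are not separately estimable
from bacterial dynamics.  The simulation inside the loss conventionally
uses b = 28, κ = bk/28.  The free-phage time course breaks this
degeneracy, which is what the phase regions and the titer module measure.

## Titer module

Plaque-count series (pfu/ml at 90–415 min post-infection) are expressed as
fold change from the first sample.  The phenotype call (stable / declining
/ amplifying) is the 95% confidence interval of the OLS slope of log₁₀
titer vs time: an interval containing zero is stable.  On noiseless model
output the calls agree with the phase regions (no-adsorption → stable,
no-production → declining, productive → amplifying).

## Synthetic data generator

The generator emulates the structure of the screening experiment, not any
particular dataset: for each strain archetype, infected (λ0 = MOI·E0) and
uninfected (λ0 = 0) wells, 4 replicates each, measured over 38 reader
cycles; plaque counts are Poisson draws around λ(t) scaled to a chosen
expected count at the first sampling time.  Everything is bit-reproducible:
noise streams are keyed by (seed, strain, condition, replicate), so a
well's noise is independent of which panel it appears in (MOI-multiplier
panels reuse the same streams, i.e. paired wells).

Dimensional anchors, chosen once (none are given by the protocol): μ =
0.8 h⁻¹ and K = 0.5 OD — nutrient-broth-like growth for which 38 cycles of
17 min (≈10.8 h, first read after a 10-min settle) span ≈8.6 scaled time
units, comparable to the ~8–11 τ that real runs reach; baseline 0.04 OD;
additive Gaussian read noise, SD 0.005 OD.  The OD mapping is identity
scale (model population ≡ OD).

Built-in archetypes: wild-type-like (κ=1, b=28, f=0.75), entry-blocked
(κ=0), replication-blocked (b=0), rate-reduced (κ=0.05), lysogeny-biased
(f=0.3), clearance-delayed (κ=0.25, a grid value; productive lysis
overtaking growth late).  The planted-recovery panel is {wild-type-like,
clearance-delayed, entry-blocked}: the model itself dictates this choice,
since entry-blocked, replication-blocked and rate-reduced bacterial
dynamics are mutually indistinguishable (that indistinguishability is the
package's central identifiability result), and the lysogeny-biased dip is
only ≈0.1 deep (lysogens at μ_r = K_r = 0.7 refill the crash almost
immediately), leaving it within 0.1 cosine distance of no-effect curves.
Recovery checks use three replicate-averaged samples per archetype — the
averaged-curve-per-sample structure a screen's clustering actually
operates on.

What the generator does not emulate: evaporation/injection volume
dynamics, well-position and condensation artifacts, multiplicative or
correlated noise, biological replicate-to-replicate parameter variation.
Passing tests therefore demonstrate that the pipeline is correct and
well-conditioned under its stated statistical assumptions, not that those
assumptions exhaust real plate-reader data.

## Problem sizes

Default analyses run in seconds on one core: the 125-member grid at 200
output points, 200-seed logistic-recovery panels, and 100-seed
planted-cluster recovery (three archetypes × three samples × eight wells)
complete in under a minute together.

## Known limitations

- No latent period: bursts are instantaneous, so very early phage kinetics
  (first ~20 min) are not meaningful.
- f is a constant average over a decision that in reality depends on MOI
  and physiology.
- The λ → pfu/ml map requires an arbitrary scale (the plaque assay fixes
  it experimentally; the generator fixes it by target count).
- The infectivity thresholds (0.05 deviation, 0.5 clearance fraction) are
  soft boundaries for labeling, not fitted quantities.
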