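# Methods

This note records the model, the numerical choices, and the limits of what
the package's tests demonstrate.

## Crypt compartment model

A crypt system is modelled as a linear chain: a stem-cell niche of fixed
census X₁ whose cells divide symmetrically at rate λ (per day); a displaced
stem-cell pool X₂ fed by niche divisions, itself dividing at λ and
committing to differentiation at rate ν; R rounds of transit-amplifying
doubling at rate γ; and a postmitotic pool Z dying at rate δ. The niche is
a census, not a birth-death population: niche divisions displace a
neighbour into X₂, so X₁ never fluctuates. Homeostasis requires ν > λ;
otherwise the displaced pool grows exponentially, which the model equates
with tumour initiation. All pool means have closed forms; the postmitotic
mean is `Z* = 2^R νλX₁/(δ(ν−λ))`, independent of γ. A consequence worth
noting is amplification: a proportional change in λ or ν moves Z* by a
larger proportion, because the (ν−λ) denominator shrinks as the rates
approach each other.

ν is never measured directly; it is derived from the steady state of the
displaced pool given a measured total stem-cell census
(`ν = λ·total/(total − X₁)`): 0.333/day for the mouse small intestine
(λ = 0.2, 6 of 15 stem cells in the niche), and 0.172 or 0.321/day for the
human colon (λ = 1/7, niche 6 or 20 of 36).

The ODE integrator is LSODA at rtol 1e-9: γ exceeds the stem-cell rates by
an order of magnitude, which is mild stiffness but enough to prefer a
stiff-capable method.

The partition of Z* into in-crypt (130 cells for the mouse) and villus
cells is a reporting constant stored on the scenario preset, not a model
state. The mouse villus budget is reported as 8 × (576 − 130) = 3,568
cells, consistent with observed villi of ~3,500 cells.

## Distribution of fitness effects and fixation

Fitness-affecting mutations arrive at rate μ per cell division and multiply
the targeted rate by a random factor: beneficial with probability P_B
(exponential displacement, mean s₊), deleterious otherwise (mean s₋).
Division-rate mutations are under selection inside the niche; the fixation
probability of a lineage with relative rate r on a one-dimensional ring of
X₁ cells is `(1 − r⁻¹)/(1 − r^(−X₁))`. Differentiation-rate mutations are
invisible to niche competition and fix neutrally at 1/X₁; for them the
beneficial direction is a *decrease* in ν (the lineage contributes longer),
so the DFE branches are mirrored.

Defaults follow a Saccharomyces cerevisiae mutation-accumulation
parameterization: μ = 1.26e-4 per division, s₊ = 0.061, P_B = 5.75%, and
s₋ = 0.217 (diploid-strain mean fitness decline per fixed mutation). These
are the only biologically calibrated DFE numbers used anywhere; everything
else is derived.

Truncation at rate 0. The branch pointing at zero (deleterious for
division, beneficial for differentiation) loses tail mass e^(−1/s) below
zero. The package renormalizes that branch alone, so branch weights stay
exactly P_B and 1 − P_B and P_B keeps its measured meaning; the same
convention is what truncated sampling in the stochastic ratchet produces.
Renormalization is a flag (`renormalize`, default true); it moves p̂ (hence
μ̂) by ~1% at s₋ = 0.217 and leaves the fixation posterior itself
unchanged.

## Posterior and recursion

The rate density after one fixation is the DFE weighted by the fixation
probability and normalized; the normalizer p̂ is the total fixation
probability, and `μ̂ = p̂ μ λ₀ X₁` is the arrival rate of fixed lineages
per crypt (for either target, the mutant supply scales with niche
divisions, λ₀X₁). Successive fixations propagate the density through a
discretized Markov kernel K(x|ℓ) = Φ(x|ℓ), built once per (grid, X₁, DFE,
target) as a dense matrix and applied by matrix-vector product; the needed
iteration depth is set by the Poisson tail (see below) and stays in the
tens.

Numerical scheme. All integrals are trapezoid sums on a linear rate grid
(default 2¹³ points; the constant-output scan uses 2¹² after grid-doubling
checks showed 4-digit agreement). The grid always contains the baseline
rate as a node; the DFE has a jump there, and the node is assigned the mean
of the one-sided limits, which cancels the leading trapezoid error across
the jump. Grid spans are 20 e-folds of the relevant exponential scale per
expected fixation (truncated tail ~1e-9); columns of the kernel are
normalized on-grid, so propagation conserves mass by construction, and a
boundary guard raises if more than 1e-6 of probability accumulates in the
outer 1% of the grid (the cue to rebuild with a larger span).
`fixation_probability` is evaluated as expm1(−ln r)/expm1(−X₁ ln r), which
is numerically stable through the neutral point r = 1; the removable
singularity itself returns 1/X₁.

## Tissue dynamics

Fixed-mutation counts per crypt are Poisson(μ̂t); the per-crypt cap m̂ is
the smallest count with upper-tail mass below 1e-10. The expected
epithelium follows `Z*(t) = Z*_total − Σ_m n_m (Z*_normal − Z*_m)` with
`Z*_m` obtained by substituting the *expected* rate after m fixations into
the steady-state formula (the model's construction). The alternative —
averaging Z* over the rate density — is exposed as `z_expectation_mode`;
because Z* is convex in λ and diverges at the homeostasis boundary, that
expectation is taken conditional on rates at least a relative 1e-3 inside
the homeostatic region, and it yields slightly *less* predicted decline
(Jensen gap ~15% of the decline at mouse parameters).

The attrition curves are nearly linear, and a first-order expansion in the
first fixation gives closed-form slopes: division
`−θλ₀μp̂X₁(r_λ−1)/(r_λ−θ)`, differentiation `−μλ₀(r_ν−1)/(θr_ν−1)`, with
θ = ν/λ₀. The differentiation slope contains neither X₁ nor p̂ — the 1/X₁
neutral fixation probability cancels the X₁-fold mutant supply — so
attrition from neutrally fixing mutations is exactly niche-size invariant.
Human scenarios are computed from the slopes alone: they are free of γ, δ
and R, which are not reliably measured in humans (the human presets carry
mouse TA/postmitotic kinetics only so full trajectories remain runnable).
Observation windows default to 3 post-adulthood years for the mouse
(1,095 d) and 75 for humans (27,375 d), overridable per scenario.

## Tumorigenesis and the niche-size trade-off

A crypt turns tumorigenic when its rate ordering inverts (division target:
rate drifts above ν; differentiation target: below λ). Crossing
probabilities q_m are one-sided tail masses of the m-fixation densities.
The aggregation over "all mutations in all crypts" is ambiguous; the
default combines Poisson crypt counts with incremental crossings
`Σ_m n_m (q_m − q_{m−1})` (a crypt contributes the chance its latest
fixation newly crossed), with the literal cumulative `Σ_m n_m q_m` as a
flag. At the study parameters the two differ by under 1% and the scan's
optimum is identical under both, as it is under survival-weighted variants;
the choice is immaterial here but kept explicit. q_m is non-decreasing over
the first several fixations and can decline deep in the sequence (the bulk
drifts away from the threshold) where Poisson weight is already ~1e-12; no
clamping is applied.

The scan varies X₁ with the half-in-niche rule (ν = 2λ, i.e. the niche
holds half the putative stem cells) and rescales the crypt count as
C(X₁) = Z_ref/Z*(X₁) so total tissue output is constant. Absolute tumour
probabilities scale with the reference output (crypt-count presets are
order-of-magnitude literature censuses: 1e6 mouse, 1e7 human); the optimum
location and all attrition values are scale-free. For division-target
mutations the scan exhibits an interior risk-minimizing niche size — at
mouse parameters and a 3-year window the computed minimum sits at X₁ = 6
with X₁ = 7 within half a percent; the minimum is very flat, and its
location slides to 7 for windows near one year — while attrition worsens
monotonically as niches shrink. For differentiation-target mutations risk
falls monotonically with niche size and attrition does not move at all.

## Stochastic simulators

Three exact (event-driven, no tau-leaping) simulators validate the analytic
pipeline rather than power it:

* `gillespie_crypt` realizes the crypt transition list with X₁ held fixed;
  ensemble means match the ODE solution within Monte-Carlo error.
* `ring_fixation` places one mutant on a ring of X₁ cells; each cell
  divides at its own rate and replaces a uniformly chosen adjacent
  neighbour (a directed variant is a flag; the neutral symmetry is
  unaffected). The mutant set stays a contiguous arc, which the
  implementation exploits as a data structure while simulating every
  division event. Fixation frequencies reproduce the closed form, and
  division counts give the expected number of new fitness-affecting
  mutations arising while a lineage segregates — averaged over all decided
  lineages (fixed or lost), since that sojourn is what the
  one-mutation-at-a-time assumption is about. At yeast μ and mouse λ it
  stays below one for all scanned niche sizes (0.16 at X₁ = 50);
  conditioning on fixation alone would exceed one above X₁ ≈ 37.
* `serial_ratchet` draws effects from the (truncation-conditioned) DFE and
  accepts with the fixation probability; ensemble means after m fixations
  match the kernel recursion.

All draw from `numpy.random.default_rng(seed)`; identical seeds give
bit-identical tallies. Default replicate counts (1e5 for fixation
frequencies, hundreds for crypt ensembles, thousands for the ratchet) make
3-standard-error bands decisive at desk scale; the test suite uses smaller
ensembles chosen for the same property.

## What the synthetic data does and does not show

The generators emulate the model's own stochastic processes, so passing
tests demonstrate internal consistency — that the quadrature, recursion and
closed forms correctly compute the model — not that the model describes
real crypts. Known idealizations: well-mixed ring geometry (spatially
explicit niches weaken selection); no Paneth cells, crypt fission,
asymmetric division, or compensatory feedback on mutant crypts; a single
exponential-mixture DFE with one global μ for both targets; one mutation
segregating at a time; tumorigenesis as bare rate inversion with no
multi-hit genetics. Absolute tumour probabilities and attrition magnitudes
inherit the DFE's uncertainty and the arbitrary crypt census; directions,
orderings, and the existence/location structure of the trade-off are the
robust outputs.

## Degenerate inputs and failure modes

Non-homeostatic parameter sets raise a dedicated error wherever a steady
state is required and are excluded (with a log entry) from scans; expected
rates crossing the tumour threshold make the trajectory error and point to
the tumour pipeline; thresholds outside a density grid, or mass escaping
it, raise grid-extension errors rather than silently truncating. DFEs with
effect scales far below the grid spacing are not resolvable; the drift
limit is exercised at scales the default grids resolve (≥1e-2).
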