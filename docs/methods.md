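# Methods

## Model and assumptions

The package models a single mushroom body compartment as a streaming linear
classifier. The MBON output is `z_t = max(w·x_t − b, 0)`; a silent MBON
(`z = 0`) is the prediction that the unconditioned stimulus is present. The
normative target is LDA: equal-covariance Gaussian class-conditionals with
means `μ₀` (neutral) and `μ₁` (conditioned), shared covariance `Σ`, and
class-1 frequency `π₁`. The online rules assume DAN activity is temporally
sparse (`π₁ ≪ 1`): the class-0 statistics can then be estimated from plain
running means over (almost all) steps, and the class-1 mean is estimated
through the elapsed-time counter `ℓ`, whose conditional mean at DAN events
is `1/π₁`. All state is double precision; a step never mutates its input
state (the array-based runner works on private copies).

Within a step the update order is fixed: output from the pre-update
`(w, b)`; then `t ← t+1`; then, on the silent branch, the running means
`μ₀,t` and `ζ_t`, the threshold, the weights (using the already-updated
statistics and the pre-update `c`), and finally `ℓ ← ℓ+1`; on the DAN
branch, the threshold (target `½ℓc − log ℓ`), the weights
(`Δw = −η ℓ x`), and `ℓ ← 1`. The running means use the global step index
`t` as denominator, not a per-class counter. The learning rate
`η_t = η₀/(1+γt)` is evaluated at the post-increment `t`.

Weight initialisation defaults to `w = 0` (an option draws Gaussian(0, σ²)
entries from a seed): the zero start keeps early behaviour deterministic and
the first silent steps immediately pull `w` toward `μ₀`. `μ₀,0` and `ζ₀`
start at 0; the `1/t` running mean makes the first silent sample overwrite
them exactly, so that choice is inert. `ℓ₀ = 1`, so a DAN event at the very
first step uses `log 1 = 0` with no special-casing.

### Variants

* `fixed_ell`: `ℓ` is replaced by a constant `ℓ*` — by default in **both**
  the weight and threshold updates (`fixed_ell_bias=False` selects the
  weights-only alternative, since the published description of the variant
  does not fix this detail).
* `graded_dan`: `y` may be any nonnegative scalar; the active branch is
  taken when `y > 0` and the depression becomes `Δw = −η ℓ y x`. The
  threshold recursion is kept as printed (the variant is defined only
  through its weight update); at `y = 1` the variant reproduces the
  standard rule exactly.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `eta0` | initial learning rate | 0.1 | grid-search optimum on the two-Gaussian stream |
| `gamma` | learning-rate decay | 1e-3 (Gaussian), 1e-2 (KC surrogate) | grid-search optima per dataset (see below) |
| `T` | stream length | 100 000 | standard run length of the accuracy experiments |
| `window` | accuracy window | 100 | the running-accuracy statistic's definition |
| `repeats` | runs per condition | 10 | mean with min–max envelope |
| `epsilon` | KC noise variance | 0.01 | conditioning noise added to the odor templates |

The grid search scans `η₀ ∈ {1, 10⁻¹, 10⁻², 10⁻³, 10⁻⁴}` ×
`γ ∈ {10⁻², 10⁻³, 10⁻⁴, 10⁻⁵, 10⁻⁶}`, scoring terminal windowed accuracy
averaged over repeats on shared streams (a paired comparison), with a
deterministic tie-break toward larger `η₀`, then larger `γ`.

Hyperparameters are calibrated **per dataset**, because the homeostatic
rule's stochastic stability depends on the input scale: each silent step
multiplies the weight error by roughly `I − η(x−μ₀)(x−μ₀)ᵀ`, so
`η‖x−μ₀‖²` persistently above ~2 lets the weights diverge. The packaged KC
surrogate has `‖x−μ₀‖² ≈ 20–40` (twelve unit-scale active units per
template), which puts a slowly-decaying `η₀ = 0.1` at the stability edge —
some template draws diverge outright. The surrogate's own grid search
(the default grids above, three template seeds, paired streams) selects
`(η₀, γ) = (0.1, 10⁻²)` — the faster decay confines the large-`η`
transient to the first few hundred steps — and that is the shipped
`DEFAULT_KC_CONFIG`. The optimum reported for real calcium-imaging KC
recordings, `(0.1, 10⁻⁴)`, is kept as `KC_RECORDING_CONFIG`; it is
appropriate for that data's response scale, not for arbitrary inputs.

## Synthetic data

**Two-Gaussian stream.** Defaults `μ₀ = (1, 0)`, `μ₁ = (−1, 0)`, `Σ = I`:
Mahalanobis separation 2, so the classes overlap and the Bayes accuracy is
below 1 for every prior (0.930 at `π₁ = 0.1`, 0.841 at 0.5). The same
geometry is reused across the `π₁` sweep; only the label frequency changes.
Label schedules: `bernoulli` (i.i.d.), `periodic` (an event every
`1/π₁` steps; requires `1/π₁` integral), and `irregular` — inter-event gaps
drawn from a mixture (gap 1 with probability 0.5, else `1 + Geometric`)
with the mean pinned to `1/π₁`, giving much higher gap variance than the
Bernoulli schedule at the same rate. The irregular schedule exists to probe
the Jensen effect in the threshold recursion (below).

**KC surrogate.** Real odor-evoked KC recordings are not redistributable,
so the generator emulates their structure: 7 odor templates over 124 units,
each template supported on `round(0.10 · 124) = 12` units chosen uniformly
(supports independent across odors, expected pairwise overlap
`0.10² · 124 ≈ 1.2` units), magnitudes i.i.d. Gamma(shape 2, scale 0.5) —
mean 1, strictly positive. Sparsity 0.10 reflects the sparse-coding regime
of the KC population; presentations are uniform i.i.d. over odors with
isotropic Gaussian noise of variance `ε = 0.01` per unit. What this
surrogate does **not** emulate: trial-to-trial gain fluctuations,
correlated noise across KCs, overlapping odor-specific reliability, or any
temporal odor structure — so passing accuracies here (≈0.9–1.0) say the
algorithm solves the geometry of sparse, nearly separable codes, not that
it reaches any particular accuracy on biological recordings. With class-1
loads of 1–3 odors out of 7, `π₁ = 1/7, 2/7, 3/7`.

All generators are pure functions of their spec, seed included; experiment
harnesses derive per-repeat seeds as `seed + r` and freeze the KC templates
across repeats (only presentation order and noise vary).

## The threshold's Jensen bias, and a known accuracy plateau

The DAN-branch threshold target `½ℓc − log ℓ` uses `log ℓ` as a stand-in
for `log(1/π₁)`. Since `log` is concave, variable inter-event intervals
make `E[log ℓ] < log E[ℓ]`, so irregular DAN timing inflates the learned
`b`: the MBON becomes less active, predicting the stimulus more often. The
package tests this directionally (periodic vs high-variance schedules at
equal `π₁`) and reports the gap.

A second, structural property follows from the same recursion: `b` is a
running average over **all** steps, so the `−log ℓ` correction enters with
weight `π₁` (its occurrence frequency), giving a stationary threshold near
`½w·(μ₀+μ₁) − π₁E[log ℓ]` rather than the offline
`½w·(μ₀+μ₁) + log(π₁/π₀)`. When the prior term dominates the geometry (the
default two-Gaussian stream at `π₁ = 0.1`), the learned threshold sits
about one projected standard deviation above `b_opt` and the terminal
accuracy plateaus near 0.87 against a 0.93 Bayes ceiling. This is a
property of the recursion as published, reproduced deliberately; the
package therefore treats threshold optimality as directional, not exact.

## Numerical choices

* The inner loop is JIT-compiled (numba) and kept operation-for-operation
  identical to the pure-Python `step()`; a test asserts bitwise equality of
  whole trajectories for all three variants.
* Offline solves use a Cholesky factorisation, never an explicit inverse;
  condition numbers above 1e12 raise an error carrying the diagnostic. The
  matrix exponential in the gradient flow uses the symmetric
  eigendecomposition.
* The Bayes accuracy is closed-form:
  `π₀Φ((m₀−b)/s) + π₁Φ((b−m₁)/s)` with `m_i = w_opt·μ_i`,
  `s² = w_optᵀΣw_opt`. Ties (`c = b`) classify as class 1, matching the
  strict `z > 0` rule; they carry zero probability under the model.
* Degenerate inputs: `μ₀ = μ₁` yields `w_opt = 0` and an accuracy equal to
  the larger prior; empty streams, inconsistent dimensions, and labels
  outside the variant's domain raise typed errors.
* `eta0 = 0` is accepted and freezes the weights while the threshold and
  running statistics continue to evolve (a useful probe configuration).

## Problem sizes

Default experiment sizes — `T = 10⁵` streams, 10 repeats, `T = 2×10⁵`
(and 10× that for the trend check) for the weight-recovery experiment,
50 random SPD problems for offline consistency — were chosen so the full
reproduction script completes in about a minute on a single CPU while
keeping Monte-Carlo standard errors well inside the tested tolerances.

## Limitations

No spiking or calcium dynamics, no dopamine kinetics, no sign constraints
on `w` (Dale's law is deliberately not imposed), no KC feedback circuitry,
and no loader for proprietary recordings (any user matrix can be streamed
through the delimited-text reader). The threshold recursion's stationary
bias (above) is inherited from the model itself.
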