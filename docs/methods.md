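# Methods

This note records the modelling conventions, numerical choices and known
limitations of `facemaxent`, at the level a maintainer or reviewer needs
to judge what the computations do and what the tests do and do not show.

## Data model and conventions

A facial vector stacks the landmark coordinates as
`r = (x₁…x_n, y₁…y_n)`, in units of the facial height, with `y` pointing
down (image convention); a `y_axis` flag flips orientation for angle
histograms and plots only, never for statistics. Fluctuations are
`Δ = r − ⟨r⟩` with `⟨·⟩` the average over all records.

The face-space constraints make the `2n = 16` coordinates exactly
rank-deficient: the covariance has `k = 6` eigenvalues that are zero up to
round-off. `find_constraints` classifies an eigenvalue as a null mode when
it is below `rel_tol = 1e-10` times the largest — the constraints are
exact by construction, so the spectral gap is many orders of magnitude and
the threshold is uncritical. The non-redundant representation keeps
`D = 2n − k` coordinates chosen greedily: while the covariance restricted
to the remaining coordinates is rank-deficient, drop the coordinate with
the largest total squared loading on the current null basis (ties broken
by lowest index). Only the span of the retained set matters for
likelihoods; the specific choice is a deterministic convention.

## Gaussian (order-1/2) maximum entropy

Hamiltonian convention: `H₂ = ½ ΔᵀJΔ − hᵀΔ`, chosen so that the
maximum-likelihood solution reads `J = C⁺`, `h = J⟨Δ⟩` with both signs
consistent (with the opposite sign for `h` the fitted mean would be
`−⟨Δ⟩`; the distinction is invisible on centred data but matters for
per-class fits, whose class means are non-zero in the pooled frame).

The density is defined with respect to Lebesgue measure *on the support
subspace*: `log Z = (rank/2)·log 2π + ½ log pdet C + ½ hᵀCh`, with the
pseudo-determinant over non-null eigenvalues. Evaluating the density at a
point with off-support components projects them out and emits a warning —
returning `−∞` was rejected because measurement noise puts real vectors
slightly off-support and classifiers must still rank them. The
pseudo-inverse tolerance is tied to `find_constraints`' `rel_tol`.

Exact sampling uses the eigendecomposition of `C`; null directions carry
exactly zero fluctuation, so samples respect the constraints to machine
precision.

## Cubic (order-3) maximum entropy

The cubic Hamiltonian `H₃ = (1/6) Σ_{μνκ} Δ_μΔ_νΔ_κ Q_{μνκ}` runs over
all ordered triples with `Q` symmetric; `Q` is stored compactly on
`μ ≤ ν ≤ κ` with multiplicities 1/3/6. The density is truncated to
`[−B, B]^D` with `B = 6` in standardised units (configurable).

**Learning** is moment-matching stochastic gradient ascent: the gradient
for each independent parameter is the data moment minus the model moment,
with model moments estimated from 64 persistent Metropolis chains
(full-vector Gaussian proposals shaped by the model's Gaussian part,
scale adapted to ~40% acceptance and then re-adapted slowly). Numerical
safeguards, each of which proved necessary in practice:

* *Growing moment window.* Chain moments are smoothed by an exponential
  moving average whose window grows with the iteration (~t/10, capped at
  1/(1−0.995)), so the stopping rule compares low-noise estimates.
* *Residual clipping.* Per-moment residuals entering the update are
  clipped to ±1: inside the hypercube a transiently mis-parametrised
  model can place chains at coordinates of order `B`, whose moments
  (~`B³`) would otherwise throw the parameters.
* *Mode guard.* During learning, intermediate parameter values can open
  deep metastable spikes in remote hypercube corners; a chain that falls
  in gets pinned (its local energy is tens of nats below the data mode)
  and wrecks the moment estimates. Chains more than 15 nats below the
  ensemble's median energy are reset to central draws. This amounts to
  fitting the model restricted to the data-supported mode, which is the
  object the classifier needs.
* *Polyak averaging.* If the residual never crosses the tolerance
  (`0.02` on standardised moments), the returned parameters are the
  average over the final half of the iterations, damping the MCMC noise.
* Learning rate `0.05/√t`, at most 2000 iterations; divergence is
  declared only for sustained, order-of-magnitude residual growth.

**Stability limit.** A hypercube-truncated cubic density in dimension
`D ≈ 10` can only represent moderate third moments: matching a
standardised third moment `m₃` requires couplings of order `m₃/2.5`, and
once the worst-corner cubic energy `~(1/6)|Q|B³` rivals the quadratic
cost of reaching that corner, the maximum-likelihood density acquires
corner spikes and MCMC learning loses ergodicity. In practice
standardised third moments above ~0.5 put the fit in this marginal
regime. The mode guard keeps the fit usable there, but moment residuals
plateau above the tolerance; fitted models still rank test points
correctly because likelihood-*ratio* scores depend on the Hamiltonians,
not on the per-class normalisations.

**Normalisation.** For `D ≤ 2`, `log Z₃` is computed by adaptive
quadrature over the hypercube. In higher dimension it is estimated by
annealed importance sampling: the base is the Gaussian part truncated to
the hypercube (normalisation `Z₂` times a Monte-Carlo box probability),
and the cubic term is switched on along a linear path in `β` with
Metropolis transitions at 200 temperatures. A single-stage importance
sampler from the Gaussian part is unusable for strong `Q`: the integral
is then dominated by hypercube-boundary regions many nats above the
Gaussian mode, which the proposal essentially never visits (effective
sample sizes of order 10 at 50,000 draws). An effective-sample-size guard
(< 100) raises rather than returning a silently biased estimate. In the
classification pipeline a failed estimate falls back to the
Gaussian-part normalisation with infinite recorded stderr; this shifts
each class's scores by a constant and therefore leaves ROC curves,
auROC and maximal accuracy unchanged.

Outside the hypercube the log density returns a finite large-negative
sentinel (−1e30) rather than raising, so classifiers can rank
off-support points.

## Gaussian–Bernoulli RBM

Energy convention:
`E(v,h) = Σ_i (v_i−b_i)²/(2σ_i²) − Σ_j c_j h_j − Σ_{ij} (v_i/σ_i²) W_{ij} h_j`,
the common Gaussian-visible form; the free energy uses overflow-safe
softplus. The marginal variance of a GRBM is the visible noise `σ²` plus
whatever the hidden layer contributes, so on standardised (unit-variance)
data the visible scales must sit *below* the data scale or the hidden
units have nothing left to model — with `σ = 1` the trained model is
provably unable to represent any unit-variance correlated target.
Scales are therefore fixed at `sigma_factor = 0.5` times the per-column
data standard deviation (overridable, including an explicit vector for
well-specified teacher–student experiments). Learnable scales were
rejected: training instability outweighed the benefit at these sample
sizes.

Training is CD-1 (minibatch 64, learning rate 5e-3, momentum 0.5→0.9 at
epoch 5, 600 epochs). CD's short negative chains match the
*reconstruction* mean rather than the equilibrium mean, leaving an
offset in the sampled marginal; after training, the visible biases are
calibrated by a damped fixed-point iteration (step `½σ²/Var(data)`, the
inverse of the mean-response gain) until the model's first moment matches
the data. A persistent-chain (PCD) variant exists behind a flag but is
off by default — with these learning rates it proved less stable than
calibrated CD.

`log Z` is estimated by AIS from the `W = 0` base model (closed-form
normalisation) along the geometric path obtained by scaling `W`, 1000
temperatures and 100 runs by default, stderr over runs.

## Classification protocol

Per-class split at `train_fraction = 0.2` (training fraction), unit
either `vector` or `subject`. Vector-level splitting leaks subject
identity across the split (a subject's other sculpts are in the training
set), which inflates accuracy whenever subjects are individually
distinctive; subject-level splitting is the conservative choice and the
one used for null (identical-class) checks, where the vector-level split
is demonstrably anti-conservative. Both modes are first-class.

Preprocessing (pooled mean, constraint basis, per-coordinate scales) is
fitted on the pooled training data and applied frozen to both classes and
the test set. Class moments are taken about the pooled-frame origin so
the class mean remains part of the sufficient statistics — it is exactly
what the order-1 model discriminates on.

ROC curves sweep thresholds over the sorted unique scores (ties grouped,
diagonal steps); auROC by trapezoid; maximal accuracy at empirical class
proportions, maximised over thresholds on the test scores (an optimistic
convention, stated as such). The PC t-test baseline projects on pooled
principal axes, computes per-axis Welch t-statistics between the class
projections, and scores a test vector by the t-weighted sum of its
standardised projections — one concrete reading of "a t-test on the
principal components", declared as this package's construction.

## Interaction tables

For landmark pair `(i, j)` with mean segment direction `û` at angle
`α_ij` (quadrant-aware) and normal `v̂`, the longitudinal and torsion
components of a matrix `M` are the quadratic forms `ûᵀM_ij û` and
`v̂ᵀM_ij v̂` of the 2×2 cross-block. This definition is
rotation-equivariant and reduces to the `xx`/`yy` entries for
axis-aligned segments; it deliberately excludes diagonal-block
contributions (a full spring-network reading would include them — the
cross-block projection is this package's declared choice). `J` is fitted
on the full 16-coordinate frame via the pseudo-inverse, so pair blocks
are well defined without back-mapping from reduced coordinates.

Bootstrap errors resample subjects by default (vectors within a subject
are dependent); vector-level resampling is available for data without
subject structure. `t = |value|/σ`, significance at `t > 1`; `σ = 0` with
a non-zero value yields `t = ∞` with a flag rather than an error.

## Synthetic studies

`make_two_class_study` draws, per class, subject-level preferred faces
from an inter-subject Gaussian (seeded random covariance with a gently
decaying spectrum, scale 0.02 facial heights), adds within-subject noise
at `intra_to_inter_ratio = 0.25` of the inter-subject covariance (chosen
once as a convention: sculpting repetitions scatter noticeably less than
subjects differ from each other), and maps everything through a seeded
random rank-10 projector to plant exactly 6 constraints. Defaults mirror
the study scale: 8 landmarks, 28 repetitions, ~95 subjects across both
classes.

Class differences are planted at a chosen order: a mean shift of 0.5
inter-subject standard deviations (order 1); an eigenvalue stretch of the
inter-subject covariance by 1.75 with matched means (order 2); or skewed
subject-level latents — standardised gamma with shape 4, skewness 1 per
latent coordinate — followed by an exact affine whiten/re-colour of class
B's records to class A's sample mean and covariance (order 3), leaving a
pure third-and-higher-order difference. The skewness default is set at
the top of the range a hypercube-truncated cubic model can stably
represent (see the stability limit above); stronger skew produces data
whose maximum-entropy description at order 3 is corner-dominated and not
learnable by any moment-matching MCMC, which is a limitation of the model
class, not of the generator.

What passing tests on these studies show — and what they do not: the
generator reproduces the *structure* the analysis relies on (exact
constraints, subject clustering, moment-matched planted differences), but
its Gaussian-plus-skew populations are far cleaner than real sculpting
data, which carries intra-subject drift, algorithmic artifacts of the
sculpting interface, and third moments of unknown provenance. Results on
synthetic studies validate the machinery, not any claim about faces.

## Problem sizes

Default test and acceptance runs use: planted-coupling recovery at
`D = 3`, 50,000 draws, `B = 2.5` (a genuinely non-Gaussian but
normalisable regime; at `B = 6` a coupling of 0.5 makes the true density
corner-dominated and the problem ill-posed); classification on 60
subjects per class × 28 repetitions; teacher–student GRBM at `D = 6`,
`N_h = 4`, 6,000 training draws; bootstrap tables at 80–100 replicas.
These sizes give each check a comfortable signal-to-noise margin while
keeping a full run in the tens of seconds.
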