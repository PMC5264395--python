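# Methods

## Model

One hierarchical Poisson encounter model covers SCR, SMR and SC. A
superpopulation of M individuals carries latent activity centres
s_i ~ Uniform(S) and inclusion indicators z_i ~ Bernoulli(ψ),
ψ ~ Beta(1, 1); the realised population is N = Σ z_i and density
D = N / area(S). Expected counts at device j in occasion k are

    μ_ijk = z_i (1 − dead_ik) λ0_ijk exp(−d_ij² / 2σ²) e_jk,

with the baseline rate per device-day log-linear in three covariates:
prior capture anywhere (Lb, coefficient b1), device class (tt = 1 for
cameras, 0 for live traps, b2) and a standardised linear occasion trend
(t, b3), each gated by a binary inclusion indicator. Identified individuals
(all of them in SCR; the marked subset in SMR) contribute their full
capture histories y_ijk; everyone else contributes only through the
device-by-occasion totals n_jk, which by superposition of independent
Poisson individuals satisfy n_jk ~ Poisson(Σ_i μ_ijk) over the unmarked
pool. In SCR the same term appears with n ≡ 0, i.e. as the all-zero-history
probability exp(−Λ_i) of the augmented individuals. Telemetry fixes are iid
bivariate normal with per-axis sd σ around the centre, shared with the
encounter model when the collared animal is identified there; unlinked
collared animals inform σ only, through their own latent centre.

Assumptions worth stating: activity centres are static over the survey
(hence a closed population up to known removals); the detection kernel is
isotropic half-normal with one σ shared by marked and unmarked animals;
effort acts multiplicatively in days; marked animals are a random sample of
the population (marking effort spread across the grid); unidentified counts
are independent across devices given the latent centres.

### Removals

A known extraction during occasion k leaves the individual at risk within
k (its removal-occasion detections are real data) and removes it from
occasion k+1 onward; `build_encounter_data` therefore sets dead[i, k'] = 1
for k' > k and validation rejects any later identified event. Reported
density uses the full superpopulation N (animals exposed to sampling during
the survey); a removal-adjusted N (N minus the known extractions) is
reported alongside.

### Priors

* Coefficients (α0, b1–b3): Normal(0, precision 0.1) in the BUGS
  convention (sd √10 ≈ 3.162) or Uniform(−100, 100); both specifications
  are exposed because indicator-based model weights are known to be
  prior-sensitive.
* σ: either noninformative Uniform(0, u) — the default u is 5× the
  design-stage σ̂ (2,000 m for a 400-m design), wide enough to be flat over
  every plausible scale while excluding the unidentifiable regime in which
  σ exceeds the state space — or an informative truncated normal derived
  from literature home ranges: the mean and range endpoints are pushed
  through σ = √(HR/πq) and the scale set to (σ_high − σ_low)/4, so the
  stated range spans ±2 prior sd (e.g. a 975-ha badger home range with
  475–1,475-ha spread gives σ ~ TruncNormal(719.7, 95.7², σ > 0)).
  The exact distributional family of such field-derived priors is a
  judgement call; the truncated normal was chosen for its explicit
  location/scale reading of "mean and covered range".
* ψ: Beta(1, 1); indicators: Bernoulli(1/2).

### Model selection

Kuo–Mallick: each indicator w_m is drawn by exact Gibbs from its full
conditional (Bernoulli(1/2) prior times the likelihood ratio at the current
coefficient); when excluded, the coefficient regenerates from its prior so
the pair (w_m, b_m) keeps its joint support. Spike-and-slab (SSVS): the
coefficient always enters the likelihood, its prior is the 50/50 mixture of
Normal(0, 0.1²) (spike) and the slab (the coefficient prior above), and
slab membership — whose posterior frequency plays the indicator role — is
Gibbs-sampled from the prior-density ratio at the current value. The spike
sd of 0.1 was fixed a priori: small enough that a practically relevant
effect (|b| ≳ 0.5 on the log scale) essentially never sits in the spike,
large enough that a null coefficient's posterior mass actually visits it.
Posterior model weights are the visit frequencies of the 2^m indicator
combinations, labelled M(tt, Lb, t)-style.

## Sampler

Metropolis-within-Gibbs, written directly (no PPL) so the z and ψ steps are
exact conjugate draws and runs are bit-for-bit reproducible from one seed.
Per sweep: random-walk updates of each activity centre (proposals outside S
rejected, implementing the uniform prior); exact Gibbs for unlinked
telemetry centres; random-walk updates of α0, active coefficients and
log σ (with Jacobian); indicator/membership Gibbs; exact Gibbs for z and ψ.
The compiled kernel keeps incremental caches — per-device kernel sums
G_j = Σ_i z_i exp(−d_ij²/2σ²) of the unmarked pool make a centre or z
update O(J) — and at the end of every chain recomputes the likelihood from
scratch and refuses to return if the running cache has drifted.

Initialisation: identified centres at their detection centroid, augmented
centres uniform on S, σ at the design σ̂ (or the informative-prior
location), α0 at log(total events / total effort-days), z ~ Bernoulli(0.5)
with observed individuals pinned at 1. Proposal scales are tuned during
burn-in toward 20–50% acceptance in multiplicative steps every 50
iterations and frozen afterwards, preserving detailed balance for the
retained draws. Augmentation defaults to M = max(100, 5 × identified); a
warning fires if P(N > 0.9 M) > 0.05 and analyses here use M = 300 for
SMR/SC, where the identified count is a poor anchor for the pool size.

Defaults are test-scale (3 chains × 5,000 iterations, burn-in 1,000);
production-scale runs (3 × 50,000+) are a `SamplerConfig` away. Convergence
is judged by the classic Gelman–Rubin factor (no chain splitting, no df
correction), threshold 1.1.

## State space and design tools

S is the axis-aligned device bounding box buffered on all sides, by default
by 3σ from a preliminary fit or the design σ̂ — at 3σ the half-normal
kernel is ~1% of its peak, so excluded animals are effectively unexposed; a
rectangle matches the uniform activity-centre prior. Device spacing bounds
(σ̂, 2σ̂) come from the bivariate-normal home-range inversion; the
chi-square quantile at 2 df has the closed form −2 ln α, used as an exact
oracle in the tests.

## Synthetic surveys

The generator reproduces the survey design the model targets: 66 cameras on
a regular 500-m grid, 69 live traps interleaved at cell centres, 98 days in
14 weekly occasions. Operation logs mimic field reality — cameras run all
survey except an optional 20–46-day outage (~83% uptime), traps operate one
14–28-day burst (~21% uptime, live-trapping being short campaigns).
Encounters are drawn occasion by occasion so the behavioural covariate and
removals feed forward; removals are triggered by live-trap captures with a
per-capture probability. Degradation to SMR keeps a uniform random marked
subset (individuals with removal records stay marked, since an extraction
implies physical capture) and collapses everyone else into the unmarked
totals, conserving events; fraction 0 yields spatial counts. Event
timestamps are scheduled ≥31 minutes apart within each detection stream so
the 30-minute independence filter is exercised but lossless, making CSV
round trips exact. Default truths sit in the study-like regime (σ = 400 m,
λ0 = 0.05/device-day, densities of order 0.1–1/km²).

What the generator does *not* emulate: movement within the survey (centres
are static points, no correlated walks), habitat-driven density variation,
misidentification, or attractant decay. Passing tests therefore demonstrate
that the estimator recovers the model's own data-generating process at
realistic survey geometry and sparsity — not robustness to the behavioural
and observational pathologies of real camera-trap data.

## Numerical choices and edge cases

* The 30-min independence filter anchors on the last *retained* event
  (strict > 30 min), which makes it idempotent; a multi-animal picture is
  one retained row carrying `n_animals` events, so simultaneous animals are
  never collapsed.
* A final short occasion is allowed; its reduced length is absorbed by the
  effort matrix. Counts at zero-effort cells are validation errors, and
  impossible data (y > 0 where μ = 0) return −∞ rather than raising inside
  the likelihood.
* Occasion covariate t is the centred/scaled occasion index (a linear
  trend); a categorical-occasion variant was considered and left out to
  keep the selection space comparable across species.
* Kernel likelihood identities are protected by tests: the compiled path
  must match the numpy/scipy reference to ~1e-10, the unmarked likelihood
  must match brute-force convolution of per-individual Poisson counts on
  tiny instances, and on all-zero data the posterior of N must match a
  closed-form Gauss–Hermite quadrature oracle.

## Problem sizes used by the test and acceptance runs

Design-formula checks are instantaneous. The convergence run is the full
study geometry (135 devices, 14 occasions, N = 40, 20% marked) with
3 × 5,000 iterations; parameter recovery uses 20 SCR replicates at N = 50
with single chains of 3,000 iterations; the precision-ordering and
selection-agreement experiments use single chains of 4,000–5,000
iterations. These sizes give Monte-Carlo errors comfortably inside the
asserted tolerances while keeping the whole suite at a few minutes on one
core.

## Known limitations

* SC (and SMR with few marked animals) rides the well-known λ0–σ–N ridge:
  the posterior is proper but right-skewed, so posterior means of N can sit
  well above the truth in any single realisation even when the sampler is
  exact; informative σ priors or telemetry are the practical remedy, and
  precision (CV) — not point recovery — is the meaningful SC diagnostic.
* The rectangle state space slightly overstates area for very irregular
  grids; no polygon/raster support.
* Marked individuals must be identifiable with certainty; a
  marked-but-unidentified class (poor-quality pictures) is not modelled.
* Open-population dynamics beyond known removals (births, immigration) are
  out of scope.
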