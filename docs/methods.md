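# Methods

This package estimates three per-unit statistics of temporal processing
from single-unit spike trains — the correlation timescale τ_C, the total
predictability R_tot and the information timescale τ_R — simulates a
branching network as synthetic ground truth, and compares the statistics
across brain areas with hierarchical Bayesian regression.  This note
documents the models, the defaults and the numerical choices, and what the
synthetic benchmarks do and do not establish about real recordings.

## Correlation timescale

Spiking is binarized in bins of Δt = 5 ms (a_t = 1 iff at least one spike
falls in [t, t+Δt)).  The autocorrelation at lag T is

    C(T) = ( ⟨a_t a_{t−T}⟩_t − ⟨a_t⟩_t² ) / ( ⟨a_t²⟩_t − ⟨a_t⟩_t² ),

with all three averages over the common index set t = T, …, T_rec − Δt.
Using lag-dependent window means (rather than one global mean) guards
against slow drift; lags whose window has zero variance are reported
undefined.  A brute-force double-loop evaluation of the same formula
serves as the unit-test oracle (agreement to 1e−12).

τ_C is extracted by bounded nonlinear least squares on lags within
[T_min, T_max]:

* **two-timescale fit** (default, T_min = 30 ms, T_max = 10 s):
  f(T) = A₁e^(−T/τ₁) + A₂e^(−T/τ₂).  τ_C is the τ with the larger
  coefficient; the other becomes the secondary timescale τ_sec, which
  absorbs slow (possibly stimulus- or state-driven) decay.  Ties in A break
  toward the smaller τ (the dominant *fast* decay; in cortical data the
  rejected timescale is usually the slow one).
* **single exponential with offset**, f(T) = Ae^(−T/τ) + O, used for
  branching-network data where no separate slow component exists.  Its τ is
  known to grow with T_max on data with a slow component — the reason the
  two-timescale form is the default for recordings.

Excluding lags below T_min suppresses refractoriness and burst effects.
Optimizer: `scipy.optimize.least_squares`, bounds τ ∈ [Δt, 100 s],
A ∈ [0, 2], O ∈ [−0.1, 1], 10 multi-starts from log-spaced τ values (sums
of exponentials have rugged least-squares surfaces); the best residual
wins.  Lags are unweighted; fits that end on a parameter bound are flagged
`at_bound`, failed fits return `converged=False` and are excluded from
medians downstream.

A fit is additionally flagged `low_signal` when its dominant amplitude is
indistinguishable from a flat autocorrelation: the least-squares noise
floor of the amplitude of an exponential regressor sampled every Δt is
σ_C·√(2Δt/τ) with σ_C ≈ 1/√n_bins, and fits below 3 floors are flagged.
Downstream, such units are reported at the resolution bound Δt — a
memoryless unit has no measurable timescale, and fitting pure correlation
noise otherwise yields arbitrary mid-range τ values (the dominant failure
mode for weakly recurrent network units).

## Predictability and information timescale

R(T) is the fraction of the current-bin spiking entropy explained by
mutual information with past spiking in a past range T:

    R(T) = I(A_t ; past state over [t−T, t)) / H(A_t).

The past range is partitioned into d = 5 contiguous binary bins whose
widths grow geometrically by 10^κ per bin (equal widths at κ = 0); each
past bin is 1 iff it contains a spike, giving 2^d past states.  I is the
plug-in estimate over the 2·2^d contingency table minus a surrogate bias:
the mean plug-in MI over n_sh = 25 random pairings of past states with
current bins.  Because the plug-in MI depends on the data only through the
table, a uniformly random pairing induces a multivariate-hypergeometric
table over the fixed marginals; surrogates are drawn directly from that
distribution (exactly the permutation null at O(2^d) per surrogate rather
than O(n)).  R is clipped below at zero, and κ is chosen per T to maximize
the corrected R over κ ∈ {0, 0.1, …, 0.8}.  With ~2.4 × 10^5 samples and
64 table cells the plug-in-plus-surrogate estimator is adequate and fully
self-contained; a regularized Bayesian embedding estimator is deliberately
out of scope.

R(T) is evaluated on a log-spaced grid of past ranges (default 25 points,
30 ms – 5 s; T_min = 30 ms excludes short-term effects exactly as the
correlation analysis does).  From the curve:

* **R_tot** — mean of R over the plateau, the longest suffix of the grid
  whose values stay within 5% of the curve maximum.
* **τ_R** — gain-weighted mean rise point.  With cumulative-max gains
  ΔR_i = max(R_i − max_{j<i} R_j, 0),
  τ_R = Σ_i (T_i − T_0)·ΔR_i / Σ_i ΔR_i, and τ_R = 0 on a flat curve.
  Cumulative-max gains keep estimator jitter from producing negative
  weights; on dense samples of R(T) = R_∞(1 − e^(−(T−T_0)/τ)) the measure
  converges to τ.  Gains only count where R(T) clears three times its own
  surrogate noise floor (the sd of the n_sh shuffle surrogates, which the
  estimator computes anyway; the per-T maximization over κ lifts the null
  by about two floors), and τ_R is set to 0 outright when R_tot itself
  sits below that floor: a unit without measurable predictability has no
  rise time, and isolated noise exceedances would otherwise place τ_R at
  an arbitrary grid point.  For past ranges shorter than d bins the
  embedding dimension is capped at T/Δt, so grids may start at a single
  time step (the simulation analysis convention).

An analytic oracle backs the tests: for a two-state Markov chain with
P(1→1) = 0.8, P(0→1) = 0.2, R at one step equals 1 − H_b(0.8) ≈ 0.278.

## Branching network

N = 1000 binary units on a sparse random directed graph; every unit draws
k = 10 out-targets uniformly (no self-edges) with raw weights uniform on
[0, 1), rescaled per sender so that Σ_i w_ij = m, the neural efficacy.
Per 5-ms step, unit i is activated recurrently with probability
min(Σ_j w_ij s_j(t−1), 1) and externally with probability
sigmoid(x_i/σ + γ); the two routes combine as independent union,
1 − (1 − p_rec)(1 − p_ext) — the standard branching-with-immigration
convention, additive at small probabilities.  Recurrence is summarized by
the amplification a/h = 1/(1 − m).

The external drive x_i is either 0 (uncorrelated input) or a per-unit
Ornstein–Uhlenbeck process with timescale τ_ext = 30 ms, advanced by the
exact discretization x(t+Δt) = x·e^(−Δt/τ_ext) + √(1−e^(−2Δt/τ_ext))·ξ
with stationary unit variance.  A slow homeostat keeps the mean unit rate
at ν* = 3.5 Hz: γ ← γ + Δt·(A* − A(t))/(N·τ_γ) with A* = N ν* Δt and
τ_γ = 60 s, applied every step using the activity just computed.

γ is initialized at the rate-matched mean-field fixed point.  With x = 0
this is γ = logit(p*) with p* = (1−m) ν* Δt.  Under OU input the sigmoid
is averaged over the stationary drive, solving
E_{x∼N(0,1)}[sigmoid(x/σ + γ)] = p* by Gauss–Hermite quadrature and
`brentq`: at small p* the Jensen gap between the two solutions is large,
and with τ_γ = 60 s the homeostat would need tens of minutes to absorb a
mis-initialized offset.

**Sensitivity σ.**  The OU variance is fixed at 1 and σ sets how strongly
the drive modulates the external rate.  The default is σ = 0.25, placing
the model in the regime the network study describes: with correlated
input, single-unit predictability at low amplification is roughly an order
of magnitude above the uncorrelated-input case (R_tot ≈ 0.15 at a/h = 1),
decreases with amplification to a minimum near a/h ≈ 20, and rises again
as recurrence-generated predictability takes over.  At σ ≈ 1 the
input-induced predictability is barely above the recurrence branch and the
regime collapses.

Simulations equilibrate before recording; recordings emit SpikeTrains in
the standard format so the full measurement pipeline runs on them
unchanged.  Simulation analysis conventions differ from recordings in two
respects, following the model's simplicity: the single-exponential-with-
offset fit is used for C(T), and the lower fitting bound is removed
(T_min = one time step).  Sweeps over a/h at full scale use 20 networks of
20 recorded units with 20-min equilibration and recording; the test-scale
default is 3 networks with 5-min equilibration and 5–10-min recordings.

**Decay-rate validation.**  For uncorrelated input the single-unit
autocorrelation decays at the population branching rate, τ = −Δt/ln m.
Two properties of the validation setup matter and are properties of the
model, not tuning: (i) it runs at N = 100 because the single-unit
correlation amplitude scales as 1/N while the decay rate is N-independent
— at N = 1000 and m = 0.8 the amplitude (~10⁻³) sits below estimator
noise for 20-min recordings; (ii) the fit starts at the second lag,
because a graph without self-edges has no one-step return path: C(Δt)
carries only the shared population mode and systematically undershoots
the exponential through all later lags (which include return-path mass),
biasing m = 0.8 fits by ~+30% when included.  With both choices the
median fitted τ_C lands within a few percent of −Δt/ln m for
m ∈ {0.8, 0.9, 0.95}.  The uncorrelated-input phenomenology sweep (all
three measures rising with a/h) runs at N = 100 for the same
amplitude-vs-noise reason, with past-range grids starting at one time
step; at N = 1000 the low-amplification units fall below the estimator
floor and their medians reflect noise handling rather than the model.

## Synthetic cohorts with known area effects

For parameter-recovery studies a generator draws multi-mouse cohorts from
exactly the structure the hierarchical model assumes: per-mouse intercept
θ_0,j and slope θ_hs,j (or offset θ_hc,j) from normal parent
distributions, and per-unit log measures from Normal(μ_ij, ε) or
SkewNormal(μ_ij, ε, α) with

    μ_ij = θ_logν·logν_norm,i + θ_rf·T_rf,i + log(θ_0,j + θ_slope,j·x_i).

Defaults: 8 mice, 5 cortical areas (V1, LM, AL, PM, AM with hierarchy
scores 0, 0.264, 0.509, 0.684, 0.798, shifted so V1 = 0), 200 units per
area, μ_θ0 = 0.5, σ_θ = 0.05, slope ±0.3 or 0, ε = 0.5, θ_logν = θ_rf =
0.1, firing rates log-normal with median 3.5 Hz and log-sd 1, receptive
fields in 70% of units.  The intercept 0.5 keeps every mouse's area
argument positive for slopes of either sign up to |0.5|; the generator
raises if a draw violates positivity.  These cohorts share the model's
own likelihood — passing recovery therefore validates inference, not the
model's adequacy for real spike statistics.

## Hierarchical Bayesian area models

The measure y (τ_C, τ_R in ms, or R_tot) of unit i in mouse j is modelled
through its logarithm: Normal(μ_ij, ε) for R_tot, SkewNormal(μ_ij, ε, α)
for the timescales (their log distribution is negatively skewed; the
scale and shape only shift the mean by a constant, so area differences
remain governed by μ_ij).  The area term is mouse-specific:
f_j = log(θ_0,j + θ_hc,j·1_hc) (*cortical groups*) or
f_j = log(θ_0,j + θ_hs,j·HS) (*cortical hierarchy*, HS shifted so V1 = 0,
making θ_0,j the V1 median e^f).  Log firing rate is centered and divided
by two standard deviations so its coefficient is comparable to the binary
receptive-field predictor.  Priors: N(0,1) on hyper-means, θ_logν, θ_rf
and α; HalfCauchy(0, 1) on the parent-distribution sds; HalfCauchy(0, 10)
on ε.  Positivity of θ_0,j + θ_slope,j·x is enforced by a log-barrier
(zero posterior density outside) rather than reparameterization, keeping
the normal parent distributions intact.

Sampling uses an ensemble sampler (emcee) with differential-evolution
moves (80% DEMove, 20% DESnookerMove), 50 walkers (at least 2·dim+2),
6000 warmup and 3000 retained steps by default.  Scale parameters are
sampled on the log scale with the Jacobian included.  The per-mouse
slopes are weakly informed (five area medians per mouse) and are sampled
non-centered (θ_slope,j = μ + σ·z_j, z_j ∼ N(0,1)) to avoid the funnel in
their hyper-sd, which otherwise traps walker subsets; the intercepts are
data-dominated and stay centered.  Walkers start from a moment-based
guess (per-mouse OLS of exponentiated area-mean log measures on the area
predictor); a run whose R-hat exceeds 1.2 is retried once from a
re-seeded start and the better-mixing run kept.  For the log-normal
likelihood the total log-likelihood is evaluated from per-(mouse, area)
sufficient statistics — algebraically identical to the unit-level sum but
independent of cohort size — while the skew-normal model uses the
unit-level path.  Walkers are treated as chains for rank-normalized R-hat
and ESS; fits with max R-hat > 1.01 are flagged invalid.  Ensemble
walkers are not independent chains and typical converged runs sit at
R-hat ≈ 1.03–1.08 under this conservative diagnostic — recovery tests
against known ground truth back up the inference.

Model comparison uses PSIS-LOO ELPD (arviz) on pointwise log-likelihoods
of ~1000 thinned draws; the ELPD difference carries a standard error over
LOO samples, and comparisons with > 5% of Pareto-k above 0.7 are flagged
unreliable.  Calibration uses LOO-PIT: the observed Kolmogorov–Smirnov
distance of the PIT values to uniformity is compared against the envelope
of 100 simulated uniform samples of the same size.

## Descriptive statistics

Medians carry percentile-bootstrap 95% confidence intervals (10,000
resamples, seeded).  Group comparisons use two-sided Mann–Whitney U
(exact p for groups ≤ 20 without ties, normal approximation with tie
correction otherwise) or Wilcoxon signed-rank for paired data, with
Bonferroni correction over the family of simultaneous tests and a
relative median difference as the effect summary.  Area medians are
related to the anatomical hierarchy score by Pearson and Spearman
correlation with an OLS line.

## Problem sizes and limitations

The simulation benchmarks run at reduced scale chosen for the accuracy
each quantity needs: the homeostatic-rate check uses one network with
5-min equilibration and 20-min recording; the amplification sweeps use 3
networks per grid point with 5–10-min recordings; Bayesian recovery uses
10 cohorts per scenario at the default cohort size.  The branching
network is a deliberately minimal model: binary units, no refractoriness,
no spatial correlation in the input, log-normal rather than heavy-tailed
rate distributions.  Passing its benchmarks validates the estimators and
the inference machinery under known ground truth; it does not establish
estimator accuracy for cortical data, where autocorrelations mix multiple
timescales and spike statistics are burstier.  Real-data analyses also
depend on inputs this package treats as given: spike sorting, unit
quality filtering, receptive-field flags and anatomical hierarchy scores.
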