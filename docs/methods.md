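# Methods

## The model

A synapse is described by `M` identical, independent docking sites in the
active zone. Each site is empty or holds one release-ready synaptic vesicle
(SV). Action potentials (APs) arrive at stimulus indices i = 1, 2, …
(deterministically at interval 1/f, or at random i.i.d. intervals in the
random-train regime). Three per-stimulus probabilities govern each site:

- `p_r,i` — a docked SV fuses upon the i-th AP (release probability);
- `p_d,i` — an empty site is refilled between APs i and i+1 (refilling
  probability);
- `p_u,i` — a docked SV undocks between APs (undocking / transient-docking
  probability).

All three may vary arbitrarily with i, so depression, facilitation and
transient replenishment regimes are all expressible. Within one cycle the
order of events is: fusion at the AP, then undocking of surviving docked
SVs, then refilling of the sites that were empty *after* fusion; each site
makes at most one transition per interval. That ordering is what makes the
occupancy probability p_i (site occupied just before AP i) obey

    p_{i+1} = p_i (1 − p_r,i)(1 − p_u,i) + (1 − p_i (1 − p_r,i)) p_d,i,
    p_1 given,

and it is enforced identically in the simulator and the analytic layer —
a site emptied by fusion may refill in the same interval; a site that
undocks may not.

Because sites are exchangeable and independent, the number of docked SVs
before AP i is Binomial(M, p_i) and the quantal content (QC, number of
fusions) is Binomial(M, p_i·p_r,i). Hence the mean QC is ⟨b_i⟩ = M p_i
p_r,i and the per-stimulus Fano factor is FF_i = 1 − p_i p_r,i = 1 −
⟨b_i⟩/M: depression and dispersion are rigidly coupled, and the QC Fano
factor never exceeds one on a deterministic train.

For constant parameters the recursion solves in closed form with geometric
relaxation factor λ = (1 − p_r)(1 − p_d − p_u), fixed point
p̄ = p_d / (p_d + p_u + p_r(1 − p_d − p_u)), steady-state Fano factor
FF = 1 − p̄ p_r, and lag-1 QC correlation

    ρ = −p_d (1 − p_r) p_r (1 − p_d − p_u) / (p_r + p_d + p_u(1 − p_r) − 2 p_d p_r) ≤ 0.

With p_u = 0, FF and ρ are symmetric under p_r ↔ p_d, ρ attains its global
minimum −0.125 at p_r = p_d = 0.5, and 1 − FF lower-bounds both
probabilities.

### Derived (not closed-book) expressions

Two expressions are this package's own derivations, stated as such and
verified against Monte-Carlo simulation in the test suite rather than
asserted:

- **Lag-ℓ correlation.** The per-site occupancy chain relaxes geometrically
  with factor λ, so ρ_ℓ = ρ_1 · λ^(ℓ−1). Verified within 3 SE of empirical
  lag-ℓ correlations on 10⁵-stimulus simulations.
- **Evoked-amplitude statistics.** With quantal sizes i.i.d. (mean ⟨c⟩,
  coefficient of variation CV_q) the amplitude is a compound sum over the
  QC; the law of total variance/covariance gives FF^e = ⟨c⟩(FF + CV_q²) and
  ρ^e = ρ·FF/(FF + CV_q²). These reduce to (FF, ρ) at ⟨c⟩ = 1, CV_q = 0 and
  are verified within 3 SE of simulated amplitude traces.
- **ρ-minimizing release probability.** Setting dρ/dp_r = 0 (p_u = 0) gives
  (2p_d − 1)p_r² − 2p_d p_r + p_d = 0, i.e. p_r* = √p_d/(√p_d + √(1 − p_d)).
  This closed form matches a 0.0005-resolution grid minimizer at every p_d
  tested and passes through (0.5, 0.5).

## Kinetics

Between APs a site is a two-state continuous-time Markov chain with docking
rate k_d and undocking rate k_u (per second). Over an interval dt,

    p_d = k_d/(k_d+k_u) · (1 − e^{−(k_d+k_u)dt}),
    p_u = k_u/(k_d+k_u) · (1 − e^{−(k_d+k_u)dt}),

so the probabilities shrink as stimulation frequency rises. The inverse map
(k_d + k_u = −ln(1 − p_d − p_u)/dt, split in proportion p_d : p_u) requires
p_d + p_u < 1 and round-trips to 1e−10. At the 50-Hz interval (dt = 20 ms),
p_d ≈ 0.57 with p_u = 0.2 maps to k_d ≈ 54 SVs per empty site per second,
and p_d ≈ 0.53 with p_u = 0 to k_d ≈ 38.

## Simulator

The reference implementation flips one Bernoulli coin per site per event
(`method="site"`); because sites are identical and independent, an
aggregated path drawing binomial counts on the occupied/empty sub-pools is
distributionally equivalent and is used for long traces and large ensembles
(`method="aggregate"`). Equivalence is proven by chi-square tests of both
paths against the exact pmf. RNG contract: `numpy.random.default_rng(seed)`
per trial, with ensemble runs deriving one stream; identical seeds give
bit-identical traces.

In the random-train regime the kinetic rates are the primitives: each
sampled i.i.d. interval is converted to (p_d, p_u) before the occupancy
update, which is the only convention under which interval length matters.
Interval variability then feeds occupancy variability and the QC Fano
factor can exceed one (it reaches ≈7 in the designated test regime:
exponential intervals with mean 20 ms, k_d = 100 s⁻¹, p_r = 1).

Quantal-size noise draws one Gaussian (mean ⟨c⟩, SD CV_q·⟨c⟩) per released
quantum and sums them per stimulus. Negative draws are clipped to zero
without renormalization; at the study regime (CV_q ≤ 0.3) the clipped mass
is below 5·10⁻⁴ and the induced bias is negligible.

## Inference

- **Empirical statistics.** FF = sample variance/mean and ρ = lag-1 Pearson
  correlation over stimuli `burn_in..end` (default burn-in 10 — the
  occupancy transient dies within ~6 stimuli at the case-study parameters).
  95% CIs by percentile bootstrap (default 1000 replicates); ρ resamples
  consecutive pairs so the quantity being estimated survives resampling,
  FF resamples single values. ρ uses raw (not detrended) QCs over the
  window.
- **Moment inversion.** For p_u = 0 the system {FF, ρ} reduces exactly to a
  quadratic: q = p_r p_d = 1 − FF + ρ·FF and s = p_r + p_d = q(2 − FF)/(1 − FF),
  so both swap-symmetric roots come from one square root — no iteration, no
  convergence concerns. For p_u > 0 a deterministic 10×10 multi-start
  bounded least-squares search finds all roots (residual < 1e−10, duplicates
  merged at 1e−6). Root disambiguation follows the normalized depression:
  the selected root is the one whose predicted p̄ is closest to the observed
  steady-state mean QC over the first-stimulus QC. Statistics outside the
  attainable set (FF ∉ (0,1), ρ < −0.125 at p_u = 0, or a complex quadratic
  root) raise rather than clip.
- **Transient least-squares fits.** Both the constant-(p_r, p_d) fit of the
  normalized depression curve and the time-varying refilling schedule
  (n free transient values + constant tail, default n = 5) use bounded
  least squares from a fixed grid of starts — fully deterministic. Stimuli
  are weighted equally.
- **Elmqvist–Quastel.** OLS line through (cumulative QC before stimulus i,
  QC_i) for i ≤ k (default 3); pool = x-intercept, p_r = QC_1/pool. A
  non-negative slope raises (no depression → inapplicable). When refilling
  is present the line is flattened by replenishment, so the pool is
  overestimated and p_r biased low — a property the tests assert on exact
  mean sequences.
- **Maximum likelihood with quantal noise.** The amplitude marginal is the
  compound binomial–Gaussian mixture Σ_b Binom(b; M, p_i p_r)·N(amp; b⟨c⟩,
  b(CV_q⟨c⟩)²), with b = 0 a point mass at zero amplitude; per-quantum
  variances add, there is no separate constant measurement-noise term. The
  Gaussian density matrix is parameter-independent and computed once; the
  occupancy sequence converges geometrically so the binomial pmf is
  evaluated only at the few distinct success probabilities. M, if not
  supplied, is scaled from the steady-state mean QC via a preliminary
  moment inversion, M ≈ mean QC/(p̄·p_r). Optimized with L-BFGS-B on
  [1e−4, 1 − 1e−4]^(n+1).
- **Feasible region.** Vectorized evaluation of FF, ρ and p̄ (p_u = 0) on a
  regular grid (default resolution 0.005), intersecting the constraints
  FF ≤ ff_max, ρ ≥ rho_min, p̄ ∈ depression range. With the case-study
  bounds (0.55, −0.06, [0.45, 0.65]) the intersection is nonempty and
  confined to p_r ≥ 0.86, p_d ∈ [0.455, 0.645].

## Synthetic data

The `mntb_lso` preset emulates the recordings the inference chain targets:
3000 stimuli at 50 Hz, M = 100 docking sites (the statistics of interest
are M-free; M only sets the amplitude scale), full initial occupancy,
p_r = 0.93, refilling schedule (0.92, 0.73, 0.66, 0.53, 0.12) then 0.51,
no undocking, quantal sizes Gaussian with mean 22 pA and CV_q = 0.3. Its
steady-state theory gives FF ≈ 0.509 and ρ ≈ −0.033. The `fig2_*` and
`fig3_*` presets cover the depression/facilitation regimes at constant low
probabilities, the matched-mean high-p_r regime (whose refilling schedule
is obtained by inverting the recursion against the low-probability mean
trajectory), and the low-noise saturated regime. `fig3_sites` stands for a
scenario in which depression arises from a shrinking number of docking
sites; a fixed-M model reproduces only its fluctuation profile (low Fano
factor throughout), not the mean depression, and the fixture is documented
accordingly.

What the fixtures deliberately do not emulate: slow drift in recording
quality, measurement noise beyond quantal-size variability, stimulation
artifacts, and heterogeneous site populations. Passing recovery tests on
these fixtures therefore demonstrates correctness of the estimators under
the model's own assumptions, not robustness to violations of them.

## Problem sizes and numerical choices

Monte-Carlo cross-checks use 10⁵ trials (ensembles) or 10⁵ stimuli (long
traces), with standard errors estimated from 20 non-overlapping chunks and
agreement asserted within 3 SE. Bootstrap coverage is checked over 40
seeded replicate recordings with 400 bootstrap replicates each. Binomial
pmfs go through scipy's log-space implementation (stable to M ~ 1e4; the
regimes here use M ≤ 200). Degenerate parameter sets (zero steady-state
denominator, fully-mixing interval probabilities, zero first-stimulus QC)
raise informative errors rather than returning limits, so configuration
bugs surface instead of propagating.

## Known limitations

- Heterogeneous or interacting docking sites (sum-of-binomials extensions)
  are out of scope; all sites share one parameter set.
- Time variation within an inter-stimulus interval is supported only as
  piecewise-constant rates per interval.
- The MLE assumes per-quantum variance additivity; a constant
  amplitude-measurement noise floor is not modelled.
- The EQ estimator is included for comparison; its no-replenishment
  assumption is violated at high-refilling synapses by construction, which
  is precisely the bias the package quantifies.
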