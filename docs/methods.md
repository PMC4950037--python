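# Methods

## Model and assumptions

Patients on arms k = 0 (control), 1, …, K contribute independent bivariate
normal (efficacy, safety) responses with arm-specific means, known standard
deviations σ_E, σ_S and known within-subject correlation ρ; allocation is
1:1 across all arms, so after n responses per arm the Fisher information per
pairwise comparison is I_T = n/(2σ_T²) for each endpoint T.  Accumulated
data enter only through the score statistics Z_Tk = I_T(μ̂_Tk − μ̂_T0),
which are jointly normal with Var(Z_Tk) = I_T, within-arm cross-endpoint
covariance ρ√(I_E I_S), and covariance I_T/2 (endpoint-wise) between arms
because the control data are shared.  Variances and ρ are treated as known
throughout — no plug-in estimation is performed — and both endpoints are
oriented so that larger responses are better.

The testing problem is co-primary per arm: H0k: {θ_Ek ≤ 0} ∪ {θ_Sk ≤ 0},
rejected only if the selected arm is shown effective *and* safe.  The
familywise error rate (FWER) is the probability of rejecting for a selected
arm whose H0 is true, and it must be bounded by α for *every* null
configuration (strong control).

## Selection geometry

The gate keeps arms with Z_Sk > c; among eligible arms the maximizer of
O_k = w_E Z_Ek/√I_E + w_S Z_Sk/√I_S is selected, ties (probability zero)
going to the lowest index.  Writing Z_Tk = I_T θ_Tk + W_Tk − W_T0 with
independent per-arm noise W_Tk ~ N(0, I_T/2), the control terms are common
to every arm, so the argmax of O equals the argmax of the iid latent scores

    V_k = w_E W_Ek/√I_E + w_S W_Sk/√I_S ~ N(0, s²),  s² = ½ + w_E w_S ρ,

shifted by w_E √I_E θ_Ek when efficacy means differ (equal safety means
always cancel).  All calibration quantities then reduce to low-dimensional
Gaussian integrals by conditioning on V_k — and, where the gate is active,
on the control safety noise W_S0, given which the arms are independent:

* **Efficacy criterion** (safety effects → ∞, θ_E = 0): every arm is
  eligible, the safety margin is vacuous, and
  P(Z_E,i* ≥ u) = K ∫ φ_s(v) Φ(v/s)^{K−1} Φ((b_E v − u)/τ_E) dv with
  b_E = Cov(W_E, V)/s² and τ_E² = I_E − Cov²/s² (control noise folded in).
  Solving for u_E at level α is a bracketed scalar root search.
* **Safety criterion** (efficacy effects → ∞, θ_S = 0): the gate binds and
  the target is conditional on at least one eligible arm,
  P(Z_S,i* ≥ u_S | N_S ≥ 1) = α / P(N_S ≥ 1).  We solve the equivalent
  joint equation P(N_S ≥ 1, Z_S,i* ≥ u_S) = α via a two-dimensional
  quadrature over (W_S0, V_1), with the rival "eligible-and-ranked-higher"
  probability q(v, z) accumulated along the V grid.
* **P(N_S ≥ 1; θ_S = 0)** integrates out the shared control, under which the
  safety statistics are equicorrelated at ½; at c = 0 it equals K/(K+1) by
  exchangeability (the control is the maximum with probability 1/(K+1)).
* **Limiting power** (all arms safe, θ_E = (δ₀,…,δ₀,δ)) is the same
  one-dimensional efficacy integral summed over which arm wins, each arm
  weighted by its mean shift on the V scale.

The two boundary searches are uncoupled.  Every quantity above has a
Monte-Carlo twin that simulates the score statistics directly at the
surrogate-infinity effects and applies the literal selection rule; the
simulator is the independent oracle for the quadrature (the test suite
enforces 3-standard-error agreement on randomized parameter sets).

## Sample size

The information search assumes a common level I_E = I_S = I₁ for
computational convenience, re-solves u_E at every candidate and brackets
the root of power(I₁) = 1 − β starting from the classical one-comparison
value (z_{1−α} + z_{1−β})²/δ².  The fractional per-arm size
n = 2·max(σ_E², σ_S²)·I₁* is rounded *up* to a whole patient and the
boundaries recomputed at the information levels n* implies
(I_E = n*/2σ_E², I_S = n*/2σ_S²); because power is increasing in
information, the attained power slightly exceeds the target.

## Multiple stages

With J analyses the selected arm (chosen at the first look only) is
monitored against control.  Post-selection, each endpoint's score sequence
has independent Gaussian increments with variance equal to the information
increment, exactly as in a univariate group-sequential test, so boundaries
come from an error-spending recursion:

* stage-1 exit probabilities use the post-selection marginal density — the
  mixture over selected arms of the conditional-normal kernels above (for
  the safety schedule, the gated, conditional-on-N_S ≥ 1 density, which is
  supported on (c, ∞));
* later stages use a Gauss–Legendre grid (221 nodes) on each continuation
  region and a convolution recursion, solving each stage's upper and lower
  boundary to match the spending increments.

Both endpoints spend against the *efficacy* information fraction
t_j = I_Ej/I_EJ, with I_Sj = σ_E² I_Ej/σ_S² because the same patients
inform both endpoints.  The efficacy schedule spends a total of α (its
futility spend 1 − α); the safety schedule spends α/P(N_S ≥ 1) under the
same conditioning as the single-stage criterion.  Cumulative spends reach
their totals at t = 1, which forces u_J = l_J on both endpoints: the trial
cannot leave analysis J undecided.  Futility is binding — crossing a lower
boundary stops the trial — and the type-I calculation relies on it.

Shipped spending families: the power family `pow:κ` (level·t^κ, κ > 0) and
an O'Brien–Fleming-type spend `obf`; anticipated information fractions
default to equal spacing.  The maximum-information search finds I_EJ such
that the multi-stage disjunctive power (each mixture component propagated
with its own drift) reaches 1 − β, with recruitment ceiling
n* = ⌈2σ_E² I_EJ⌉ per arm.  With J = 1 the machinery reproduces the
single-stage design exactly.

## Tunable parameters

| parameter | meaning | default |
|---|---|---|
| `alpha` | FWER level (strong control) | 0.05 |
| `beta` | one minus target disjunctive power | 0.1 |
| `delta`, `delta0` | desirable / minimum clinically important standardized efficacy effects | required |
| `w_E`, `w_S` | selection weights, w_E² + w_S² = 1 | √½, √½ |
| `rho` | within-subject endpoint correlation | 0.0 |
| `sigma_E`, `sigma_S` | known response SDs | 1.0 |
| `c` | minimum-safety threshold on the safety score scale (−∞ disables the gate for co-primary-efficacy use) | 0.0 |
| `n_stages`, `spending_upper`, `spending_lower` | analyses and spending families | 1, `pow:2` |
| `gamma_surrogate` | finite stand-in for infinite effects in limiting configurations | 10⁶ |

Equal weights make selection consistent with the final co-primary test and
(with equal variances) make the two boundaries coincide.

## Numerical choices

Gaussian expectations use Gauss–Legendre rules truncated at ±8.5 standard
deviations (600 nodes on the selection score, 160 on the control safety
noise); the tail integral q(v, z) inside the gated-selection formula is
accumulated with a half-node midpoint correction, which a 2×10⁷-replicate
simulation confirms to ~10⁻⁴ absolute accuracy.  Boundary roots use Brent's
method with tolerance 10⁻⁴ on the score scale; the information searches use
tolerance 2×10⁻³ on I (the power gradient is ~5×10⁻³ per information unit,
so this matches a 10⁻⁴ power tolerance).  When u_S ≤ c the safety margin is
subsumed by the gate and the crossing probability is returned exactly as
P(N_S ≥ 1); designs in that regime are outside the validated range.  At the
degenerate corners (|ρ| = 1, or a zero weight, where a conditional variance
vanishes) tail probabilities fall back to indicators; the multi-stage
safety *density* additionally requires a non-degenerate conditional and
raises otherwise.  Monte-Carlo routes draw replicates in fixed 200 000-row
chunks from independent child streams of the master seed, so every result
is bit-for-bit reproducible and independent of execution order; the
Monte-Carlo boundary solver uses common random numbers, reading boundaries
off empirical quantiles so its objective is monotone.

## What the simulator does and does not emulate

The simulator draws either patient-level bivariate normal responses or the
score statistics directly from their exact joint law (allowing fractional
information levels).  It reproduces precisely the model the design assumes:
normal responses, known variances and correlation, common information per
endpoint across arms, no dropout, no overrunning, selection exactly at the
planned first look.  Passing tests therefore certify the design logic and
its calibration *under the model*, not robustness to non-normality,
estimated nuisance parameters, staggered entry or deviations from the
pre-specified selection rule — except for correlation misspecification,
which the OC engine probes explicitly by generating data at a true ρ
different from the design ρ.  Under perfect correlation with equal
variances all worst-case configurations collapse onto the same
extreme-value event, and the realized FWER exceeds the nominal level by
roughly 13% of α; the error-spending calibration itself is exact only at
the design ρ.

## Design choices

* The safety criterion is solved in joint rather than conditional form —
  numerically identical targets, but the joint form keeps the root search
  monotone when the gate regime changes.
* Worst-case sweeps use the K+1 graded patterns (m arms with the huge
  effect on efficacy, the rest on safety, m = 0..K) alongside the global
  null; the mixed-null sweep enumerates all 2^K patterns, a superset of any
  graded subset.
* The multi-stage safety schedule's conditioning (on N_S ≥ 1, as in the
  single-stage criterion) is applied to both its upper and lower spends;
  the futility level for each endpoint is one minus its upper level.
* Replication defaults: 10⁴ per grid cell for exploratory sweeps, 10⁵ for
  FWER/power verification — at 10⁵ the binomial standard error at α = 0.05
  is 6.9×10⁻⁴, small enough to resolve the effects of interest while
  keeping any sweep in seconds on one CPU.

## Known limitations

Only 1:1 allocation, a single selected arm, selection at the first analysis
and normal endpoints are supported; futility is always binding; there is no
sample-size re-estimation, no mid-study correlation estimation and no
confidence intervals on termination.  The `w_E = 0` corner (selection by
safety alone) degenerates the conditional safety density and is supported
for single-stage designs only.
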