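# Methods

## Data model and counting-process representation

A subject contributes (L, T̃, Δ̃, Z): entry (delayed-entry/truncation)
time L ≥ 0, censored event time T̃ = min(T, C) > 0, status Δ̃ ∈ {0..d}
(0 = censored), covariates Z.  All computation runs through the
counting-process representation δ_X = (Y, Y_c, N₀..N_d) with

* event at-risk indicator Y(s) = 1(s ≤ T̃),
* censoring at-risk indicator Y_c(s) = 1(s < T̃) + 1(s = T̃, Δ̃ = 0),
* counting processes N_j(s) = 1(T̃ ≤ s, Δ̃ = j).

The Y_c definition encodes the tie convention used throughout: at a
tied time, events precede censorings (an event subject has already left
the censoring risk set at its own time, a censored subject has not).
The empirical averages (Ĥ, Ĥ_c, Ĥ_j) constitute the empirical
distribution Fₙ; every estimator in the package is a functional of Fₙ.

Curves are stored on the pooled sorted unique observed times as
right-continuous step functions with O(log n) interior queries.  Ĥ is
left-continuous, so the stored function is s ↦ Ĥ(s+) and the at-value
is its left limit.  Ĥ_c has isolated values at times carrying both
events and censorings; the stored step function is exact at every jump
time — the only locations where Ĥ_c enters a hazard increment.

## Estimators

Censoring hazard (Nelson–Aalen) ΔΛ̂₀(u) = ΔĤ₀(u)/Ĥ_c(u) and its
product limit Ĝ; cause hazards ΔΛ̂_j(u) = ΔĤ_j(u)/Ĥ(u); cumulative
incidences in IPCW form F̂_j(s) = Σ_{u≤s} ΔĤ_j(u)/Ĝ(u−).  The event
survival is always formed as Ŝ = 1 − Σ_j F̂_j, so the denominator
Ŝ(s)Ĝ(s) = Ĥ(s+) is consistent between the plain and
truncation-adjusted paths; the product-limit alternative is kept only
as a test oracle (the two agree to 1e−10 on tied data, which the suite
checks, together with the identity Ĥ(s+) = Ŝ(s)Ĝ(s)).

Zero risk sets raise hard errors naming the offending time, since all
asymptotics assume H_c(t) > 0 at the analysis time.

With delayed entry the risk sets become Y^L(s) = 1(L ≤ s ≤ T̃) (and the
analogous Y_c^L); the same formulas then produce the
truncation-adjusted Ĝ and F̂_j.

The entry-time distribution is estimated by the product-limit estimator
on the reversed time scale: reverse-hazard increments
ΔΛ̂_L(u) = ΔN_L(u)/Ĥ(u) at the entry atoms, and
F̂_L(s) = Π_{u∈(s,τ]} (1 − ΔΛ̂_L(u)) with τ the largest observed entry,
so F̂_L estimates P(L ≤ s | L ≤ τ) and F̂_L(τ) = 1.  Ties between entry
and event times are resolved by the construction itself (the at-risk
count Ĥ(u) includes subjects with T̃ = u); this choice is inherited
from the reversed-time formulation rather than asserted as meaningful.

The ρ-mapping reconstructs the counting averages from (Ĝ, F̂_j):
Ĥ = Ŝ(s−)Ĝ(s−), Ĥ_c = Ŝ(s)Ĝ(s−), Ĥ₀ = ∫ Ŝ d(1−Ĝ),
Ĥ_j = ∫ Ĝ(u−) dF̂_j.  On untruncated data ρ∘(curve fitting) returns
the raw empirical summary exactly (a tested identity).

## Pseudo-observations

**Jackknife.**  θ̂ₙ,ᵢ = n θ̂ₙ − (n−1) θ̂ₙ⁽ⁱ⁾ with θ̂ the (hazard-form)
Aalen–Johansen estimate at t.  The single-pass algorithm works on the
event-time grid u₁ < … < u_K ≤ t with risk counts r_k, total event
counts dall_k and cause counts d1_k.  Removing subject i downdates r_k
by one exactly on its at-risk window [a_i, b_i] (grid indices with
L_i ≤ u_k ≤ T̃_i) and its own event counts at b_i.  Prefix products of
the downdated factors g_k = 1 − dall_k/(r_k − 1), prefix sums of the
downdated increments, and a suffix recursion
D_{k−1} = d1_k/r_k + (1 − dall_k/r_k) D_k for the post-window remainder
yield every leave-one-out estimate in O(n + m) after sorting.  Windowed
ratios of prefix products are used on the truncated path; if a prefix
product is exactly zero (a risk set annihilated inside the window —
only possible in degenerate tiny-risk-set configurations) the affected
subjects fall back to a direct O(m) recomputation.  The naive O(n²)
path is retained as an oracle and CLI option; the two agree to 1e−12
on tied data.

On truncated samples the jackknife uses truncation-adjusted risk sets
and an unweighted fit — deliberately reproducing the practice whose
bias the modified IJ corrects.

**Infinitesimal jackknife.**  The influence-function plug-in

θ̂ᴵᴶₙ,ᵢ = 1(T̃ᵢ ≤ t, Δ̃ᵢ = j)/Ĝ(T̃ᵢ−)
  + ∫₀ᵗ (F̂_j(t) − F̂_j(s))/(Ŝ(s)Ĝ(s)) dM̂₀ᵢ(s),
M̂₀ᵢ(s) = N₀ᵢ(s) − ∫₀ˢ Y_cᵢ(u) dΛ̂₀(u),

evaluated with one set of full-sample curves.  By construction
Σᵢ M̂₀ᵢ(s) = 0 at every s, hence mean(θ̂ᴵᴶ) = F̂_j(t) to machine
precision; without censoring both integrals degenerate and every
flavour returns the indicator exactly.  Pseudo-values may fall outside
[0, 1] and are never clipped.

**Truncation-modified IJ.**  The same formula evaluated at the
ρ-mapped truncation-adjusted curves, with Y_c from the *untruncated*
setting (all subjects at risk from time zero), paired with weights
ŵᵢ = 1/F̂_L(min(T̃ᵢ, τ)) in the estimating equation.  Subjects with
follow-up beyond τ get the τ-conditional weight 1; the unknown
normalising constant of F̂_L cancels from both the weighted EE root and
its sandwich variance.  A question the formulas leave open is which
censoring hazard enters M̂₀ᵢ here; the ρ-reconstructed one and the
truncation-adjusted Nelson–Aalen are algebraically identical
(ΔΛ = 1 − Ĝ(u)/Ĝ(u−) in both cases, Ĝ being the product limit of the
adjusted hazard), so the point is moot in this implementation.

**Weight-derivative surface.**  The alternative dfbeta-style
implementation extends the hazard-form estimator to subject weights,
F̂₁ʷ(t) = Σ_k Sʷ(u_k−) ΔΛ̂₁ʷ(u_k), and differentiates analytically with
respect to each subject's own weight at equal weights.  The survival is
implemented as the product integral Π(1 − ΔΛʷ) rather than the literal
exp(−Λʷ) — the two differ at O(ΔΛ²), and only the product-integral
variant coincides with the Kaplan–Meier/IPCW identity that makes the
derivative equal the influence function.  The suite verifies agreement
with the plug-in IJ values below 1e−14 at n = 1000 and against central
finite differences at 1e−6 steps.

## Regression layer

Links: identity, log, logit, cloglog (inverse links μ).  A defaults to
the quasi-score ∂μ/∂β, matching GEE practice.  Identity link solves the
weighted normal equations in closed form; other links use Fisher
scoring initialised at link(mean pseudo clipped to (0.001, 0.999)) for
the intercept, with step-halving on μ-domain violations, convergence at
EE-norm < 1e−10 or relative β-change < 1e−12, max 100 iterations.

Variances:

* Huber–White: M̂⁻¹(Σᵢ ÛᵢÛᵢ′)M̂⁻ᵀ with Ûᵢ the weighted per-subject
  estimating function at β̂.  Conservative for KM/AJ pseudo-values
  because it drops the h₁ (second-order influence) term.
* Asymptotic Σ: plug-in of Var{h₀ + h₁}, with
  h₁ᵢ = (1/n) Σ_k A(β̂; Z_k) φ̈(X_k, Xᵢ) and φ̈ obtained by 4-point
  central differences of the weighted AJ functional along two-parameter
  reweightings (default step 1e−4 in direction space; keep it below 1/n
  so perturbed weights stay positive).  The uncentered sum of outer
  products is used so the no-censoring case (where φ̈ ≡ 0 because the
  functional is then linear in Fₙ) reproduces the sandwich exactly.
  The full h₁ costs O(n²) functional evaluations; a subsample option
  draws fewer k-terms.  Intended for moderate n; the closed-form second
  derivative from the literature could replace the numerical route and
  should match it.
* Bootstrap: subject-level resampling with pseudo-values and sampling
  weights recomputed per replicate; failed replicates are skipped and
  counted, more than 10% failing is an error; seeded and bit-for-bit
  reproducible.

Wald intervals and p-values in `summary()` use the Huber–White
variance.

## Simulation engine

The generator implements the linear-subdistribution competing-risks
model F₁(s|Z) = (β₀ + β₁Z)s, F₂(s|Z) = ηs on s ∈ [0, 1] with
Z ~ Bernoulli(p_Z) and uniform censoring C ~ U[0, 1/p_c]; p_c is
calibrated from the target observed-censoring fraction p_oc through
p_oc = P(C<1){P(T≤1)/2 + P(T>1)}.  Event-free subjects carry a latent
T = +∞; with p_c > 0 they are always censored before 1/p_c, and with
p_c = 0 their observed time is capped at the administrative time
1 + 1e−9 with status 0, since only t = 1 is ever analysed.  Truncation
draws L with mass 0.2 at zero and otherwise U(0, 1), independent of
everything, and rejection-samples until n subjects with L ≤ T̃ are
retained (n is the retained size).

What this emulates — and does not: covariate-independent censoring and
truncation, a single binary covariate, linear-in-time subdistributions.
Passing tests therefore demonstrate correctness of the estimators and
their variance theory under independent censoring/truncation; they say
nothing about covariate-dependent censoring (out of scope, as is any
regression modelling of the censoring distribution).

`run_scenario` applies every requested method to the same simulated
data per replicate, fits the identity-link model with the binary
exposure, and reports per-cell bias, average estimate, √n·SD,
√n·mean Huber–White SE, each with Monte-Carlo standard errors
(SD-of-estimates/√R for means; SD/√(2(R−1)) for the SD itself; a
200-draw replicate bootstrap for the efficiency ratio).  Efficiency is
the SD ratio (IJ/IPCW), not the variance ratio, matching how such
tables are conventionally printed.  Same seed ⇒ bit-identical output;
per-cell seeds derive from `SeedSequence([seed, cell])`.

## Problem sizes and numerical choices

The acceptance script uses 200–1000 replications per cell (200 at the
two n = 10,000 truncated cells, 300 at the n = 10,000 untruncated
cells, 500–1000 at n ≤ 2000); the resulting Monte-Carlo SE of a
√n-scaled SD is about 2–4% of its value, and of an average estimate
about 0.1–0.3%.  The test suite uses 100–500 replications with the
same summaries and compares against the full-study reference values at
max(3 Monte-Carlo SEs, 2%).

Tie-breaks, degenerate inputs: events precede censorings at tied times
(encoded in Y_c); entry exactly equal to the event time is retained
(L ≤ T̃ is a closed condition); ties between two event types at the
same time need no ordering (the pooled-jump representation keeps both
and no estimator here depends on an ordering); a subject alone at risk
at its own event time contributes a skipped jump to its leave-one-out
curve.

## Known limitations

Interval censoring, time-varying covariates, recurrent events,
multi-time (vector-t) GEE with working correlation, restricted-mean and
years-lost functionals, covariate-dependent censoring, and general
multi-state models are out of scope.  The asymptotic-Σ variance is
O(n²) and implemented for untruncated samples only (for truncated
cohorts the bootstrap is the supported second opinion).  The truncation
machinery assumes L, C and (T, Δ, Z) mutually independent.
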