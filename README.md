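# ijpseudo

Pseudo-observation regression for right-censored — and left-truncated —
time-to-event data with competing risks.

## The problem

Regression models for *cumulative* quantities (a survival probability
S(t | Z), a cause-specific cumulative incidence F₁(t | Z)) are awkward
under censoring: the response V = 1(T ≤ t, Δ = 1) is not observed for
censored subjects.  The pseudo-observation approach replaces each
subject's unobservable response by a transformation θ̂ₙ,ᵢ of the whole
censored sample whose conditional mean matches E(V | Z), and then fits
an ordinary generalized-linear mean model

    E(V | Z) = μ(β′Z),      Σᵢ A(β; Zᵢ) wᵢ {θ̂ₙ,ᵢ − μ(β; Zᵢ)} = 0.

This package implements two flavours of pseudo-observations built on
the Aalen–Johansen estimate F̂₁ (Kaplan–Meier for survival):

* **jackknife**: θ̂ₙ,ᵢ = n θ̂ₙ − (n−1) θ̂ₙ⁽ⁱ⁾, computed for all n
  leave-one-out samples in a single O(n + m) pass (the naive O(n²)
  recomputation is kept as an oracle);
* **infinitesimal jackknife (IJ)**: θ̂ᴵᴶₙ,ᵢ = φ(Fₙ) + φ̇_{Fₙ}(Xᵢ), the
  functional value plus its first-order influence function,

      θ̂ᴵᴶₙ,ᵢ = ∫₀ᵗ dN₁ᵢ(s)/Ĝ(s−) + ∫₀ᵗ (F̂₁(t)−F̂₁(s))/(Ŝ(s)Ĝ(s)) dM̂₀ᵢ(s),

  where Ĝ is the censoring Kaplan–Meier and M̂₀ᵢ the censoring
  martingale residual.  The two flavours are asymptotically equivalent;
  the IJ values are computed from one set of full-sample curves and are
  much faster.

For cohorts with **left truncation** (delayed entry: a subject is only
sampled if its entry time L does not exceed its censored event time T̃),
the influence function of the risk-set-adjusted estimator has the wrong
conditional mean, so both classical pseudo-observation variants are
biased unless the covariates carry no information on P(T̃ ≥ L | Z).
The package implements the corrected method: IJ pseudo-observations
evaluated through the ρ-mapping of the truncation-adjusted curves, with
inverse-probability-of-sampling weights ŵᵢ = 1/F̂_L(T̃ᵢ) in the
estimating equation, where F̂_L is the reversed-time product-limit
estimate of the entry-time distribution.

Variance estimation: Huber–White sandwich (conservative — it ignores
the second-order-influence correlation term), a plug-in asymptotic
variance using a numerical second-order influence function, and a
subject-level nonparametric bootstrap that recomputes pseudo-values and
weights inside every replicate.

## Worked example

Simulate a left-truncated competing-risks cohort (cause-1 risk
F₁(1|Z) = 0.20 + 0.20·Z, competing risk 0.20, 20% observed censoring,
entry times with mass 0.2 at zero and otherwise uniform) and regress
the 1-year cumulative incidence on the binary exposure:

```python
import ijpseudo as ij

cfg = ij.ScenarioConfig(p_Z=0.5, beta0=0.20, beta1=0.20, eta=0.20,
                        p_oc=0.20, n=2000, truncation=True)
cohort = ij.simulate_truncated_cohort(cfg, seed=42)

reg = ij.PseudoRegression(t=1.0, cause=1, link="identity",
                          method="ij_truncated").fit(ij.sample_to_frame(cohort))
print(reg.summary())
```

```
       term  estimate    se_hw   ci_low  ci_high            p
(Intercept)  0.212561 0.016070 0.181064 0.244057 6.126460e-40
         z1  0.179929 0.024472 0.131965 0.227893 1.945610e-13
```

The exposure coefficient 0.180 (95% CI 0.132–0.228) estimates the true
risk difference β₁ = 0.20; the intercept 0.213 estimates the baseline
risk β₀ = 0.20.  For contrast, the unmodified jackknife on the same
truncated cohort gives β̂₁ = 0.182, and the marginal risk-set-adjusted
Aalen–Johansen estimate of F₁(1) in the truncated sample is 0.256
(versus the true marginal 0.30) — with a symmetric exposure
distribution the slope bias is mild, but it grows sharply when p_Z is
asymmetric (see the scenario-5 grid).

Estimator classes follow scikit-learn conventions
(`get_params`/`set_params`, fitted attributes with trailing
underscores); `PseudoObservations` is a transformer producing the
pseudo-value column, and module-level functions (`ij_pseudo`,
`jackknife_pseudo`, `fit_pseudo_glm`, ...) expose the same operations
functionally.  A command-line interface mirrors the library:

```bash
ijpseudo compute-pseudo records.csv --time 1 --method ij-truncated --out pseudo.csv
ijpseudo fit records.csv --time 1 --link identity --method ij-truncated
ijpseudo simulate --scenario 3 --reps 1000 --seed 7 --out table.csv
ijpseudo curves records.csv --out curves.csv
```

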