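# Methods

This note documents the models, estimators, and numerical choices behind
voikit, in the spirit of a statistical package's methods appendix.  Nothing
here states an empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Decision-theoretic quantities

For decision options `D`, parameter vector `Z = (X, Y)` and net monetary
benefit `f_d(Z) = λ·QALYs − costs` at willingness-to-pay `λ` (GBP/QALY):

* value of the current-information decision: `max_d E[f_d(Z)]`;
* EVPI: `E[max_d f_d(Z)] − max_d E[f_d(Z)]` — worth of resolving all
  uncertainty before deciding;
* EVPPI for subset X: `E_X[max_d E[f_d(X,Y) | X]] − max_d E[f_d(Z)]` —
  worth of resolving X only.

Both are non-negative, and EVPPI ≤ EVPI, with equality when X = Z.  These
orderings are enforced as statistical invariants in the tests (within
combined standard errors).

## Built-in models

### Depression treatment decision tree

Three options (1 = no treatment, 2 = CBT, 3 = antidepressants).  A patient
recovers with probability `P_rec(d)`, then relapses with probability
`P_rel(d)`; the three terminal states carry 30-year costs `C` and QALYs `Q`.
Net benefit:

```
NB(d) = λ·[P_rec(1−P_rel)·Q_rec + P_rec·P_rel·Q_rel + (1−P_rec)·Q_nrec]
      − [P_rec(1−P_rel)·C_rec + P_rec·P_rel·C_rel + (1−P_rec)·C_nrec + C_treat(d)]
```

with fixed initial treatment costs `C_treat = (0, 300, 30)` GBP.  Parameter
distributions (12 stochastic dimensions, canonical order
`p_rec_1, p_rel_1, lorrec_2, lorrec_3, lorrel_2, lorrel_3, c_rec, c_rel,
c_nrec, q_rec, q_rel, q_nrec`):

| block | distribution |
| --- | --- |
| `p_rec_1` | Beta(6, 200) |
| `p_rel_1` | Beta(2, 100) |
| `(lorrec_2, lorrec_3)` | MVN(mean (0.99, 1.33), cov [[0.22, 0.15], [0.15, 0.20]]) |
| `(lorrel_2, lorrel_3)` | MVN(mean (−1.48, −0.40), cov [[0.14, 0.05], [0.05, 0.11]]) |
| costs | Normal: C_rec ~ N(1000, 50²), C_rel ~ N(2000, 100²), C_nrec ~ N(2500, 125²) |
| QALYs | Normal: Q_rec ~ N(26, 2²), Q_rel ~ N(23, 3²), Q_nrec ~ N(20, 4²) |

Treatment effects enter on the log-odds scale:
`P_rec(d) = expit(logit(p_rec_1) + lorrec_d)` for d = 2, 3, likewise for
relapse.  The correlated log-odds-ratio pairs are the multivariate-normal
approximation of a Bayesian network-meta-analysis posterior; `fit_mvn`
provides the same moment-matching for user-supplied MCMC tables (with a
marginal-skewness warning as a crude adequacy check).

Defaults and rationale:

* **λ = 20,000 GBP/QALY** — the conventional UK-style threshold; exposed as
  a config/CLI override.  The reproduced EVPI (~575) and the four EVPPIs
  corroborate this choice.
* Costs are sampled as plain Normals with the stated means/SDs (parameters
  like mean 1000, sd 50 are only plausible on the natural scale).
* Four standard query subsets: `probabilities` (all six event-probability
  parameters), `costs_qalys`, `cbt` (= `lorrec_2, lorrel_2`),
  `antidepressant` (= `lorrec_3, lorrel_3`).  The latter two *split* the
  correlated MVN blocks, so conditional sampling of the complement uses the
  exact Gaussian conditional (Schur complement); its covariance is
  value-independent and precomputed once per subset.

### Linear-Gaussian toy model (oracle)

Two decisions, `nb(1) = 0`, `nb(2) = X + Y` with `X ~ N(μ, σ_x²)`,
`Y ~ N(0, σ_y²)`.  With `s² = σ_x² + σ_y²`:

```
EVPI    = s·φ(μ/s) + μ·Φ(μ/s) − max(μ, 0)
EVPPI_X = σ_x·φ(μ/σ_x) + μ·Φ(μ/σ_x) − max(μ, 0)
```

These closed forms are the convergence oracle for all three estimator
families and for the cost-scaling property tests.  The toy model's own
noise structure (Gaussian, two decisions, one-dimensional subsets) is far
simpler than a real cost-effectiveness model; passing the oracle tests
shows estimator correctness, not model realism.

## Estimators

### Error budget

All budget-driven workflows use the split MSE = bias² + variance with bias
≤ ε/2 and variance ≤ 3ε²/4, so that (ε/2)² + 3ε²/4 = ε².  The inner-sample
bias of the nested estimator decays like 1/M, the outer variance like 1/N,
giving total cost ~ε⁻³ for nested MC and ~ε⁻² for MLMC and QMC.

### Nested Monte Carlo

EVPI uses N joint draws: first term = mean of per-draw maxima; second term
= max over decisions of the N-draw means.  The standard error is from the
delta method: with `d*` the empirical best decision, the per-draw values
`g_n = max_d f_d(Z_n) − f_{d*}(Z_n)` have the estimator as their mean, and
`SE = sd(g)/√N`.  *Known limitation*: this SE mildly understates the
replicate-to-replicate spread at small N, where the identity of the best
decision is itself noisy (a second-order term the delta method drops); at
the budgets the workflows choose, the understatement is within a factor
~1.5, and the tests verify order-of-magnitude calibration.  The estimator
is biased *downward* (the second term is biased upward by Jensen's
inequality); the tests demonstrate this at N = 10.

EVPPI draws N outer subset values and M inner conditional complements; the
first term averages `max_d` of inner means, the second is `max_d` of the
grand mean over all N·M draws, reusing the same draws (as is standard; the
induced correlation between terms is exactly what the paired `h_n` SE
accounts for).

### Multilevel Monte Carlo

Level ℓ is the nested estimator with `M = 2^ℓ` inner samples.  The level-ℓ
coupled difference uses one outer draw and 2^ℓ shared inner draws: the fine
summand averages all of them, the coarse summand is the *antithetic*
average of the (ℓ−1)-level summand on the two halves.  Expected differences
decay like `c·2^(−αℓ)`; variances decay as well (fitted rate β > 0 is
asserted on both built-in models).

**Second-term handling.**  The telescoping applies only to the nested first
term.  A standalone plain-MC run (4,000 draws) identifies the best
current-information decision `d*`, and `f_{d*}` is subtracted *per draw*
inside the level-0 stream (`max_d f_d − f_{d*}`).  The expectation is
unchanged, but the common net-benefit shift shared by all decisions cancels:
on the depression model this drops the level-0 variance from ~5×10⁹ to
~5×10⁵ (GBP²), without which the level-0 allocation alone would need ~10¹⁰
draws at ε = 0.5.  Misidentification of `d*` would bias the estimate upward
by the (small) gap between the top decision means; with clearly separated
decisions and thousands of pilot draws this is negligible, and an exact tie
is harmless because then either decision attains the max.

**Bias extrapolation and level choice.**  |E[d_ℓ]| is fitted as
`c·2^(−αℓ)` by weighted least squares on the log₂ scale (inverse squared
relative standard error weights).  The remaining bias beyond a candidate
level L is the *sum of directly simulated level means above L* plus the
fitted geometric tail beyond the finest level — far more robust than
extrapolating from the first few levels, because the empirical decay
accelerates (α is not constant in ℓ).  Pilot levels start at
(0, 1, 2) × 100 draws; each difference level is then refined to at least
1,000 draws (the d_ℓ distribution is spiky — decision flips are rare
events — so tiny pilots can badly underestimate both moments) and until its
standard error resolves either the bias bound or the mean itself, with a
per-level refinement budget of 8×10⁶ evaluations.  Levels are added while
the fitted tail beyond the finest level exceeds half the bias bound, up to
`max_level = 12` (M = 4,096); beyond that the run aborts advising a larger
ε.  The chosen L is the *smallest* level whose remaining bias is within
ε/2 — so a huge ε legitimately returns the level-0 (EVPI-form) estimator.

**Allocation.**  `N_ℓ ∝ √(V_ℓ / C_ℓ)` with `C_ℓ = 2^ℓ`, scaled so
`Σ V_ℓ/N_ℓ` meets the variance budget (the standard multilevel allocation),
with ceilings.  The reported bias estimate is the pilot's remaining-bias
value (post-refinement re-fits over-weight the ultra-precise low levels and
extrapolate the tail poorly).  With a fixed master seed the entire adaptive
run is deterministic.

The same pilot (`choose_inner_samples`) calibrates M = 2^L for the plain
nested-MC and QMC workflows — neither can estimate its own bias.

### Randomized quasi-Monte Carlo

Outer points come from the Sobol sequence (Joe–Kuo direction numbers via
scipy, 30-bit precision); K = 16 independently randomized replicates by
default (8–32 is the empirically adequate range; larger K trades point-set
quality for interval precision).  Scrambling is a **digital shift** — each
coordinate XOR-ed with one random 30-bit word per replicate — which
uniformly randomizes the set while preserving the dyadic balance property
(2^(m−s) points per bisected cell, verified exactly in tests); nested
(Owen) scrambling is available as `kind="owen"`.  Rank-1 lattice rules
(`frac(n·z/N)`, components of z coprime with N) with Cranley–Patterson
shifts are provided as an alternative generator.

Points map to parameters through the inverse-CDF transform; correlated MVN
blocks use the componentwise standard-normal quantile followed by the fixed
lower-triangular Cholesky factor, so the uniform-coordinate-to-parameter
map is stable and runs are bit-reproducible given seeds.  Uniforms are
clamped to [eps, 1−eps] (machine epsilon) before inversion so boundary
points cannot produce infinite quantiles; the all-zeros first Sobol point
is additionally skipped by default in unscrambled sets.

QMC is applied to the **outer samples only**; inner conditional draws stay
pseudo-random (inner accuracy is bias-limited, not variance-limited, so
low-discrepancy inner points would not help).  Per-replicate estimates use
the same paired form as nested MC; the estimate is their mean and
`SE = sd(replicates)/√K`.  The ε-driven workflow doubles N from 256 until
the replicate variance meets the 3ε²/4 bound, capped at 2×10⁸ total
evaluations per run (the SE is reported honestly either way).

### Credible intervals

`estimate ± 1.96·SE`, widened to the hull with the bias-corrected point
`estimate − bias` when a multilevel bias estimate is available.  This
deliberately reports *both* uncertainty sources rather than folding the
bias into a single RMSE-style band.

### Population scaling

`per_person × Σ_{t=0}^{h−1} patients/discount^t` — the effective discounted
patient count over a technology lifetime (5,000/year at 1.035 over 10 years
≈ 43,039 effective patients).

## Cost accounting

All methods report `total_nb_evaluations` in units of *parameter draws at
which the net-benefit vector is evaluated* (N·M for nested MC, K·N·M for
QMC, Σ N_ℓ·2^ℓ plus pilots for MLMC), making families comparable on one
axis.  Pilot and calibration draws are included in workflow totals.

## Problem sizes used in tests and the acceptance script

The test-suite and acceptance script run at desk scale: EVPI at 2²¹ MC
draws and 16×2¹⁶ QMC points; EVPPI at ε = 0.5 via the QMC workflow
(~10⁶–4×10⁷ evaluations per subset, the CBT subset being the most
expensive because its nested bias decays slowly in M); toy-model oracle
checks at 10⁴–3×10⁵ draws; the replicate RMSE study at 20 × 50,000 draws.
These sizes were chosen to give 3σ-separations for every asserted
comparison; tolerances are derived from each estimator's own reported
SE and bias (plus the published credible-interval widths where published
values are compared), not tuned to outcomes.

## Known limitations

* The delta-method EVPI standard error understates the spread at small N
  (see above); replicate-based SEs (QMC) do not share this issue.
* The MVN approximation for MCMC posteriors is moment-matching only;
  heavy-tailed or skewed posteriors are flagged by a skewness warning but
  not modelled (no multivariate-t or copula alternatives).
* Lattice generating vectors use a fixed Korobov-style default rather than
  component-by-component construction; Sobol is the primary generator.
* The configurable model family is the depression-style decision tree;
  arbitrary user models are supplied programmatically as a
  `DecisionProblem` (vectorised net-benefit callable plus a
  `DistributionSpec`), not via config file.
* Decision-relevant structural uncertainty, time discounting inside the
  tree, and EVSI are out of scope.
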