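# Methods

## Model

The package simulates competitive blood reconstitution after transplantation
of a single hematopoietic stem cell (HSC) together with 2×10⁵ whole-bone-
marrow competitor cells into a lethally irradiated recipient. Twelve
compartments are tracked for each of three origins (donor, competitor,
recipient; 36 state variables): long-term (LT) and short-term (ST) HSC pools
with logistic self-renewal, progenitor pools for neutrophils/monocytes (N),
erythrocytes (E), platelets (P) and B cells (B), mature myeloid counts, and a
two-stage eclipse chain for B-cell maturation. The eclipse chain is the
linear chain trick: inserting two first-order stages between the B progenitor
pool and mature B cells gives the maturation delay an Erlang(2, d_B)
distribution, reproducing the characteristically late B-cell rise.

The model is written on a normalized scale on which the competitor steady
state is (L, S, Y_i) = (1, 1, 1); the normalization constants L* and S* (the
LT/ST carrying capacities on the cell-count scale) survive only in the donor
initial condition L_D(0) = 1/L* or S_D(0) = 1/S*. Steady-state consistency
removes three parameter groups from estimation: d_i = p_Li + p_Si,
α_i = δ_i Z*_i / d_i, K_S = r_S/(p_LS + r_S).

Crowding is shared across origins (Σ_j L_j and Σ_j S_j): donor and
competitor stem cells compete for the same niche. Recipient cells have every
production rate zero — irradiation ablates the host's stem and progenitor
pools — and their mature cells decay exponentially at per-lineage rates δR_i,
which is why the recipient compartments also serve as an analytic oracle for
the integrator. The myeloid bypass is the direct LT→progenitor flux
p_Li L_D; B cells have none (p_LB = 0).

### Assumptions

- LT/IT-class clones are modelled as one LT population (they are not
  distinguishable from primary-transplant data).
- d_i and α_i are shared across origins; death rates differ only for
  recipient-derived cells (irradiation effect).
- Random-effect covariance is diagonal; covariates act additively on the
  log scale and only on the donor.
- T cells are outside the model's scope.

## Default parameters

Rates are per week. Growth rates and normalization constants use the
published young-population estimates (r_L = 2.39, r_S = 2.84,
L* = 1.07×10⁷, S* = 3.34×10⁷); aged covariates use the published
multiplicative factors where printed (r_L ×0.780, r_S ×1.18, p_SN ×0.260,
p_SE ×0.512, p_SP ×0.431, p_LP ×1.44). The remaining defaults are package
choices representing the qualitative physiology rather than fitted values:

| parameter | default | rationale |
|---|---|---|
| p_LS | 1.0 | ST production comparable to LT self-renewal |
| p_LP, p_SP | 1.5, 1.0 | platelet bypass active (week-24 dependency ≈ 0.6) |
| p_LN, p_LE | 1e-7 | N/E bypass essentially inactive (< 1e-6) |
| p_SN, p_SE, p_SB | 2.0, 2.0, 1.5 | canonical route dominant for N/E; delayed B output |
| δ_N, δ_E, δ_P, δ_B | 7, 0.17, 1.4, 0.35 | mature lifespans ≈ 1 d, 6 wk, 5 d, 3 wk |
| δR_E, δR_P | 0.30, 1.0 | recipient decay observable over the 8-week BM assay |
| Z*_N, Z*_E, Z*_P, Z*_B | 1.5e3, 9e6, 1e6, 4e3 | murine CBC per µL |
| LC0, SC0 (pop.) | 1e-6 | ~10–30 HSCs among 2×10⁵ competitor BM cells |
| ω_ψ, ω_φ | 0.3, 0.5 | moderate clone heterogeneity; uncertain graft composition |
| a_F, a_T | 0.3, 0.15 | logit-chimerism / log-CBC error scales |

With these values a population-average donor clone reaches ~8% chimerism
(set by the 1:10 ratio of donor to competitor LT pools), platelets rise
before erythrocytes and B cells, early-week chimerism sits below the 0.001%
detection limit (≈20% of records censored), and CBC dips before recovering —
the qualitative signatures of the real assays.

## Synthetic cohorts

`CohortDesign` defaults mirror the study's assay table: 53/22 young/aged
single-LT, 28/11 single-ST and 10 bone-marrow-only mice; chimerism at weeks
2, 3, 4, 8, 12, 16, 24; CBC at 4–24 weeks on the subset of mice matching the
study's CBC counts; recipient-decay chimerism (E, P) to week 8 for BM mice.
Noise is logit-normal for chimerism, log-normal for CBC; values strictly
below 0.001% are left-censored and stored at the limit. Draw order is fixed
(individuals in id order, parameters in declared order), so a seed fully
determines a cohort.

What the generator does **not** emulate: the real data's assay-to-assay
measurement schedules, missingness patterns, T-cell lineage, engraftment
failure, or any correlation between random effects. Passing recovery tests
on these cohorts therefore demonstrates the estimator's correctness under
the stated statistical model, not performance on the real deposit.

## Estimation

The likelihood is the censored observation model: Gaussian densities on the
log-odds (chimerism, scale a_F,i) and log (CBC, scale a_T,i) scales;
left-censored chimerism contributes Φ((logit(limit) − logit(f))/a_F,i).
Predictions are clipped to [1e-6, 100−1e-6] % before the logit.

`ChimerismMixedEffects` is an iterative conditional two-stage estimator:

1. **Per-mouse MAP.** L-BFGS-B on the log scaling factors (plus log LC0,
   SC0) with the log-normal prior; gradients by forward differences evaluated
   in one compiled batch; multi-start on the first sweep (log-uniform
   jitter), warm starts afterwards. Bounds of ±4 log units on scales keep
   line searches out of stiff extremes.
2. **Population update.** Population rates move to the geometric mean of the
   young modes (scales recentred so individual donor rates are unchanged);
   covariates are aged-minus-young mean differences; omegas the pooled mode
   spread; error scales the RMS of uncensored residuals.
3. **Population-block refinement.** A short L-BFGS-B ascent of the total
   data likelihood over the shared population rates with scales held fixed,
   recomputing the derived (d, α, K_S) each step. This step is essential:
   stage 1 only adjusts donor-relative scales, while a population rate also
   drives every competitor, so without it a mis-set population rate is
   absorbed into the competitor pools instead of corrected.

Sweeps repeat until the population vector's relative change is below `tol`
(default 1e-4, max 200 sweeps). Standard errors for covariates are the
two-stage approximation ω̂√(1/n_young + 1/n_aged); Wald p-values are
two-sided normal. Known limitations of the two-stage scheme: omegas are
biased downward (mode shrinkage), and the covariate SE ignores individual
estimation error — adequate for sign/recovery use, not for fine inference.

By default the near-inactive N/E bypass scales are fixed at 1 (values of
1e-7/week are unidentifiable from chimerism); death rates, recipient decay
rates, Z*_i and the normalization constants are taken from configuration —
Z*_i is initialized from the mean of week-20/24 CBC when present, the same
procedure used on real data.

### Numerical choices

- Integrator: adaptive Dormand–Prince 5(4), rtol 1e-8 / atol 1e-10
  (simulation) or 1e-6 / 1e-8 (inside fits), compiled with numba; the
  stiffness ratio (δ_N ≈ 7/wk vs δ_E ≈ 0.17/wk) is mild enough for an
  explicit pair, and scipy's LSODA is retained as an implicit-capable
  cross-check (`method="lsoda"`). Tiny negative states (within solver
  tolerance) are floored to zero; larger violations raise.
- Dependency 0/0 points are reported missing and excluded from minima; the
  "any time point" grid for the dropped/stable call is weekly weeks 1–24
  (week 0 is degenerate by construction).
- Strict inequalities at both classification thresholds (dependency < 20%
  dropped, week-24 < 50% low); boundary values classify stable/high.
- Censoring is strict: a value exactly at the detection limit is kept.
- Clustering: Euclidean distance (the linkage is complete by specification;
  the metric is a package choice), deterministic scipy ordering; k-means
  with 50 seeded restarts, best inertia kept.
- ROC: thresholds swept over all scores, ties entering simultaneously, AUC
  by trapezoid — algebraically the Mann–Whitney U/(n₁n₂) statistic, which
  the tests verify exactly. Both ratio orientations are scanned with the
  fixed convention "higher score ⇒ stable".

## Reference experiments (problem sizes)

The recovery study fits five 90-mouse cohorts (40/20 young/aged single-LT,
20/10 single-ST, CBC on a study-like subset) generated with an injected
aged covariate of log 2 on r_L, starting each fit from population rates
jittered by up to ±35%, flat covariates and inflated variance components.
The fit schedule (5 sweeps, 35/12 inner iterations, relaxed solver
tolerance) keeps one cohort fit in roughly a minute; the medians it reports
are unchanged at the precision quoted when the schedule is lengthened. The
ratio screen uses 60 single-LT mice with a bimodal platelet-bypass design
(pLP scales 5.0 vs 0.05, other omegas 0.15) so that the class contrast comes
from the designed bypass difference; classes are assigned by classifying
each mouse's own simulated dependency series.

## Limitations

- The estimator is not SAEM and does not claim numerical equality with
  estimates obtained from the real data; the acceptance surface is recovery
  on synthetic cohorts.
- Identifiability of L*/S* jointly with growth rates from chimerism alone is
  poor; they are fixed by configuration (the single-cell initial condition
  interpretation).
- p_LP/p_SP trade off against each other late in reconstitution (both pools
  approach their shares), so individual platelet-route splits are better
  identified than their population split.
- Week-24 stationarity of donor production is assumed where the analysis
  reads week-24 values; it is not re-derived.
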