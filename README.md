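# hemaflux

Compartmental modelling of hematopoietic stem cell (HSC) differentiation
kinetics from single-cell transplantation data, including the **myeloid
bypass pathway** — the direct route from long-term HSCs to myeloid
progenitors that skips the short-term HSC stage.

## Who this is for

Researchers analysing longitudinal *chimerism* data (the percentage of
peripheral-blood cells of each lineage derived from a transplanted donor
clone) from competitive transplantation assays in mice: a single donor HSC
transplanted together with whole-bone-marrow competitor cells into an
irradiated recipient, followed over 24 weeks across four lineages —
neutrophils/monocytes (N), erythrocytes (E), platelets (P) and B cells (B).

## The model

Three cell origins (donor D, competitor C, recipient R) compete in one host.
On a normalized scale where the competitor steady state is 1:

    dL_j/dt   = r_L,j (1 - Σ_m L_m) L_j
    dS_j/dt   = r_S,j (1 - Σ_m S_m / K_S) S_j + p_LS,j L_j
    dY_ij/dt  = p_Li,j L_j + p_Si,j S_j - d_i Y_ij        i ∈ {N,E,P,B}
    dZ_ij/dt  = α_i d_i Y_ij - δ_ij Z_ij                  i ∈ {N,E,P}
    dE1_j/dt  = α_B d_B Y_Bj - d_B E1_j                   (B-cell eclipse
    dE2_j/dt  = d_B E1_j - d_B E2_j                        chain: Erlang
    dZ_Bj/dt  = d_B E2_j - δ_B,j Z_Bj                      maturation delay)

`p_Li L` is the bypass flux (zero for B cells). Steady-state constraints pin
`d_i = p_Li + p_Si`, `α_i = δ_i Z*_i / d_i` and `K_S = r_S/(p_LS + r_S)`.
Observed chimerism is `100·Z_iD/(Z_iD+Z_iC)` for N and B and
`100·Z_iD/(Z_iD+Z_iC+Z_iR)` for E and P (recipient cells are
indistinguishable in those lineages).

Per-mouse donor rates are population rates times log-normal scaling factors
with additive aged-group covariates on the log scale. Observations carry
logit-normal (chimerism) and log-normal (blood count) noise and are
left-censored at the 0.001% detection limit. `ChimerismMixedEffects` fits
this hierarchy with an iterative two-stage scheme: per-mouse empirical-Bayes
modes, population/covariate/variance updates, and a population-block
likelihood refinement.

Downstream analyses: donor **influx** series (production rates between
compartments), **bypass dependency** `p_Li L_D / (p_Li L_D + p_Si S_D)` with
the stable/dropped (min < 20%) × high/low (week-24 < 50%) classification,
within-individual normalized clustering (complete linkage, k-means), and an
exhaustive ROC scan of chimerism-ratio features against the bypass classes.

## Worked example

```python
import numpy as np
from hemaflux import (
    CohortDesign, ChimerismMixedEffects, default_population, generate_cohort,
)
from hemaflux.bypass import classify_individual

pop = default_population()
design = CohortDesign(seed=1)           # study-sized cohort: 114 single-cell + 10 BM mice
obs, truth = generate_cohort(design, pop)
print(len(truth), "mice,", len(obs), "records,",
      f"{obs[obs.kind == 'chimerism'].censored.mean():.0%} censored")

cls = classify_individual(truth["LTy-001"], pop)
print(cls.label, f"min dependency {cls.min_dependency:.3f}, week 24 {cls.dependency_at_24:.3f}")
```

prints

```
124 mice, 3992 records, 20% censored
dropped-high min dependency 0.110, week 24 0.618
```

124 mice carry 3992 chimerism/CBC/recipient-decay records of which about a
fifth of the chimerism values fall below the 0.001% detection limit (mostly
the earliest weeks, before the donor clone has produced mature cells). The
first young single-LT mouse relies on the platelet bypass for 62% of its
platelet progenitor production at week 24 ("high") but its dependency dipped
to 11% mid-reconstitution ("dropped").

A complete pipeline (simulate → fit → influx → classify → cluster → scan) is
available from the shell:

```sh
hemaflux all --seed 1 --out results/
```

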