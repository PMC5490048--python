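# eusocia

Eco-evolutionary models of the preadaptations that trigger the transition
to eusociality in partially bivoltine Hymenoptera.

Many solitary bees and wasps fit two broods into a season: overwintered
foundresses breed in spring and, if they survive, again in summer, while
spring-born daughters breed once. `eusocia` asks when natural selection
favours those spring daughters staying home as helpers instead — the
first step toward a worker caste — and how that decision coevolves with
the mothers' brood sex ratios. It is written for theoreticians in social
evolution and sex allocation: a class-structured demographic engine,
reproductive values and selection gradients, an adaptive-dynamics
integrator, and a matching stochastic individual-based simulator, over
every combination of life cycle (female hibernation vs. larval diapause),
ploidy (haplodiploid vs. diploid) and mating system (lifetime monogamy,
serial monogamy, polyandry with effective mate number m_e).

## The model in brief

A scenario is a stationary annual life cycle with classes for
foundresses, stored sperm, helper and non-helper daughters, and males of
each brood. Winter survival is scaled so the annual projection matrix
**D** has dominant eigenvalue λ = 1; its right eigenvector **u** is the
stable class structure, and the left eigenvector **v** of the matching
gene-flow matrix **A** holds class reproductive values (summer daughter
normalized to v = 1). A mutant's inclusive fitness weighs each offspring
or sibling by relatedness × reproductive value; selection differentials
∂W/∂x at the resident drive three traits: the spring sex ratio z1, the
summer sex ratio z2, and the helping tendency h.

The headline quantity is the **eusociality threshold** B_min: the
smallest helping efficiency B (extra siblings per maternal offspring per
helper, conditional on maternal survival, B = S_f·b) at which helping is
favoured. For haplodiploids with female hibernation and male generation
overlap O_m,

    B_min = 2·m_e·(2 − O_m) / (m_e·(2 − O_m) + 2)

which runs from 1 (monogamy, no overlap) down to 2/3 (monogamy, full
overlap) and saturates at 2 under extreme polyandry; diploids need
B_min = 2·m_e/(m_e + 1) regardless of overlap, and serial monogamy
(half-sibling broods) needs B_min = 2.

## Worked example

```python
from eusocia import (ModelConfig, TraitState, ADSettings,
                     eusociality_threshold, sex_ratio_equilibrium,
                     integrate_coevolution)

cfg = ModelConfig(F1=5.0, F3=5.0, S_f=0.9, S_m=0.6, b=1.5)  # haplodiploid FH monogamy

print(sex_ratio_equilibrium(cfg))                 # no-help equilibrium
print(eusociality_threshold(cfg).B_min)           # threshold at that equilibrium

traj = integrate_coevolution(cfg, TraitState(0.5, 0.5, 0.0),
                             ADSettings(T_total=800, h_release_time=300))
print(traj.final_state())
```

prints

```
(0.611461859778172, 0.4019750375536938)
0.9107259390652178
TraitState(z1=0.0, z2=0.49999999961252545, h=1.0)
```

Read: with male survival S_m = 0.6, selection first splits the sex ratios
(male-biased spring brood, 61% sons; female-biased summer brood, 40%
sons), which lowers the helping threshold to B_min ≈ 0.91 — helpers pay
even at sub-unit efficiency. The realized efficiency here is
B = S_f·b = 1.35, so once helping is allowed to evolve the system crosses
to the worker-caste equilibrium: an all-female, all-helper spring brood
(z1 = 0, h = 1) and an unbiased summer brood (z2 = 1/2) — an effectively
univoltine colony with a lifetime-unmated worker cohort.

The same analyses are available from the shell:

```
eusocia threshold --Sm 0.6                 # one scenario, one row of CSV
eusocia sweep --param S_m --from 0 --to 1 --steps 50   # threshold curves
eusocia trajectory --Sm 0.6 --F1 5 --F3 5 --T 800 --h-release 300 --out traj.csv
eusocia simulate --N 500 --years 20000 --h-start 2000 --seed 42 --out run.csv
eusocia fig2 / eusocia fig3                # bundled reference drivers
```

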