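# Methods

`eusocia` models the joint evolution of brood sex ratios and daughter
helping in partially bivoltine Hymenopteran life cycles, and asks under
which preadaptations (ploidy, overwintering mode, mating system, male
generation overlap) natural selection favours the first step toward a
worker caste. This note records the model, its assumptions, the numerical
choices, and what the accompanying tests do and do not establish.

## The annual life cycle and its class structure

A year has two breeding episodes. Under **female hibernation (FH)** only
mated females overwinter. Spring starts with mated foundresses (class 1)
and their stored sperm (class 2). Each foundress produces `F1` offspring
at sex ratio `z1` (proportion sons, class 7); daughters either help at the
natal nest (probability `h`, class 4) or breed solitarily in summer
(class 3). Foundresses survive to a second brood with probability `S_f`
(class 5) together with their sperm (class 6). Spring males mate with the
class-3 females in summer and, surviving with probability `S_m`, join the
autumn mating pool. Summer mothers (classes 3 and 5) breed at sex ratio
`z2`; autumn daughters mate and overwinter. Under **larval diapause
(LD)** both sexes overwinter: the spring generation is unmated females
(class 1) plus overwintered males (class 2), spring males of class 2
survive into the summer pool with `S_m` (class 8), and autumn offspring of
both sexes overwinter. Sperm classes are bookkeeping devices: their
reproduction columns are zero (offspring are counted through mothers), so
no gene flow is double-counted.

Winter survival is scaled by a factor `alpha = 1/(F_A (1 - z2))`, where
`F_A` is the total autumn production per foundress, which pins the
dominant eigenvalue of the annual projection matrix at exactly 1 — a
stationary population, the model's statement of density-dependent
overwintering. The stable class structure `u` has the closed form of
simple cohort bookkeeping (`u1 = 1`, `u3 = F1(1-z1)(1-h)`, …) and is
verified against the dominant eigenvector at every construction.

## Helping

Each helper raises her mother's second-brood output linearly:
`F5 = F1 (1 + b n)` with `n = h (1 - z1) F1` expected helpers. The
decision-time benefit of helping is `B = S_f b` extra siblings per
maternal offspring, conditional on the mother surviving; helpers whose
mother dies contribute nothing and have zero direct reproduction. `B` is
the *efficiency ratio* — `B > 1` means a helper raises siblings more
efficiently than she would raise her own offspring — and all thresholds
are reported on this scale, which makes them invariant to the fecundity
baseline chosen for the helper boost.

## Reproductive values and generation overlap

The gene-flow matrix `A` mirrors the demographic transitions but assigns
genetic credit: survivors 100% to themselves; haplodiploid mothers 100%
of sons, mothers and fathers 50% each of daughters; diploid parents 50%
of everything; male columns scaled by the mates per male (`Q1`, `Q2`).
Class reproductive values `v` are the dominant left eigenvector of `A`
(eigenvalue 1 at demographic equilibrium), normalized so a summer-born
daughter has value 1. With no male generation overlap the within-brood
male/female RV ratio reduces to the classic 1/2 (haplodiploids) or 1
(diploids). Overlap — spring males surviving into the autumn pool (FH) or
overwintered males into the summer pool (LD) — is summarized by `O_m`,
implemented as the overlapping brood's paternity share of the later pool.
FH overlap inflates spring-male RV and deflates summer-male RV; LD does
the reverse. These RV asymmetries are what drive split sex ratios.

## Selection, equilibria, thresholds

Mutant inclusive fitness weighs each offspring (or sibling) class by
relatedness times resident reproductive value. Relatedness uses the
gene-credit convention (fraction of the recipient's genome identical by
descent with the focal female): daughters 1/2 in both ploidies, sons 1
(haplodiploid) or 1/2 (diploid), sisters `1/4 + p/2` (haplodiploid) or
`(1+p)/4` (diploid) with `p = 1/m_e` the probability of sharing a father,
brothers 1/2 or `(1+p)/4`. This convention, paired with the RV
normalization, makes the no-overlap sex-ratio equilibrium exactly
unbiased — the criterion that fixes the convention where several
textbook variants exist.

Selection differentials are central finite differences (step `1e-6`) of
mutant fitness at the resident, cross-checked against the analytic
derivatives (mutant fitness is linear in each mutant trait); the summer
sex ratio, expressed by two classes, combines the class differentials
with normalized frequency weights (both class gradients are proportional,
so the equilibrium is weighting-independent). Sex-ratio equilibria are
found by damped projected gradient ascent from (1/2, 1/2); boundary
values count as equilibria when the gradient points outward. Gradients at
trait boundaries use one-sided differences, and resident traits are
clipped `1e-9` inside [0, 1] so classes emptied at a boundary keep their
limiting reproductive values.

The eusociality threshold `B_min` is the smallest `B` at which the
helping differential at `h = 0` turns nonnegative, found by bisection on
`B` in [1e-3, 10] to `1e-6`, with sex ratios at their no-help equilibrium
(`fixed_sex_ratios`) or re-equilibrated at `h = 1e-4`
(`coevolved_sex_ratios`; with an infinitesimal feedback the two agree to
about `1e-5`). At an interior equilibrium the summer RV ratio is pinned
at `r_dau/r_son`, which collapses the threshold to the closed identity
`B_min = 2/(1 + 2p(1 - z2*))`; the bisection result matches it to the
bisection tolerance, a strong end-to-end consistency check. As a function
of overlap the haplodiploid FH surface is
`B_min = 2 m_e (2 - O_m) / (m_e (2 - O_m) + 2)` — spanning 1 (monogamy,
no overlap) to 2/3 (monogamy, full overlap) and saturating at 2 under
extreme polyandry, with sub-unit thresholds exactly when
`m_e < 2/(2 - O_m)` — while diploids sit at `2 m_e/(m_e + 1)` regardless
of overlap and serial monogamy (half-sibling broods) at 2. One caveat:
the operational `O_m` (paternity share) and the algebraic overlap measure
implicit in the closed surface coincide at the limits but differ by a few
percent at interior `S_m`; threshold-versus-`S_m` curves therefore always
use the bisection path, and the closed surface is reserved for
statements parameterized directly by `O_m`.

## Adaptive dynamics

Traits evolve by `dx/dt = K dW/dx` (`K = 1`; evolutionary time is in
arbitrary units, with an option to rescale the reported axis so the
pre-release phase spans a chosen number of years for overlaying
individual-based runs). The integrator is an adaptive Heun scheme with an
embedded Euler error estimate (`rtol 1e-9`, `atol 1e-12`), per-step
projection onto the unit box, and projected gradients at pinned
boundaries; helping is frozen until a release time. At the reference
parameters (`F1 = F3 = 5`, `S_f = 0.9`, `S_m = 0.6`, `b = 1.5`,
haplodiploid FH monogamy) the pre-release phase settles at the split
equilibrium (z1 ≈ 0.611, z2 ≈ 0.402); after release the system crosses to
the worker-caste equilibrium `(z1, z2, h) = (0, 1/2, 1)`: an all-female,
all-helper spring brood, an unbiased summer brood, and `O_m → 0`. The
default horizon (`T = 800`, release at 300) converges with all active
gradients below `1e-7`; tightening the tolerance tenfold moves the
endpoint by less than `1e-6` per trait.

## Individual-based simulation

The simulator draws Poisson offspring numbers, assigns sex by the
mother's expressed `z1`/`z2` (haplodiploid sons from unfertilized eggs
carry a single maternal gamete), recruits helpers by the daughter's own
expressed `h`, samples mates uniformly with replacement from the current
male pool, stores ejaculates (several, with fixed paternity shares whose
squares sum to `1/m_e`, under polyandry; a fresh single mate per brood
under serial monogamy), survives foundresses and overlapping males
binomially, and restores exactly `N` breeding females by uniform winter
sampling (LD thins overwintering males by the same factor). Every
transmitted gamete mutates per allele with probability `mu = 0.01` by a
Normal(0, `sigma = 0.01`) step clipped to [0, 1]; helping-locus mutation
is disabled before the release year. Unmated females do not reproduce.
Defaults are `N = 5000` nests and 25,000 years with release at 10,000.

With traits frozen, yearly cohort sizes match the analytic class
structure; with selection on, sex ratios converge to the analytic
equilibria and, at the reference parameters, the full transition to
`(0, 1/2, 1)` completes roughly 15,000 years after helping is released —
at `N = 500` just as at larger `N`, because the selection response is
limited by mutational variance input, which sets a timescale that does
not shrink with population size or simulated horizon. Scaled-down runs
must therefore keep the full post-release duration: the packaged
transition driver uses `N = 500` over 20,000 years (release at 2,000),
which reproduces the deterministic endpoint within the stochastic ribbon;
a 6,000-year horizon reaches only `h ≈ 0.4` regardless of `N`.

## What the tests show — and what they do not

The synthetic regimes exercise the model's own stated conditions; nothing
here is fit to field data. Passing tests establish internal consistency
(closed-form demography vs. eigenstructure, event-level allele-descent
bookkeeping vs. eigenvector reproductive values, finite-difference vs.
analytic gradients, integrator vs. root-finder, simulator vs. analytic
demography and equilibria) and agreement with the model's published
limiting thresholds. They do not establish that real halictine or vespid
populations satisfy the assumptions: lifetime sperm storage, linear
helper returns, random mating, no inbreeding, no spatial or age
structure, maternal control of brood sex ratios, and annual colonies
without queen–worker conflict are all taken as given.

## Known limitations

- The coevolved-threshold mode captures only the first-order (`h = 1e-4`)
  sex-ratio feedback; finite-helping feedback is available through the
  trajectory integrator instead.
- The explicit integrator resolves the stiff approach to equilibria by
  step-size control rather than an implicit method; very tight tolerance
  requests trade directly into run time.
- The individual-based simulator treats an ejaculate as one genome and
  mutates per fertilization; sperm-by-sperm mutation would differ only in
  within-brood paternal variance.
- `O_m` is reported as a paternity share; closed-form threshold surfaces
  in `O_m` are exact only at the anchored limits (see above).
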