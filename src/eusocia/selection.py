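"""Relatedness, inclusive fitness, selection gradients, and thresholds.

A rare mutant's inclusive fitness is her expected number of offspring (or,
for a prospective helper, siblings) in each class, weighted by the
relatedness of the recipient to her and by the recipient's reproductive
value in the resident population. Selection differentials are derivatives
of that mutant fitness at the resident trait value; traits expressed by
more than one class (the summer sex ratio, set by both spring-born
breeders and surviving foundresses) are aggregated with normalized class
frequency weights.

The eusociality threshold ``B_min`` is the smallest survival-conditional
helper benefit ``B = S_f b`` at which the selection differential on
helping is nonnegative at ``h = 0``, with sex ratios at (or, in the
coevolved mode, infinitesimally perturbed from) their no-help equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np

from .config import Mating, ModelConfig, Ploidy, TraitState, validate_config
from .demography import (
    HELPER,
    SOLITARY_DAUGHTER,
    SURVIVOR,
    DemographicState,
    stable_class_distribution,
)
from .reproductive_value import ReproductiveValues, reproductive_values

BOUNDARY_EPS = 1e-9
FD_STEP = 1e-6


class ThresholdMode(str, Enum):
    FIXED_SEX_RATIOS = "fixed_sex_ratios"
    COEVOLVED_SEX_RATIOS = "coevolved_sex_ratios"


class SelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class RelatednessSet:
    """Relatedness of the trait-controlling female to her kin.

    Coefficients are the expected fraction of the recipient's genome that
    is identical by descent with genes carried by the focal female — the
    convention that pairs with the gene-flow credit rules, so that
    'life-for-life' values are simply ``r * v``. ``r_sis``/``r_bro`` refer
    to the siblings a helper would rear (half-siblings under serial
    monogamy, paternity-diluted under polyandry with ``p = 1/m_e``).
    """

    r_dau: float
    r_son: float
    r_sis: float
    r_bro: float
    p: float
    m_e: float


@dataclass(frozen=True)
class SelectionGradients:
    dW_dz1: float
    dW_dz2: float
    dW_dh: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dW_dz1, self.dW_dz2, self.dW_dh])


@dataclass(frozen=True)
class ThresholdResult:
    B_min: float
    mode: ThresholdMode
    config: ModelConfig
    z1_star: float
    z2_star: float


@dataclass(frozen=True)
class ResidentState:
    """Everything needed to evaluate mutant fitness at a resident."""

    config: ModelConfig
    traits: TraitState
    demography: DemographicState
    rvs: ReproductiveValues
    relatedness: RelatednessSet


def relatedness_coefficients(config: ModelConfig) -> RelatednessSet:
    """Relatedness coefficients for the scenario's ploidy and mating system.

    Haplodiploid females: daughters 1/2, sons 1 (a son's genome is wholly
    maternal), sisters ``1/4 + p/2`` (3/4 for full sisters), brothers 1/2.
    Diploids: daughters and sons 1/2, siblings ``(1+p)/4``. Serial
    monogamy makes the helper's charges maternal half-siblings (p = 0
    across broods).
    """
    validate_config(config)
    if config.mating is Mating.SERIAL_MONOGAMY:
        p = 0.0
        m_e = math.inf
    else:
        m_e = config.m_e
        p = 1.0 / m_e
    if config.ploidy is Ploidy.HAPLODIPLOID:
        r_sis = 0.25 + 0.5 * p
        r_bro = 0.5
        r_dau, r_son = 0.5, 1.0
    else:
        r_sis = 0.25 * (1.0 + p)
        r_bro = r_sis
        r_dau, r_son = 0.5, 0.5
    return RelatednessSet(
        r_dau=r_dau, r_son=r_son, r_sis=r_sis, r_bro=r_bro, p=p, m_e=m_e
    )


def resident_state(config: ModelConfig, traits: TraitState) -> ResidentState:
    """Demography, RVs and relatedness of the resident population.

    Trait values are clipped ``BOUNDARY_EPS`` inside [0,1] so that classes
    emptied at a boundary keep well-defined limiting values.
    """
    clipped = TraitState(
        z1=min(max(traits.z1, BOUNDARY_EPS), 1.0 - BOUNDARY_EPS),
        z2=min(max(traits.z2, BOUNDARY_EPS), 1.0 - BOUNDARY_EPS),
        h=min(max(traits.h, 0.0), 1.0 - BOUNDARY_EPS),
    )
    demog = stable_class_distribution(config, clipped, check=False)
    rvs = reproductive_values(config, clipped, demog)
    rel = relatedness_coefficients(config)
    return ResidentState(
        config=config, traits=clipped, demography=demog, rvs=rvs, relatedness=rel
    )


# ---------------------------------------------------------------------------
# Mutant inclusive-fitness functions (resident quantities held fixed)
# ---------------------------------------------------------------------------

def inclusive_fitness_sex_ratio(
    mutant: TraitState, resident: ResidentState
) -> float:
    """Inclusive fitness of a spring foundress with mutant sex ratios.

    Spring brood: ``F1`` offspring at the mutant ``z1``; non-helping
    daughters carry the spring-breeder RV, helper daughters have zero own
    RV but raise the mutant's summer fecundity. Summer brood: with
    probability ``S_f`` the mutant survives and produces ``F5(z1')``
    offspring at her mutant ``z2``. Resident-dependent quantities (class
    RVs, mate counts) are evaluated at the resident.
    """
    cfg = resident.config
    rel = resident.relatedness
    rvs = resident.rvs
    h_res = resident.traits.h
    z1m, z2m = mutant.z1, mutant.z2
    F1 = cfg.F1
    v = rvs.v
    spring = F1 * (
        z1m * rel.r_son * rvs.v_m1
        + (1.0 - z1m)
        * rel.r_dau
        * ((1.0 - h_res) * v[SOLITARY_DAUGHTER] + h_res * v[HELPER])
    )
    F5_mut = F1 * (1.0 + cfg.b * h_res * (1.0 - z1m) * F1)
    summer_per_off = (
        (1.0 - z2m) * rel.r_dau * rvs.v_f2 + z2m * rel.r_son * rvs.v_m2
    )
    return spring + cfg.S_f * F5_mut * summer_per_off


def inclusive_fitness_helping(mutant_h: float, resident: ResidentState) -> float:
    """Inclusive fitness of a spring daughter with mutant helping tendency.

    With probability ``1-h`` she breeds herself (``F3`` offspring at the
    resident summer sex ratio); with probability ``h`` she helps, adding
    ``B`` siblings per maternal offspring, valued at sibling relatedness.
    Both branches are expressed per maternal summer offspring by the
    common factor ``F3``, making ``B`` the efficiency ratio at which she
    is indifferent.
    """
    cfg = resident.config
    rel = resident.relatedness
    rvs = resident.rvs
    z2 = resident.traits.z2
    B = cfg.S_f * cfg.b
    own = (1.0 - z2) * rel.r_dau * rvs.v_f2 + z2 * rel.r_son * rvs.v_m2
    sibs = (1.0 - z2) * rel.r_sis * rvs.v_f2 + z2 * rel.r_bro * rvs.v_m2
    return cfg.F3 * ((1.0 - mutant_h) * own + mutant_h * B * sibs)


def _summer_fitness_by_class(
    mutant_z2: float, resident: ResidentState
) -> tuple[float, float]:
    """Mutant summer-brood fitness for class-3 and class-5 mothers."""
    cfg = resident.config
    rel = resident.relatedness
    rvs = resident.rvs
    per_off = (
        (1.0 - mutant_z2) * rel.r_dau * rvs.v_f2
        + mutant_z2 * rel.r_son * rvs.v_m2
    )
    return cfg.F3 * per_off, resident.demography.F5 * per_off


# ---------------------------------------------------------------------------
# Selection gradients
# ---------------------------------------------------------------------------

def _fd(fun: Callable[[float], float], x: float, lo: float = 0.0, hi: float = 1.0) -> float:
    """Central finite difference, one-sided at the domain boundaries."""
    step = FD_STEP
    a, b = max(lo, x - step), min(hi, x + step)
    if b <= a:
        raise SelectionError("degenerate finite-difference interval")
    return (fun(b) - fun(a)) / (b - a)


def selection_gradient(
    trait_id: str, config: ModelConfig, traits: TraitState,
    resident: ResidentState | None = None,
) -> float:
    """Selection differential for ``z1``, ``z2`` or ``h`` at the resident.

    Finite differences of the mutant inclusive-fitness functions; the
    summer sex ratio aggregates its two expressing classes (spring-born
    breeders and surviving foundresses) with normalized frequency weights.
    """
    if resident is None:
        resident = resident_state(config, traits)
    t = resident.traits
    if trait_id == "z1":
        return _fd(
            lambda x: inclusive_fitness_sex_ratio(t.replace(z1=x), resident), t.z1
        )
    if trait_id == "z2":
        u = resident.demography.u
        u3, u5 = u[SOLITARY_DAUGHTER], u[SURVIVOR]
        tot = u3 + u5
        if tot <= 0.0:
            return 0.0
        w3, w5 = u3 / tot, u5 / tot
        g3 = _fd(lambda x: _summer_fitness_by_class(x, resident)[0], t.z2)
        g5 = _fd(lambda x: _summer_fitness_by_class(x, resident)[1], t.z2)
        return w3 * g3 + w5 * g5
    if trait_id == "h":
        return _fd(lambda x: inclusive_fitness_helping(x, resident), t.h)
    raise SelectionError(f"unknown trait_id: {trait_id!r}")


def selection_gradients(
    config: ModelConfig, traits: TraitState
) -> SelectionGradients:
    resident = resident_state(config, traits)
    return SelectionGradients(
        dW_dz1=selection_gradient("z1", config, traits, resident),
        dW_dz2=selection_gradient("z2", config, traits, resident),
        dW_dh=selection_gradient("h", config, traits, resident),
    )


def closed_form_gradients(
    config: ModelConfig, traits: TraitState, resident: ResidentState | None = None
) -> SelectionGradients:
    """Analytic gradients (mutant fitness is linear in each mutant trait).

    Used as an independent cross-check of the finite-difference path.
    """
    if resident is None:
        resident = resident_state(config, traits)
    cfg, rel, rvs = resident.config, resident.relatedness, resident.rvs
    t = resident.traits
    v = rvs.v
    F1 = cfg.F1
    summer_per_off = (
        (1.0 - t.z2) * rel.r_dau * rvs.v_f2 + t.z2 * rel.r_son * rvs.v_m2
    )
    g1 = (
        F1
        * (
            rel.r_son * rvs.v_m1
            - rel.r_dau
            * ((1.0 - t.h) * v[SOLITARY_DAUGHTER] + t.h * v[HELPER])
        )
        - cfg.S_f * cfg.b * t.h * F1**2 * summer_per_off
    )
    u = resident.demography.u
    u3, u5 = u[SOLITARY_DAUGHTER], u[SURVIVOR]
    tot = u3 + u5
    per_off_slope = rel.r_son * rvs.v_m2 - rel.r_dau * rvs.v_f2
    g2 = 0.0
    if tot > 0.0:
        g2 = (u3 * cfg.F3 + u5 * resident.demography.F5) / tot * per_off_slope
    B = cfg.S_f * cfg.b
    own = (1.0 - t.z2) * rel.r_dau * rvs.v_f2 + t.z2 * rel.r_son * rvs.v_m2
    sibs = (1.0 - t.z2) * rel.r_sis * rvs.v_f2 + t.z2 * rel.r_bro * rvs.v_m2
    gh = cfg.F3 * (B * sibs - own)
    return SelectionGradients(dW_dz1=float(g1), dW_dz2=float(g2), dW_dh=float(gh))


# ---------------------------------------------------------------------------
# Sex-ratio equilibria
# ---------------------------------------------------------------------------

def sex_ratio_equilibrium(
    config: ModelConfig,
    h_fixed: float = 0.0,
    start: tuple[float, float] = (0.5, 0.5),
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> tuple[float, float]:
    """Joint equilibrium ``(z1*, z2*)`` of the two sex-ratio gradients.

    Damped gradient-ascent iteration (on the analytic gradients, which are
    cross-checked against the finite-difference path elsewhere) from
    ``start`` with projection onto [0,1]; a boundary value is an
    equilibrium when the gradient points outward there. Raises
    :class:`SelectionError` on non-convergence.
    """
    validate_config(config)
    z1, z2 = start
    eta = 0.05 / max(config.F1, config.F3)
    last = np.inf
    for it in range(max_iter):
        traits = TraitState(z1=z1, z2=z2, h=h_fixed)
        resident = resident_state(config, traits)
        grads = closed_form_gradients(config, traits, resident)
        g1, g2 = grads.dW_dz1, grads.dW_dz2
        # projected gradient: pinned boundaries only count inward pulls
        p1 = 0.0 if (z1 <= 0.0 and g1 < 0) or (z1 >= 1.0 and g1 > 0) else g1
        p2 = 0.0 if (z2 <= 0.0 and g2 < 0) or (z2 >= 1.0 and g2 > 0) else g2
        err = max(abs(p1), abs(p2))
        if err < tol:
            return float(z1), float(z2)
        if err > 4.0 * last:
            eta *= 0.5  # overshooting; damp harder
        last = err
        z1 = min(max(z1 + eta * p1, 0.0), 1.0)
        z2 = min(max(z2 + eta * p2, 0.0), 1.0)
    raise SelectionError(
        f"sex-ratio equilibrium did not converge: z=({z1}, {z2}), "
        f"gradients=({g1}, {g2})"
    )


# ---------------------------------------------------------------------------
# Eusociality threshold
# ---------------------------------------------------------------------------

def helping_gradient_at_B(
    config: ModelConfig,
    B: float,
    mode: ThresholdMode,
    z_star_h0: tuple[float, float],
    eps_h: float = 1e-4,
) -> float:
    """Helping selection differential at ``h -> 0`` for benefit level ``B``."""
    if config.S_f <= 0.0:
        raise SelectionError("S_f = 0: helping can never pay (B = S_f*b = 0)")
    cfg = config.replace(b=B / config.S_f)
    if mode is ThresholdMode.FIXED_SEX_RATIOS:
        z1, z2 = z_star_h0
        traits = TraitState(z1=z1, z2=z2, h=0.0)
    else:
        z1, z2 = sex_ratio_equilibrium(cfg, h_fixed=eps_h, start=z_star_h0)
        traits = TraitState(z1=z1, z2=z2, h=eps_h)
    return selection_gradient("h", cfg, traits)


def eusociality_threshold(
    config: ModelConfig,
    mode: ThresholdMode | str = ThresholdMode.FIXED_SEX_RATIOS,
    bracket: tuple[float, float] = (1e-3, 10.0),
    tol: float = 1e-6,
) -> ThresholdResult:
    """Minimal helper benefit ``B_min`` for helping to be favoured.

    Bisection on ``B`` of the sign of the helping differential at
    ``h = 0``, with sex ratios at their no-help equilibrium
    (``fixed_sex_ratios``) or re-equilibrated at an infinitesimal helping
    level (``coevolved_sex_ratios``).
    """
    mode = ThresholdMode(mode)
    validate_config(config)
    z_star = sex_ratio_equilibrium(config, h_fixed=0.0)
    lo, hi = bracket
    g_lo = helping_gradient_at_B(config, lo, mode, z_star)
    g_hi = helping_gradient_at_B(config, hi, mode, z_star)
    if g_lo >= 0.0 or g_hi <= 0.0:
        raise SelectionError(
            "no sign change of the helping gradient in the bracket: "
            f"g({lo}) = {g_lo}, g({hi}) = {g_hi}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if helping_gradient_at_B(config, mid, mode, z_star) < 0.0:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        B_min=0.5 * (lo + hi),
        mode=mode,
        config=config,
        z1_star=z_star[0],
        z2_star=z_star[1],
    )


def threshold_at_overlap(
    O_m: float, m_e: float = 1.0, ploidy: Ploidy | str = Ploidy.HAPLODIPLOID,
    mating: Mating | str = Mating.MONOGAMY,
) -> float:
    """Closed-form FH eusociality threshold as a function of overlap.

    Evaluating the life-for-life comparison at the no-help sex-ratio
    equilibrium (where the summer sex ratio satisfies
    ``z2* = (1 - O_m)/(2 - O_m)`` and the summer male/female RV ratio is
    pinned at ``r_dau/r_son``) gives, with ``p = 1/m_e``:

    * haplodiploids: ``B_min = 2 m_e (2 - O_m) / (m_e (2 - O_m) + 2)``,
      spanning 1 (monogamy, no overlap) down to 2/3 (monogamy, full
      overlap) and saturating at 2 under extreme polyandry;
    * diploids: ``B_min = 2 m_e / (m_e + 1)``, independent of overlap;
    * serial monogamy: ``B_min = 2`` (half-sibling broods), independent of
      overlap and ploidy.
    """
    if not 0.0 <= O_m <= 1.0:
        raise SelectionError(f"O_m out of [0,1]: {O_m!r}")
    if m_e < 1.0:
        raise SelectionError(f"m_e < 1: {m_e!r}")
    if Mating(mating) is Mating.SERIAL_MONOGAMY:
        return 2.0
    if Ploidy(ploidy) is Ploidy.DIPLOID:
        return 2.0 * m_e / (m_e + 1.0)
    x = 2.0 - O_m
    return 2.0 * m_e * x / (m_e * x + 2.0)
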