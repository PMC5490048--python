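"""Demographic transition matrices and stable class structure.

The annual cycle is split into a spring generation and a summer generation.
For the female-hibernation (FH) cycle we track seven classes::

    1  overwintered mated foundresses          (spring)
    2  sperm stored by the foundresses         (spring)
    3  spring-born daughters breeding solitarily (summer)
    4  spring-born daughters helping their mother (summer)
    5  foundresses surviving to breed again    (summer)
    6  the sperm those survivors still carry   (summer)
    7  spring-born males                       (summer)

For the larval-diapause (LD) cycle both sexes overwinter and the summer
male pool mixes new sons with surviving overwintered males, giving eight
classes: 1 overwintered females, 2 overwintered males, 3/4 non-helping and
helping spring-born daughters, 5 surviving spring females, 6 their stored
sperm, 7 spring-born sons, 8 overwintered males surviving into summer.

Spring-to-summer transitions are collected in ``M1``, summer-to-spring
transitions in ``M2``; the annual block matrix ``D`` combines both, and
winter survival is scaled by a factor ``alpha`` so that the dominant
eigenvalue of ``D`` is exactly one (a stationary population). Sperm
columns contain only zeroes: offspring are counted through their mothers
to prevent double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LifeCycle, Mating, ModelConfig, TraitState, validate_config

# 0-based indices of the conventional 1-based class numbers used in docs.
FOUNDRESS, SPERM_SPRING, SOLITARY_DAUGHTER, HELPER, SURVIVOR, SPERM_SUMMER, SPRING_MALE = range(7)
LD_OVERWINTER_MALE = 1  # class 2 in the LD cycle is a male class, not sperm
LD_SURVIVING_MALE = 7  # class 8: overwintered males surviving into summer

N_CLASSES = {LifeCycle.FH: 7, LifeCycle.LD: 8}
SPRING_CLASSES = {LifeCycle.FH: 2, LifeCycle.LD: 2}


class DemographyError(RuntimeError):
    pass


@dataclass(frozen=True)
class HelperEffect:
    """Expected helpers per surviving foundress and the resulting fecundity.

    ``n_helpers = h (1 - z1) F1`` is the expected number of daughters that
    stay to help; the surviving mother's summer fecundity rises linearly,
    ``F5 = F1 (1 + b n_helpers)``. ``B = S_f b`` is the expected benefit a
    helper provides per maternal offspring at the moment of the helping
    decision, conditional on her mother surviving to breed again.
    """

    n_helpers: float
    F5: float
    B: float


@dataclass(frozen=True)
class DemographicState:
    """Stable class structure of a resident population at equilibrium."""

    config: ModelConfig
    traits: TraitState
    u: np.ndarray  # per-class frequencies, u[0] = 1
    Q1: float  # mates per male: autumn pool (FH) / spring males (LD)
    Q2: float  # mates per male in the summer mating pool
    alpha: float  # winter-survival scaling enforcing lambda(D) = 1
    F_A: float  # total autumn offspring per spring foundress
    F5: float  # helper-boosted fecundity of surviving foundresses
    M1: np.ndarray
    M2: np.ndarray
    D: np.ndarray
    unmated: bool  # True when receptive females face an empty male pool

    @property
    def n_classes(self) -> int:
        return self.u.size


def helper_effect(config: ModelConfig, traits: TraitState) -> HelperEffect:
    """Expected helper number, boosted fecundity and helper benefit ``B``."""
    n_helpers = traits.h * (1.0 - traits.z1) * config.F1
    F5 = config.F1 * (1.0 + config.b * n_helpers)
    return HelperEffect(n_helpers=n_helpers, F5=F5, B=config.S_f * config.b)


def _class_frequencies(config: ModelConfig, traits: TraitState) -> np.ndarray:
    """Closed-form stable class frequencies with u[class 1] = 1.

    Obtained by forward bookkeeping of a foundress cohort: each class is a
    fixed per-foundress multiple of the class-1 frequency, and winter
    scaling returns the population to its spring size.
    """
    F1, S_f, S_m = config.F1, config.S_f, config.S_m
    z1, z2, h = traits.z1, traits.z2, traits.h
    u3 = F1 * (1.0 - z1) * (1.0 - h)
    u4 = F1 * (1.0 - z1) * h
    u5 = S_f
    u6 = 0.0 if config.mating is Mating.SERIAL_MONOGAMY else S_f
    u7 = F1 * z1
    if config.life_cycle is LifeCycle.FH:
        return np.array([1.0, 1.0, u3, u4, u5, u6, u7])
    # LD: both sexes overwinter with a common scaling, so the overwintered
    # male-to-female ratio equals the autumn brood sex ratio z2/(1-z2).
    if z2 >= 1.0:
        raise DemographyError("LD cycle requires z2 < 1 (no overwintering females)")
    u2 = z2 / (1.0 - z2)
    return np.array([1.0, u2, u3, u4, u5, u6, u7, S_m * u2])


def build_transition_matrices(
    config: ModelConfig, traits: TraitState
) -> tuple[np.ndarray, np.ndarray]:
    """Spring-to-summer (``M1``) and summer-to-spring (``M2``) matrices.

    Columns index contributing classes, rows receiving classes, in the
    class order listed in the module docstring. ``M2`` already carries the
    winter scaling ``alpha``.
    """
    validate_config(config)
    state = _assemble(config, traits)
    return state.M1, state.M2


def _assemble(config: ModelConfig, traits: TraitState) -> DemographicState:
    F1, F3, S_f, S_m = config.F1, config.F3, config.S_f, config.S_m
    z1, z2, h = traits.z1, traits.z2, traits.h
    eff = helper_effect(config, traits)
    F5 = eff.F5
    u = _class_frequencies(config, traits)
    n = u.size
    n_spring = SPRING_CLASSES[config.life_cycle]
    n_summer = n - n_spring

    u3, u5, u7 = u[SOLITARY_DAUGHTER], u[SURVIVOR], u[SPRING_MALE]
    F_A = F3 * u3 + F5 * u5
    if F_A * (1.0 - z2) <= 0.0:
        raise DemographyError(
            "no overwintering daughters are produced (F_A*(1-z2) = 0); "
            "the population cannot replace itself"
        )
    alpha = 1.0 / (F_A * (1.0 - z2))

    unmated = False
    if config.life_cycle is LifeCycle.FH:
        autumn_males = F_A * z2 + S_m * u7
        if autumn_males > 0.0:
            Q1 = F_A * (1.0 - z2) / autumn_males
        else:
            Q1 = 0.0
            unmated = unmated or F_A * (1.0 - z2) > 0.0
        if config.mating is Mating.SERIAL_MONOGAMY:
            receptive = u3 + u5
        else:
            receptive = u3
        if u7 > 0.0:
            Q2 = receptive / u7
        else:
            Q2 = 0.0
            unmated = unmated or receptive > 0.0
    else:
        u2, u8 = u[LD_OVERWINTER_MALE], u[LD_SURVIVING_MALE]
        Q1 = 1.0 / u2 if u2 > 0.0 else 0.0
        if u2 == 0.0:
            unmated = True  # spring females with no overwintered males
        pool = u7 + u8
        if pool > 0.0:
            Q2 = u3 / pool
        else:
            Q2 = 0.0
            unmated = unmated or u3 > 0.0

    M1 = np.zeros((n_summer, n_spring))
    M1[SOLITARY_DAUGHTER - n_spring, 0] = F1 * (1.0 - z1) * (1.0 - h)
    M1[HELPER - n_spring, 0] = F1 * (1.0 - z1) * h
    M1[SURVIVOR - n_spring, 0] = S_f
    if config.mating is not Mating.SERIAL_MONOGAMY:
        M1[SPERM_SUMMER - n_spring, 0] = S_f
    M1[SPRING_MALE - n_spring, 0] = F1 * z1
    if config.life_cycle is LifeCycle.LD:
        M1[LD_SURVIVING_MALE - n_spring, 1] = S_m

    M2 = np.zeros((n_spring, n_summer))
    M2[0, SOLITARY_DAUGHTER - n_spring] = alpha * F3 * (1.0 - z2)
    M2[0, SURVIVOR - n_spring] = alpha * F5 * (1.0 - z2)
    if config.life_cycle is LifeCycle.FH:
        # each overwintering daughter carries exactly one stored ejaculate
        M2[1, :] = M2[0, :]
    else:
        M2[1, SOLITARY_DAUGHTER - n_spring] = alpha * F3 * z2
        M2[1, SURVIVOR - n_spring] = alpha * F5 * z2

    D = np.zeros((n, n))
    D[:n_spring, n_spring:] = M2
    D[n_spring:, :n_spring] = M1

    return DemographicState(
        config=config,
        traits=traits,
        u=u,
        Q1=Q1,
        Q2=Q2,
        alpha=alpha,
        F_A=F_A,
        F5=F5,
        M1=M1,
        M2=M2,
        D=D,
        unmated=unmated,
    )


def stable_class_distribution(
    config: ModelConfig, traits: TraitState, check: bool = True
) -> DemographicState:
    """Stable class structure, mate counts and winter scaling.

    The frequencies come from closed-form cohort bookkeeping; with
    ``check=True`` they are verified against the dominant right eigenvector
    of the annual matrix ``D`` (relative tolerance 1e-8) and the dominant
    eigenvalue is required to equal 1 to within 1e-10.
    """
    validate_config(config)
    state = _assemble(config, traits)
    if check:
        lam, u_eig = dominant_right_eigenpair(state.D)
        if abs(lam - 1.0) > 1e-10:
            raise DemographyError(f"dominant eigenvalue {lam!r} != 1 after scaling")
        u_ext = _stacked_u(state)
        u_eig = u_eig / u_eig[FOUNDRESS]
        if not np.allclose(u_eig, u_ext, rtol=1e-8, atol=1e-12):
            raise DemographyError(
                "closed-form class frequencies disagree with the eigenvector: "
                f"{u_ext} vs {u_eig}"
            )
    return state


def _stacked_u(state: DemographicState) -> np.ndarray:
    """The stacked spring+summer class vector fixed by D (u1 = 1)."""
    return state.u.copy()


def dominant_right_eigenpair(D: np.ndarray) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and nonnegative right eigenvector of ``D``."""
    vals, vecs = np.linalg.eig(D)
    # D is block-cyclic, so -r accompanies the Perron root r; the Perron
    # root is the eigenvalue with the largest real part.
    k = int(np.argmax(vals.real))
    lam = vals[k]
    if abs(lam.imag) > 1e-12:
        raise DemographyError(f"dominant eigenvalue is complex: {lam!r}")
    vec = vecs[:, k].real
    # the Perron vector of a nonnegative matrix can be flipped in sign
    if vec.sum() < 0:
        vec = -vec
    vec[np.abs(vec) < 1e-14] = np.abs(vec[np.abs(vec) < 1e-14])
    return float(lam.real), vec


def male_mate_counts(
    state: DemographicState,
) -> tuple[float, float]:
    """Mean mates per male for the two mating episodes (``Q1``, ``Q2``)."""
    return state.Q1, state.Q2


def generation_overlap(state: DemographicState) -> tuple[float, float]:
    """Operational generation-overlap measures ``(O_m, O_f)``.

    ``O_m`` is the paternity share of the earlier male brood in the later
    mating pool: for FH, spring males surviving at rate ``S_m`` within the
    autumn pool; for LD, overwintered males surviving into the summer pool.
    ``O_f`` (LD only; 0 for FH) is the analogous maternity share of
    surviving spring females in the autumn brood.
    """
    cfg, traits = state.config, state.traits
    u = state.u
    if cfg.life_cycle is LifeCycle.FH:
        survivors = cfg.S_m * u[SPRING_MALE]
        pool = state.F_A * traits.z2 + survivors
        O_m = survivors / pool if pool > 0.0 else 0.0
        O_f = 0.0
    else:
        survivors = u[LD_SURVIVING_MALE]
        pool = u[SPRING_MALE] + survivors
        O_m = survivors / pool if pool > 0.0 else 0.0
        O_f = state.F5 * u[SURVIVOR] / state.F_A if state.F_A > 0.0 else 0.0
    return float(O_m), float(O_f)
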