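"""Gene-flow matrices and class-specific reproductive values.

The gene-flow matrix ``A`` has the block structure of the demographic
matrix ``D`` but distributes each new or surviving individual's genes over
the classes that contributed them: survivors credit 100% to themselves;
under haplodiploidy a mother gets 100% credit for sons while mother and
father each get 50% credit for daughters; under diploidy both parents get
50% credit for offspring of either sex. Columns of male (or sperm) classes
are scaled by the mean number of mates per male, since each male's genetic
output runs through all the females he mated.

The dominant left eigenvector of ``A`` (eigenvalue 1 at demographic
equilibrium) holds the class-specific individual reproductive values (RVs).
Brood-level RVs are reported with the summer-born daughter normalized to
one; helpers forgo reproduction and therefore carry zero individual RV,
their effect entering only through their mother's boosted fecundity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import LifeCycle, Mating, ModelConfig, Ploidy, TraitState
from .demography import (
    FOUNDRESS,
    HELPER,
    LD_OVERWINTER_MALE,
    LD_SURVIVING_MALE,
    SOLITARY_DAUGHTER,
    SPERM_SPRING,
    SPERM_SUMMER,
    SPRING_MALE,
    SURVIVOR,
    DemographicState,
    generation_overlap,
    stable_class_distribution,
)


class ReproductiveValueError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReproductiveValues:
    """Class-specific and brood-level reproductive values.

    ``v`` is indexed like the class vector ``u``; ``v_f2`` is 1 by
    normalization. ``O_m`` (and ``O_f`` for the LD cycle) are the
    generation-overlap measures of the underlying demographic state.
    """

    v: np.ndarray
    v_f1: float
    v_m1: float
    v_f2: float
    v_m2: float
    O_m: float
    O_f: float


def build_gene_flow_matrix(
    config: ModelConfig, traits: TraitState, state: DemographicState | None = None
) -> np.ndarray:
    """Assemble the gene-flow matrix ``A`` for the scenario.

    ``A[i, j]`` is the expected per-capita genetic credit flowing from
    class ``j`` to class ``i`` over one generation step.
    """
    if state is None:
        state = stable_class_distribution(config, traits, check=False)
    F1, F3, S_f, S_m = config.F1, config.F3, config.S_f, config.S_m
    z1, z2, h = traits.z1, traits.z2, traits.h
    F5, alpha, Q1, Q2 = state.F5, state.alpha, state.Q1, state.Q2
    haplo = config.ploidy is Ploidy.HAPLODIPLOID
    n = state.u.size
    A = np.zeros((n, n))

    if config.life_cycle is LifeCycle.FH:
        # --- spring -> summer ---
        dau = 0.5 * F1 * (1.0 - z1)
        A[SOLITARY_DAUGHTER, FOUNDRESS] = dau * (1.0 - h)
        A[SOLITARY_DAUGHTER, SPERM_SPRING] = dau * (1.0 - h)
        A[HELPER, FOUNDRESS] = dau * h
        A[HELPER, SPERM_SPRING] = dau * h
        A[SURVIVOR, FOUNDRESS] = S_f
        if config.mating is not Mating.SERIAL_MONOGAMY:
            A[SPERM_SUMMER, SPERM_SPRING] = S_f
        if haplo:
            A[SPRING_MALE, FOUNDRESS] = F1 * z1
        else:
            A[SPRING_MALE, FOUNDRESS] = 0.5 * F1 * z1
            A[SPRING_MALE, SPERM_SPRING] = 0.5 * F1 * z1

        # --- summer -> spring: autumn daughters (next foundresses) ---
        A[FOUNDRESS, SOLITARY_DAUGHTER] = 0.5 * alpha * F3 * (1.0 - z2)
        A[FOUNDRESS, SURVIVOR] = 0.5 * alpha * F5 * (1.0 - z2)
        if config.mating is Mating.SERIAL_MONOGAMY:
            # a surviving foundress re-mates with a spring male, so spring
            # males father both broods of autumn offspring
            per_male = state.F_A / state.u[SPRING_MALE]
            A[FOUNDRESS, SPRING_MALE] = 0.5 * alpha * (1.0 - z2) * per_male
        else:
            A[FOUNDRESS, SPERM_SUMMER] = 0.5 * alpha * F5 * (1.0 - z2)
            A[FOUNDRESS, SPRING_MALE] = 0.5 * alpha * F3 * (1.0 - z2) * Q2

        # --- summer -> spring: sperm stored by next foundresses ---
        # Autumn sons mate Q1 times; surviving spring males join the autumn
        # pool directly. Son credit is maternal only under haplodiploidy.
        son_credit = 1.0 if haplo else 0.5
        A[SPERM_SPRING, SOLITARY_DAUGHTER] = son_credit * alpha * F3 * z2 * Q1
        A[SPERM_SPRING, SURVIVOR] = son_credit * alpha * F5 * z2 * Q1
        father_term = 0.0
        if not haplo:
            if config.mating is Mating.SERIAL_MONOGAMY:
                per_male = state.F_A / state.u[SPRING_MALE]
                father_term = 0.5 * alpha * z2 * per_male * Q1
            else:
                A[SPERM_SPRING, SPERM_SUMMER] = 0.5 * alpha * F5 * z2 * Q1
                father_term = 0.5 * alpha * F3 * z2 * Q2 * Q1
        A[SPERM_SPRING, SPRING_MALE] = alpha * S_m * Q1 + father_term
        return A

    # ---------------- LD ----------------
    dau = 0.5 * F1 * (1.0 - z1)
    A[SOLITARY_DAUGHTER, FOUNDRESS] = dau * (1.0 - h)
    A[SOLITARY_DAUGHTER, LD_OVERWINTER_MALE] = dau * (1.0 - h) * Q1
    A[HELPER, FOUNDRESS] = dau * h
    A[HELPER, LD_OVERWINTER_MALE] = dau * h * Q1
    A[SURVIVOR, FOUNDRESS] = S_f
    A[SPERM_SUMMER, LD_OVERWINTER_MALE] = S_f * Q1
    if haplo:
        A[SPRING_MALE, FOUNDRESS] = F1 * z1
    else:
        A[SPRING_MALE, FOUNDRESS] = 0.5 * F1 * z1
        A[SPRING_MALE, LD_OVERWINTER_MALE] = 0.5 * F1 * z1 * Q1
    A[LD_SURVIVING_MALE, LD_OVERWINTER_MALE] = S_m

    A[FOUNDRESS, SOLITARY_DAUGHTER] = 0.5 * alpha * F3 * (1.0 - z2)
    A[FOUNDRESS, SURVIVOR] = 0.5 * alpha * F5 * (1.0 - z2)
    A[FOUNDRESS, SPERM_SUMMER] = 0.5 * alpha * F5 * (1.0 - z2)
    A[FOUNDRESS, SPRING_MALE] = 0.5 * alpha * F3 * (1.0 - z2) * Q2
    A[FOUNDRESS, LD_SURVIVING_MALE] = 0.5 * alpha * F3 * (1.0 - z2) * Q2

    if haplo:
        A[LD_OVERWINTER_MALE, SOLITARY_DAUGHTER] = alpha * F3 * z2
        A[LD_OVERWINTER_MALE, SURVIVOR] = alpha * F5 * z2
    else:
        A[LD_OVERWINTER_MALE, SOLITARY_DAUGHTER] = 0.5 * alpha * F3 * z2
        A[LD_OVERWINTER_MALE, SURVIVOR] = 0.5 * alpha * F5 * z2
        A[LD_OVERWINTER_MALE, SPERM_SUMMER] = 0.5 * alpha * F5 * z2
        A[LD_OVERWINTER_MALE, SPRING_MALE] = 0.5 * alpha * F3 * z2 * Q2
        A[LD_OVERWINTER_MALE, LD_SURVIVING_MALE] = 0.5 * alpha * F3 * z2 * Q2
    return A


def class_reproductive_values(A: np.ndarray) -> np.ndarray:
    """Dominant left eigenvector of ``A`` (unnormalized, nonnegative)."""
    vals, vecs = np.linalg.eig(A.T)
    k = int(np.argmax(vals.real))
    lam = vals[k]
    if abs(lam.imag) > 1e-12:
        raise ReproductiveValueError(f"dominant eigenvalue is complex: {lam!r}")
    if abs(lam.real - 1.0) > 1e-8:
        raise ReproductiveValueError(
            f"gene-flow matrix eigenvalue {lam.real!r} != 1; "
            "was it built at demographic equilibrium?"
        )
    v = vecs[:, k].real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9):
        raise ReproductiveValueError("left eigenvector is not sign-definite")
    return np.clip(v, 0.0, None)


def reproductive_values(
    config: ModelConfig,
    traits: TraitState,
    state: DemographicState | None = None,
    boundary_eps: float = 1e-9,
) -> ReproductiveValues:
    """Class and brood reproductive values with ``v_f2 = 1``.

    Trait values sitting exactly on a boundary that would empty a class
    (e.g. ``z1 = 0`` removing spring males) are nudged inward by
    ``boundary_eps`` so all RVs are defined by their continuous limits.
    """
    z1 = min(max(traits.z1, boundary_eps), 1.0 - boundary_eps)
    z2 = min(max(traits.z2, boundary_eps), 1.0 - boundary_eps)
    h = min(max(traits.h, 0.0), 1.0 - boundary_eps)
    traits_in = TraitState(z1=z1, z2=z2, h=h)
    if state is None or traits_in != traits:
        state = stable_class_distribution(config, traits_in, check=False)
    A = build_gene_flow_matrix(config, traits_in, state)
    v = class_reproductive_values(A)

    alpha, Q1 = state.alpha, state.Q1
    scale = alpha * v[FOUNDRESS]
    if scale <= 0.0:
        raise ReproductiveValueError("foundress RV vanished; degenerate scenario")
    v = v / scale
    v_f2 = 1.0
    if config.life_cycle is LifeCycle.FH:
        # an autumn son's genetic future is the sperm he leaves in his Q1
        # mates, each overwintering with probability alpha
        v_m2 = alpha * Q1 * v[SPERM_SPRING]
    else:
        v_m2 = alpha * v[LD_OVERWINTER_MALE]
    v_f1 = (1.0 - h) * v[SOLITARY_DAUGHTER] + h * v[HELPER]
    v_m1 = v[SPRING_MALE]
    O_m, O_f = generation_overlap(state)
    return ReproductiveValues(
        v=v, v_f1=float(v_f1), v_m1=float(v_m1), v_f2=v_f2, v_m2=float(v_m2),
        O_m=O_m, O_f=O_f,
    )
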