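"""Independent oracles used by the test suite.

These re-derive expected results from first principles through code paths
that share nothing with the implementation they check: stable class
structure by brute-force iteration of the annual matrix, mate counts by
explicit head counts, and reproductive values by an allele-descent
bookkeeping recursion that follows each mating and transmission event of
the life cycle.
"""

from __future__ import annotations

import numpy as np

from eusocia.config import LifeCycle, Mating, ModelConfig, Ploidy, TraitState


def iterate_to_stationarity(D: np.ndarray, n_iter: int = 10_000, seed: int = 0) -> np.ndarray:
    """Stable structure by applying ``D`` to a random positive vector."""
    rng = np.random.default_rng(seed)
    x = rng.random(D.shape[0]) + 0.5
    for _ in range(n_iter):
        x = D @ x
        s = x.sum()
        if s == 0:
            raise RuntimeError("population vector collapsed to zero")
        x = x / s
    # the annual matrix is block-cyclic (spring <-> summer), so successive
    # iterates alternate phase; averaging two consecutive iterates removes
    # the period-2 component and leaves the stationary structure
    x = x + D @ x
    return x / x.sum()


def cohort_head_counts(config: ModelConfig, traits: TraitState) -> dict:
    """Mate counts per male from explicit cohort bookkeeping (FH only)."""
    F1, F3, S_f, S_m, b = config.F1, config.F3, config.S_f, config.S_m, config.b
    z1, z2, h = traits.z1, traits.z2, traits.h
    foundresses = 1.0
    spring_daughters_breeding = foundresses * F1 * (1 - z1) * (1 - h)
    spring_daughters_helping = foundresses * F1 * (1 - z1) * h
    spring_sons = foundresses * F1 * z1
    survivors = foundresses * S_f
    helpers_per_survivor = F1 * (1 - z1) * h
    F5 = F1 * (1 + b * helpers_per_survivor)
    autumn_offspring = F3 * spring_daughters_breeding + F5 * survivors
    autumn_females = autumn_offspring * (1 - z2)
    autumn_males = autumn_offspring * z2 + S_m * spring_sons
    return {
        "Q1": autumn_females / autumn_males,
        "Q2": spring_daughters_breeding / spring_sons,
        "helpers": spring_daughters_helping,
        "F5": F5,
    }


class _DescentBookkeeper:
    """Expected allele-descent fractions through the life-cycle events.

    ``p[c]`` is the expected fraction of a class-c individual's genome
    descending from the focal gene copies. ``spring`` rebuilds the summer
    classes from the spring ones (reproduction, survival); ``winter``
    rebuilds the next spring classes from the summer ones (late-season
    mating and overwintering). Haplodiploid sons carry a single maternal
    gamete; daughters average a maternal and a paternal gamete.
    """

    def __init__(self, cfg: ModelConfig, tr: TraitState):
        self.cfg, self.tr = cfg, tr
        self.haplo = cfg.ploidy is Ploidy.HAPLODIPLOID
        F1, b = cfg.F1, cfg.b
        z1, h = tr.z1, tr.h
        self.n3 = F1 * (1 - z1) * (1 - h)
        self.n5 = cfg.S_f
        self.n7 = F1 * z1
        self.F5 = F1 * (1 + b * h * (1 - z1) * F1)

    def _offspring(self, p_mother: float, p_father: float) -> tuple[float, float]:
        dau = 0.5 * p_mother + 0.5 * p_father
        son = p_mother if self.haplo else dau
        return dau, son

    def spring(self, p: np.ndarray) -> np.ndarray:
        cfg, tr = self.cfg, self.tr
        q = p.copy()
        if cfg.life_cycle is LifeCycle.FH:
            p1, p2 = p[0], p[1]
            dau, son = self._offspring(p1, p2)
            q[2] = q[3] = dau
            q[4], q[5], q[6] = p1, p2, son
        else:
            # LD: overwintered females each take a random overwintered male
            p1, p_sperm = p[0], p[1]
            dau, son = self._offspring(p1, p_sperm)
            q[2] = q[3] = dau
            q[4], q[5], q[6] = p1, p_sperm, son
            q[7] = p[1]  # overwintered males surviving into summer
        return q

    def winter(self, p: np.ndarray) -> np.ndarray:
        cfg, tr = self.cfg, self.tr
        F3, S_m, z2 = cfg.F3, cfg.S_m, tr.z2
        q = p.copy()
        p3, p5, p6, p7 = p[2], p[4], p[5], p[6]
        if cfg.life_cycle is LifeCycle.FH:
            father3 = p7  # class-3 females mate spring males
            # survivors reuse stored sperm unless it is not kept between broods
            father5 = p7 if cfg.mating is Mating.SERIAL_MONOGAMY else p6
        else:
            p8 = p[7]
            pool = self.n7 + S_m * (z2 / (1 - z2))
            father3 = (self.n7 * p7 + S_m * (z2 / (1 - z2)) * p8) / pool
            father5 = p6
        dau3, son3 = self._offspring(p3, father3)
        dau5, son5 = self._offspring(p5, father5)
        w3, w5 = F3 * self.n3, self.F5 * self.n5
        q[0] = (w3 * dau3 + w5 * dau5) / (w3 + w5)
        if cfg.life_cycle is LifeCycle.FH:
            # stored sperm of a next-spring foundress: a random male from the
            # autumn pool (new sons plus surviving spring males)
            m3, m5, m_old = w3 * z2, w5 * z2, S_m * self.n7
            q[1] = (m3 * son3 + m5 * son5 + m_old * p7) / (m3 + m5 + m_old)
        else:
            # overwintering males: a random autumn son
            q[1] = (w3 * son3 + w5 * son5) / (w3 + w5)
        return q


def descent_reproductive_values(
    config: ModelConfig, traits: TraitState, years: int = 10_000
) -> np.ndarray:
    """Relative individual RVs from long-run allele-descent bookkeeping.

    For each class, inject one focal-derived genome per individual of that
    class and follow the expected descent fraction through every mating
    and transmission event for ``years`` years. The common limiting
    fraction is proportional to (class frequency) x (individual RV), so
    dividing by the class frequency recovers relative RVs.
    """
    from eusocia.demography import SPRING_CLASSES, stable_class_distribution

    book = _DescentBookkeeper(config, traits)
    state = stable_class_distribution(config, traits, check=False)
    u = state.u
    n = u.size
    n_spring = SPRING_CLASSES[config.life_cycle]
    out = np.zeros(n)
    for k in range(n):
        p = np.zeros(n)
        p[k] = 1.0
        if k >= n_spring:
            p = book.winter(p)  # summer-class injections face winter first
        for _ in range(years):
            p = book.winter(book.spring(p))
        p = book.spring(p)  # refresh summer classes before reading the mix
        if np.ptp(p) > 1e-8 * max(p.max(), 1e-300):
            raise RuntimeError(f"descent fractions did not mix: {p}")
        out[k] = p.mean() / u[k] if u[k] > 0 else 0.0
    return out
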