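"""Stochastic individual-based simulation of the annual life cycle.

Each individual carries three continuous-allele loci controlling the
spring sex ratio ``z1``, the summer sex ratio ``z2`` and the helping
tendency ``h``; traits are expressed in codominance (the phenotype is the
mean of the carried alleles). Females are diploid; males are haploid under
haplodiploidy (developing from unfertilized eggs) and diploid otherwise.
Sex-ratio loci are expressed only by reproducing females, the helping
locus by spring-born daughters.

One simulated year runs: spring reproduction (Poisson offspring numbers),
helper recruitment, spring mating, maternal survival, helper-boosted
summer reproduction, late-season mating with the surviving overlapping
male brood in the pool, and density-dependent overwintering that restores
exactly ``N`` breeding females. Alleles mutate with probability ``mu`` per
transmitted gamete by a Normal(0, sigma) step clipped to [0,1];
helping-locus mutation is disabled before a release year so the sex
ratios can equilibrate first.

Mating systems: under lifetime monogamy a female stores one ejaculate for
life; under polyandry she stores the ejaculates of ``ceil(m_e)`` distinct
males with paternity shares whose squares sum to ``1/m_e``; under serial
monogamy (FH only) a surviving foundress discards her sperm and takes a
new single mate from the summer male pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LifeCycle, Mating, ModelConfig, Ploidy, validate_config

Z1, Z2, H = 0, 1, 2  # locus order


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationSettings:
    """Individual-based run controls.

    Defaults follow the reference setup: 5,000 nests, mutation rate and
    mutational step s.d. both 0.01, 25,000 years with helping mutations
    released at year 10,000.
    """

    N: int = 5000
    mu: float = 0.01
    sigma: float = 0.01
    T_years: int = 25000
    h_mutation_start: int = 10000
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise SimulationError(f"N must be >= 2, got {self.N}")


def paternity_shares(m_e: float) -> np.ndarray:
    """Paternity shares over ``ceil(m_e)`` mates with sum-of-squares 1/m_e.

    ``k - 1`` equal minor shares and one major share solve the two moment
    constraints; for integer ``m_e`` all shares are equal.
    """
    if m_e < 1.0:
        raise SimulationError(f"m_e < 1: {m_e!r}")
    k = max(1, math.ceil(m_e - 1e-12))
    if k == 1:
        return np.array([1.0])
    s = 1.0 / m_e
    disc = 1.0 - k * (1.0 - s) / (k - 1.0)
    disc = max(disc, 0.0)
    a = (1.0 - math.sqrt(disc)) / k
    x = 1.0 - (k - 1) * a
    return np.array([x] + [a] * (k - 1))


@dataclass
class Population:
    """Spring breeding females, their stored sperm, and (LD) the male pool.

    ``genomes``: (n, 3, 2) female allele pairs. ``sperm``: stored
    ejaculates, shape (n, k, 3) under haplodiploidy or (n, k, 3, 2) under
    diploidy, with per-mate paternity ``shares`` (n, k); ``k`` is 1 except
    under polyandry. LD females start the year unmated (``sperm is
    None``) and ``males`` holds the overwintered male cohort.
    """

    genomes: np.ndarray
    sperm: np.ndarray | None
    shares: np.ndarray | None
    ploidy: Ploidy
    males: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.genomes.shape[0]

    def phenotypes(self) -> np.ndarray:
        """Expressed trait values of the breeding females, shape (n, 3)."""
        return self.genomes.mean(axis=2)


@dataclass
class YearlyRecord:
    year: int
    z1_mean: float
    z1_sd: float
    z2_mean: float
    z2_sd: float
    h_mean: float
    h_sd: float
    n_foundresses: int
    n_helpers: int
    n_spring_males: int
    n_autumn_offspring: int
    extinct: bool = False


def _blank_males(n: int, ploidy: Ploidy, fill: np.ndarray) -> np.ndarray:
    if ploidy is Ploidy.HAPLODIPLOID:
        return np.tile(fill[None, :], (n, 1))
    return np.tile(fill[None, :, None], (n, 1, 2))


def initialize_population(
    settings: SimulationSettings, config: ModelConfig
) -> Population:
    """All sex-ratio alleles start at 0.5, all helping alleles at 0."""
    validate_config(config)
    init = np.array([0.5, 0.5, 0.0])
    n = settings.N
    genomes = np.tile(init[None, :, None], (n, 1, 2))
    if config.life_cycle is LifeCycle.LD:
        return Population(
            genomes=genomes, sperm=None, shares=None, ploidy=config.ploidy,
            males=_blank_males(n, config.ploidy, init),
        )
    shares = paternity_shares(
        config.m_e if config.mating is Mating.POLYANDRY else 1.0
    )
    k = shares.size
    sperm = np.repeat(_blank_males(n, config.ploidy, init)[:, None], k, axis=1)
    return Population(
        genomes=genomes, sperm=sperm,
        shares=np.tile(shares, (n, 1)), ploidy=config.ploidy,
    )


def mutate_alleles(
    values: np.ndarray, mu: float, sigma: float, rng: np.random.Generator,
    frozen_h: bool = False,
) -> np.ndarray:
    """Per-allele mutation of a gamete array (axis 1 indexes loci).

    Each allele mutates with probability ``mu``; a mutation adds a
    Normal(0, sigma) deviate, clipped to [0,1]. ``frozen_h`` masks the
    helping locus.
    """
    if mu <= 0.0 or values.size == 0:
        return values
    out = values.copy()
    hits = rng.random(values.shape) < mu
    if frozen_h:
        hits[:, H, ...] = False
    n_hits = int(hits.sum())
    if n_hits:
        out[hits] = np.clip(out[hits] + rng.normal(0.0, sigma, n_hits), 0.0, 1.0)
    return out


def mutate_allele(
    value: float, mu: float, sigma: float, rng: np.random.Generator
) -> float:
    """Scalar form of :func:`mutate_alleles` (single allele, single locus)."""
    if rng.random() < mu:
        return float(np.clip(value + rng.normal(0.0, sigma), 0.0, 1.0))
    return float(value)


def _maternal_gametes(genomes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One meiotic gamete per row of an (n, 3, 2) genome array."""
    picks = rng.integers(0, 2, size=genomes.shape[:2])
    return np.take_along_axis(genomes, picks[:, :, None], axis=2)[:, :, 0]


def _paternal_gametes(
    sperm: np.ndarray,
    shares: np.ndarray,
    mothers: np.ndarray,
    ploidy: Ploidy,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per offspring, drawing each father by paternity share."""
    n_off = mothers.size
    sh = shares[mothers]
    cum = np.cumsum(sh, axis=1)
    father = (rng.random(n_off)[:, None] > cum).sum(axis=1)
    father = np.minimum(father, sh.shape[1] - 1)
    ej = sperm[mothers, father]
    if ploidy is Ploidy.HAPLODIPLOID:
        return ej.copy()
    return _maternal_gametes(ej, rng)


@dataclass
class _Brood:
    fem_genomes: np.ndarray  # (nf, 3, 2)
    fem_mothers: np.ndarray  # index of each daughter's mother
    male_genomes: np.ndarray  # (nm, 3) haploid or (nm, 3, 2) diploid


def _reproduce(
    genomes: np.ndarray,
    sperm: np.ndarray,
    shares: np.ndarray,
    fecundity: np.ndarray,
    z_expr: np.ndarray,
    ploidy: Ploidy,
    mu: float,
    sigma: float,
    frozen_h: bool,
    rng: np.random.Generator,
) -> _Brood:
    """One brood from mated mothers: Poisson(``fecundity``) offspring each,
    sons with probability ``z_expr``; every transmitted gamete mutates
    independently."""
    haplo = ploidy is Ploidy.HAPLODIPLOID
    counts = rng.poisson(fecundity)
    mothers = np.repeat(np.arange(genomes.shape[0]), counts)
    n_off = mothers.size
    empty_m = np.empty((0, 3)) if haplo else np.empty((0, 3, 2))
    if n_off == 0:
        return _Brood(np.empty((0, 3, 2)), mothers, empty_m)
    is_male = rng.random(n_off) < np.repeat(z_expr, counts)

    mat = _maternal_gametes(genomes[mothers], rng)
    mat = mutate_alleles(mat, mu, sigma, rng, frozen_h)

    mothers_f = mothers[~is_male]
    pat = _paternal_gametes(sperm, shares, mothers_f, ploidy, rng)
    pat = mutate_alleles(pat, mu, sigma, rng, frozen_h)
    fem = np.stack([mat[~is_male], pat], axis=2)

    if haplo:
        males = mat[is_male]
    else:
        pat_m = _paternal_gametes(sperm, shares, mothers[is_male], ploidy, rng)
        pat_m = mutate_alleles(pat_m, mu, sigma, rng, frozen_h)
        males = np.stack([mat[is_male], pat_m], axis=2)
    return _Brood(fem, mothers_f, males)


def _draw_mates(
    n_females: int,
    pool: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_females, k) indices into ``pool``; the k mates of a female are
    distinct whenever the pool allows it."""
    M = pool.shape[0]
    idx = rng.integers(0, M, (n_females, k))
    if k > 1 and M > k:
        for _ in range(20):  # resample colliding mates
            srt = np.sort(idx, axis=1)
            dup_rows = (np.diff(srt, axis=1) == 0).any(axis=1)
            if not dup_rows.any():
                break
            idx[dup_rows] = rng.integers(0, M, (int(dup_rows.sum()), k))
    return idx


def _store_matings(
    n_females: int,
    pool: np.ndarray,
    shares: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Each female stores the ejaculates of her mates drawn from ``pool``."""
    k = shares.size
    idx = _draw_mates(n_females, pool, k, rng)
    return pool[idx], np.tile(shares, (n_females, 1))


def run_year(
    population: Population,
    config: ModelConfig,
    settings: SimulationSettings,
    rng: np.random.Generator,
    year: int = 0,
) -> tuple[Population | None, YearlyRecord]:
    """Advance the population one year.

    Returns the next spring population (``None`` on extinction) and the
    yearly record of foundress trait statistics and cohort sizes.
    """
    haplo = config.ploidy is Ploidy.HAPLODIPLOID
    ld = config.life_cycle is LifeCycle.LD
    serial = config.mating is Mating.SERIAL_MONOGAMY
    frozen_h = year < settings.h_mutation_start
    mu, sigma = settings.mu, settings.sigma
    genomes = population.genomes
    n = population.n
    phen = population.phenotypes()
    shares1 = paternity_shares(
        config.m_e if config.mating is Mating.POLYANDRY else 1.0
    )

    record_kwargs = dict(
        year=year,
        z1_mean=float(phen[:, Z1].mean()), z1_sd=float(phen[:, Z1].std()),
        z2_mean=float(phen[:, Z2].mean()), z2_sd=float(phen[:, Z2].std()),
        h_mean=float(phen[:, H].mean()), h_sd=float(phen[:, H].std()),
        n_foundresses=n, n_helpers=0, n_spring_males=0, n_autumn_offspring=0,
    )

    if ld:
        # overwintered females mate at the start of spring
        if population.males is None or population.males.shape[0] == 0:
            return None, YearlyRecord(**record_kwargs, extinct=True)
        sperm, shares = _store_matings(n, population.males, shares1, rng)
        winter_males = population.males
    else:
        sperm, shares = population.sperm, population.shares
        winter_males = None

    # --- spring brood ---
    spring = _reproduce(
        genomes, sperm, shares, np.full(n, float(config.F1)), phen[:, Z1],
        population.ploidy, mu, sigma, frozen_h, rng,
    )
    h_expr = spring.fem_genomes.mean(axis=2)[:, H]
    helps = rng.random(h_expr.size) < h_expr
    helpers_per_nest = np.bincount(spring.fem_mothers[helps], minlength=n)
    breeders = spring.fem_genomes[~helps]
    spring_males = spring.male_genomes
    record_kwargs.update(
        n_helpers=int(helps.sum()), n_spring_males=spring_males.shape[0]
    )

    # --- summer mating pool for the new breeding daughters ---
    if ld:
        # spring-born sons plus overwintered males surviving with S_m
        survive_m = rng.random(winter_males.shape[0]) < config.S_m
        summer_pool = np.concatenate([spring_males, winter_males[survive_m]])
    else:
        summer_pool = spring_males
    if summer_pool.shape[0] > 0 and breeders.shape[0] > 0:
        b_sperm, b_shares = _store_matings(
            breeders.shape[0], summer_pool, shares1, rng
        )
    else:
        breeders = breeders[:0]  # unmated daughters do not reproduce
        b_sperm, b_shares = sperm[:0], shares[:0]

    # --- maternal survival; helpers boost surviving mothers only ---
    survive = rng.random(n) < config.S_f
    F5 = config.F1 * (1.0 + config.b * helpers_per_nest[survive])
    surv_sperm, surv_shares = sperm[survive], shares[survive]
    if serial:
        # sperm is not stored between broods: survivors take one new mate
        if summer_pool.shape[0] > 0:
            surv_sperm, surv_shares = _store_matings(
                int(survive.sum()), summer_pool, np.array([1.0]), rng
            )
        else:
            survive = np.zeros_like(survive)  # unmated: no second brood
            surv_sperm, surv_shares = sperm[:0], shares[:0]
            F5 = F5[:0]

    # --- summer broods ---
    summer_new = _reproduce(
        breeders, b_sperm, b_shares, np.full(breeders.shape[0], float(config.F3)),
        breeders.mean(axis=2)[:, Z2], population.ploidy, mu, sigma, frozen_h, rng,
    )
    summer_old = _reproduce(
        genomes[survive], surv_sperm, surv_shares, F5, phen[survive][:, Z2],
        population.ploidy, mu, sigma, frozen_h, rng,
    )
    aut_fem = np.concatenate([summer_new.fem_genomes, summer_old.fem_genomes])
    aut_males = np.concatenate([summer_new.male_genomes, summer_old.male_genomes])
    record_kwargs.update(n_autumn_offspring=aut_fem.shape[0] + aut_males.shape[0])

    if aut_fem.shape[0] == 0:
        return None, YearlyRecord(**record_kwargs, extinct=True)

    # --- winter: density dependence restores N breeding females ---
    n_next = min(settings.N, aut_fem.shape[0])
    keep = rng.choice(aut_fem.shape[0], size=n_next, replace=False)

    if ld:
        # both sexes overwinter; males are thinned by the same factor so
        # the spring sex ratio mirrors the autumn brood composition
        frac = n_next / aut_fem.shape[0]
        keep_m = rng.random(aut_males.shape[0]) < frac
        males_next = aut_males[keep_m]
        if males_next.shape[0] == 0:
            return None, YearlyRecord(**record_kwargs, extinct=True)
        next_pop = Population(
            genomes=aut_fem[keep], sperm=None, shares=None,
            ploidy=population.ploidy, males=males_next,
        )
        return next_pop, YearlyRecord(**record_kwargs)

    # FH: autumn daughters mate (autumn sons + S_m-surviving spring males)
    old_survive = rng.random(spring_males.shape[0]) < config.S_m
    pool = np.concatenate([aut_males, spring_males[old_survive]])
    if pool.shape[0] == 0:
        return None, YearlyRecord(**record_kwargs, extinct=True)
    new_sperm, new_shares = _store_matings(n_next, pool, shares1, rng)
    next_pop = Population(
        genomes=aut_fem[keep], sperm=new_sperm, shares=new_shares,
        ploidy=population.ploidy,
    )
    return next_pop, YearlyRecord(**record_kwargs)


def run_simulation(
    config: ModelConfig, settings: SimulationSettings
) -> pd.DataFrame:
    """Run ``T_years`` years and return the yearly records as a DataFrame.

    Identical seeds give bit-identical output; on extinction the final row
    has ``extinct=True`` and the run stops early.
    """
    validate_config(config)
    rng = np.random.default_rng(settings.seed)
    pop = initialize_population(settings, config)
    records: list[YearlyRecord] = []
    for year in range(settings.T_years):
        pop, rec = run_year(pop, config, settings, rng, year=year)
        if year % settings.record_every == 0 or pop is None or rec.extinct:
            records.append(rec)
        if pop is None:
            break
    return pd.DataFrame([r.__dict__ for r in records])
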