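"""Scenario configuration shared by all model components.

A scenario is fully specified by the life cycle (female hibernation ``FH``
or larval diapause ``LD``), the genetic system (haplodiploid or diploid),
the mating system (lifetime monogamy, serial monogamy, or polyandry with an
effective mate number ``m_e``), and the demographic parameters: spring
fecundity ``F1``, fecundity of spring-born solitary breeders ``F3``, adult
female survival from spring to summer ``S_f``, male survival across broods
``S_m``, and the per-helper fecundity benefit ``b``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import pathlib
from dataclasses import dataclass
from typing import Any, Mapping


class LifeCycle(str, enum.Enum):
    FH = "FH"
    LD = "LD"


class Ploidy(str, enum.Enum):
    HAPLODIPLOID = "haplodiploid"
    DIPLOID = "diploid"


class Mating(str, enum.Enum):
    MONOGAMY = "monogamy"
    SERIAL_MONOGAMY = "serial_monogamy"
    POLYANDRY = "polyandry"


class ConfigError(ValueError):
    """Raised when a scenario configuration violates a model invariant."""


@dataclass(frozen=True)
class ModelConfig:
    """A fully specified model scenario.

    Parameters
    ----------
    life_cycle
        ``FH`` (only mated females overwinter) or ``LD`` (both sexes
        overwinter as diapause larvae).
    ploidy
        ``haplodiploid`` or ``diploid``.
    mating
        ``monogamy`` (lifetime sperm storage from a single male),
        ``serial_monogamy`` (a new single mate per brood, no sperm
        carry-over; FH only), or ``polyandry`` (sperm of ``m_e`` effective
        mates stored for life).
    m_e
        Effective number of mates per female, the inverse of the
        probability that two maternal sisters share a father. Must be 1
        under monogamy.
    F1, F3
        Fecundity of spring foundresses and of spring-born solitary
        breeders (offspring per female per brood).
    S_f
        Probability that a spring female survives to breed again in summer.
    S_m
        Survival of the overlapping male brood into the later mating pool
        (FH: spring males into autumn; LD: overwintered males into summer).
    b
        Additional offspring gained per helper per maternal offspring.
    """

    life_cycle: LifeCycle = LifeCycle.FH
    ploidy: Ploidy = Ploidy.HAPLODIPLOID
    mating: Mating = Mating.MONOGAMY
    m_e: float = 1.0
    F1: float = 2.0
    F3: float = 2.0
    S_f: float = 0.9
    S_m: float = 0.6
    b: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "life_cycle", LifeCycle(self.life_cycle))
        object.__setattr__(self, "ploidy", Ploidy(self.ploidy))
        object.__setattr__(self, "mating", Mating(self.mating))

    @property
    def p_same_father(self) -> float:
        """Probability that two maternal sisters of the same brood share a father."""
        return 1.0 / self.m_e

    def replace(self, **kwargs: Any) -> "ModelConfig":
        return validate_config(dataclasses.replace(self, **kwargs))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k in ("life_cycle", "ploidy", "mating"):
            d[k] = d[k].value
        return d


@dataclass(frozen=True)
class TraitState:
    """The three evolvable traits, each a probability.

    ``z1``/``z2`` are the proportions of sons in the spring and summer
    broods; ``h`` is the probability that a spring-born daughter stays at
    the natal nest as a helper.
    """

    z1: float = 0.5
    z2: float = 0.5
    h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("z1", "z2", "h"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} out of [0,1]: {val!r}")

    def replace(self, **kwargs: Any) -> "TraitState":
        return dataclasses.replace(self, **kwargs)

    def as_array(self):
        import numpy as np

        return np.array([self.z1, self.z2, self.h], dtype=float)


def _require_prob(cfg: ModelConfig, field: str) -> None:
    val = getattr(cfg, field)
    if not 0.0 <= val <= 1.0:
        raise ConfigError(f"{field} out of [0,1]: {val!r}")


def validate_config(config: ModelConfig) -> ModelConfig:
    """Check all configuration invariants; return the config unchanged.

    Raises :class:`ConfigError` naming the offending field otherwise.
    Validation is idempotent.
    """
    for field in ("S_f", "S_m"):
        _require_prob(config, field)
    for field in ("F1", "F3"):
        if getattr(config, field) <= 0.0:
            raise ConfigError(f"{field} must be > 0: {getattr(config, field)!r}")
    if config.b < 0.0:
        raise ConfigError(f"b must be >= 0: {config.b!r}")
    if config.m_e < 1.0:
        raise ConfigError(f"m_e < 1: {config.m_e!r}")
    if config.mating is Mating.MONOGAMY and config.m_e != 1.0:
        raise ConfigError(
            f"monogamy requires m_e = 1, got m_e = {config.m_e!r}"
        )
    if config.mating is Mating.SERIAL_MONOGAMY and config.life_cycle is LifeCycle.LD:
        # Re-mating between broods is only defined for the FH cycle, where
        # a summer male pool exists at the time the second brood is sired.
        raise ConfigError("serial_monogamy is only defined for the FH life cycle")
    return config


def load_config(path: str | pathlib.Path, **overrides: Any) -> ModelConfig:
    """Read a scenario from a flat YAML or JSON key-value file."""
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data: Mapping[str, Any] = json.loads(text)
    else:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**dict(data), **overrides}
    return validate_config(ModelConfig(**merged))
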