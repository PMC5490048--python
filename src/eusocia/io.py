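"""CSV writers and threshold sweep drivers.

All tabular output is plain RFC-4180 CSV with ``.`` decimal separators and
full round-trip float precision. Simulation output files carry the full
configuration and seed as ``#``-prefixed header comment lines.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adaptive_dynamics import Trajectory
from .config import ModelConfig, validate_config
from .selection import SelectionError, ThresholdMode, eusociality_threshold

_PARAM_DOMAINS = {
    "S_m": (0.0, 1.0),
    "S_f": (0.0, 1.0),
    "b": (0.0, np.inf),
    "F1": (0.0, np.inf),
    "F3": (0.0, np.inf),
    "m_e": (1.0, np.inf),
}


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter threshold sweep over a list of scenarios."""

    parameter: str
    start: float
    stop: float
    steps: int
    scenarios: tuple[ModelConfig, ...]
    mode: ThresholdMode = ThresholdMode.FIXED_SEX_RATIOS

    def __post_init__(self) -> None:
        if self.parameter not in _PARAM_DOMAINS:
            raise ValueError(f"unknown sweep parameter: {self.parameter!r}")
        lo, hi = _PARAM_DOMAINS[self.parameter]
        if not (lo <= self.start <= hi and lo <= self.stop <= hi):
            raise ValueError(
                f"sweep range [{self.start}, {self.stop}] outside the legal "
                f"domain [{lo}, {hi}] of {self.parameter}"
            )
        if self.steps < 2:
            raise ValueError("steps must be >= 2")


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Threshold ``B_min`` for every (scenario, parameter value) pair.

    Scenario-level failures (e.g. no sign change in the bisection bracket)
    are recorded in the ``error`` column of the affected row, not raised.
    """
    values = np.linspace(spec.start, spec.stop, spec.steps)
    rows = []
    for cfg in spec.scenarios:
        validate_config(cfg)
        for val in values:
            row = {
                "life_cycle": cfg.life_cycle.value,
                "ploidy": cfg.ploidy.value,
                "mating": cfg.mating.value,
                "m_e": cfg.m_e,
                spec.parameter: float(val),
                "mode": spec.mode.value,
                "B_min": np.nan,
                "z1_star": np.nan,
                "z2_star": np.nan,
                "error": "",
            }
            try:
                res = eusociality_threshold(
                    cfg.replace(**{spec.parameter: float(val)}), spec.mode
                )
                row.update(
                    B_min=res.B_min, z1_star=res.z1_star, z2_star=res.z2_star
                )
            except (SelectionError, ValueError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | pathlib.Path, header_meta: dict | None = None) -> None:
    """Write a DataFrame as CSV, optionally preceded by ``# key=value`` lines."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_meta:
            for key, val in header_meta.items():
                fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_trajectory(trajectory: Trajectory, path: str | pathlib.Path) -> None:
    """Write an adaptive-dynamics trajectory as CSV (deterministic layout)."""
    write_table(trajectory.to_frame(), path)


def read_table(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping comment headers."""
    return pd.read_csv(path, comment="#")
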