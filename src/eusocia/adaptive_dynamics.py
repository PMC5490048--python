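"""Adaptive-dynamics integration of the trait-substitution dynamics.

Each trait evolves at a rate proportional to its selection differential,
``dx/dt = K * dW/dx``, with trait values projected onto [0,1] after every
step (a trait pinned at a boundary stays there while its gradient points
outward). The helping trait is held frozen until a release time,
mirroring simulations in which helping mutations are only introduced once
the sex ratios have equilibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, TraitState, validate_config
from .selection import closed_form_gradients, resident_state


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ADSettings:
    """Integrator controls.

    ``K`` scales evolutionary time (the dynamics' trajectory shape is
    invariant to it); ``T_total`` and ``h_release_time`` are in the same
    arbitrary time units. ``match_ibm_phase`` rescales reported time so
    the pre-release phase spans that many units (for overlaying
    individual-based runs where sex ratios equilibrate over a fixed number
    of years).
    """

    K: float = 1.0
    T_total: float = 800.0
    h_release_time: float = 300.0
    dt_init: float = 0.05
    dt_max: float = 5.0
    rtol: float = 1e-9
    atol: float = 1e-12
    record_every: float = 1.0
    match_ibm_phase: float | None = None


@dataclass
class Trajectory:
    """Time-indexed record of the resident traits and their gradients."""

    time: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    h: np.ndarray
    gradients: np.ndarray  # shape (n, 3)
    O_m: np.ndarray
    settings: ADSettings
    config: ModelConfig
    converged: bool = False

    def final_state(self) -> TraitState:
        return TraitState(z1=float(self.z1[-1]), z2=float(self.z2[-1]), h=float(self.h[-1]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "z1": self.z1,
                "z2": self.z2,
                "h": self.h,
                "dW_dz1": self.gradients[:, 0],
                "dW_dz2": self.gradients[:, 1],
                "dW_dh": self.gradients[:, 2],
                "O_m": self.O_m,
            }
        )


def _rhs(config: ModelConfig, x: np.ndarray, h_active: bool, K: float) -> tuple[np.ndarray, float]:
    traits = TraitState(z1=float(x[0]), z2=float(x[1]), h=float(x[2]))
    resident = resident_state(config, traits)
    g = closed_form_gradients(config, traits, resident).as_array()
    if not h_active:
        g[2] = 0.0
    # projected gradient at the box boundaries
    for i in range(3):
        if (x[i] <= 0.0 and g[i] < 0.0) or (x[i] >= 1.0 and g[i] > 0.0):
            g[i] = 0.0
    return K * g, resident.rvs.O_m


def integrate_coevolution(
    config: ModelConfig,
    initial: TraitState = TraitState(0.5, 0.5, 0.0),
    settings: ADSettings = ADSettings(),
) -> Trajectory:
    """Integrate the coevolution of (z1, z2, h) over evolutionary time.

    Heun (explicit trapezoid) steps with an embedded Euler error estimate
    drive adaptive step sizes; the state is clipped to the unit box after
    every stage. Gradients are recomputed from the full resident
    demography and reproductive values at every evaluation.
    """
    validate_config(config)
    x = np.clip(initial.as_array(), 0.0, 1.0)
    t = 0.0
    dt = settings.dt_init
    times, states, grads, oms = [], [], [], []
    next_record = 0.0

    def record(t, x, g, om):
        times.append(t)
        states.append(x.copy())
        grads.append(g.copy())
        oms.append(om)

    g, om = _rhs(config, x, t >= settings.h_release_time, settings.K)
    record(t, x, g, om)
    next_record = settings.record_every
    n_fail = 0
    while t < settings.T_total:
        h_active = t >= settings.h_release_time
        # do not step across the release time
        dt_eff = min(dt, settings.dt_max, settings.T_total - t)
        if not h_active:
            dt_eff = min(dt_eff, settings.h_release_time - t)
        f0, om = _rhs(config, x, h_active, settings.K)
        x_euler = np.clip(x + dt_eff * f0, 0.0, 1.0)
        f1, _ = _rhs(config, x_euler, h_active, settings.K)
        x_heun = np.clip(x + 0.5 * dt_eff * (f0 + f1), 0.0, 1.0)
        err = float(np.max(np.abs(x_heun - x_euler)))
        tol = settings.atol + settings.rtol * float(np.max(np.abs(x_heun)))
        if err > tol and dt_eff > 1e-10:
            dt = max(dt_eff * max(0.2, 0.9 * (tol / err) ** 0.5), 1e-10)
            n_fail += 1
            if n_fail > 10000:
                raise IntegrationError(
                    f"step size underflow at t={t}, state={x}"
                )
            continue
        n_fail = 0
        t += dt_eff
        x = x_heun
        if err > 0:
            dt = min(dt_eff * min(5.0, 0.9 * (tol / err) ** 0.5), settings.dt_max)
        else:
            dt = min(dt_eff * 5.0, settings.dt_max)
        if t >= next_record - 1e-12 or t >= settings.T_total:
            g, om = _rhs(config, x, h_active, settings.K)
            record(t, x, g, om)
            next_record = t + settings.record_every

    time_arr = np.array(times)
    if settings.match_ibm_phase is not None and settings.h_release_time > 0:
        time_arr = time_arr * (settings.match_ibm_phase / settings.h_release_time)
    states_arr = np.array(states)
    traj = Trajectory(
        time=time_arr,
        z1=states_arr[:, 0],
        z2=states_arr[:, 1],
        h=states_arr[:, 2],
        gradients=np.array(grads),
        O_m=np.array(oms),
        settings=settings,
        config=config,
    )
    traj.converged = _is_converged(traj, grad_tol=1e-7)
    return traj


def _is_converged(trajectory: Trajectory, grad_tol: float) -> bool:
    g = trajectory.gradients[-1]
    x = np.array([trajectory.z1[-1], trajectory.z2[-1], trajectory.h[-1]])
    ok = True
    for i in range(3):
        pinned_out = (x[i] <= 0.0 and g[i] < 0.0) or (x[i] >= 1.0 and g[i] > 0.0)
        ok = ok and (abs(g[i]) < grad_tol or pinned_out)
    return bool(ok)


def detect_equilibrium(
    trajectory: Trajectory, grad_tol: float = 1e-7
) -> tuple[TraitState, bool]:
    """Final state and whether it is an equilibrium at tolerance ``grad_tol``.

    A trait counts as equilibrated when its gradient is below tolerance or
    when it is pinned at a boundary with the gradient pointing outward.
    """
    return trajectory.final_state(), _is_converged(trajectory, grad_tol)
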