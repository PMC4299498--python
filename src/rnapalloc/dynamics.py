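"""Time courses of sigma-fragment production against a shared core budget.

A controller turns sigma-fragment outputs on and off over time.  In
*allocated* mode every output is a sigma fragment that must recruit the
shared core fragment, so total active polymerase can never exceed the
core budget, whatever the schedule.  In *unallocated* mode every output
is a complete polymerase whose activity is proportional to its own
level, so simultaneous outputs add up and can cross a toxicity
threshold.

Species totals follow production/dilution kinetics::

    d total_i / dt = production_i(t) - dilution * total_i

(and likewise for the core pool in allocated mode).  Binding is much
faster than dilution for the tight SynZIP-fused fragments, so by
default the core/sigma partition is re-equilibrated algebraically at
each step (quasi-equilibrium).  An explicit-kinetics mode integrating
the binding/unbinding reactions is kept both for checking the
time-scale separation and as an independent oracle for the algebraic
equilibrium solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import NumericalError, ValidationError
from .model import AllocatorSystem, BoundState, activate_core, equilibrate, promoter_activities

__all__ = [
    "Schedule",
    "DynamicsConfig",
    "Trajectory",
    "simulate",
    "threshold_report",
    "kinetic_steady_state",
]


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant production schedule.

    ``events`` is a list of ``(time_h, sigma_name, production_rate)``;
    each event sets that fragment's production rate from its time until
    the fragment's next event (rate 0 before the first event).
    """

    events: tuple[tuple[float, str, float], ...]
    horizon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(tuple(e) for e in self.events))
        if self.horizon <= 0:
            raise ValidationError("schedule horizon must be > 0")
        per_sigma: dict[str, float] = {}
        for t, name, rate in self.events:
            if rate < 0:
                raise ValidationError(f"production rate for {name!r} must be >= 0")
            if t < 0:
                raise ValidationError("event times must be >= 0")
            if name in per_sigma and t < per_sigma[name]:
                raise ValidationError(f"event times for {name!r} must be non-decreasing")
            per_sigma[name] = t

    def sigma_names(self) -> list[str]:
        seen: list[str] = []
        for _, name, _ in self.events:
            if name not in seen:
                seen.append(name)
        return seen

    def rate(self, sigma: str, t: float) -> float:
        r = 0.0
        for et, name, rate in self.events:
            if name == sigma and et <= t:
                r = rate
        return r


@dataclass(frozen=True)
class DynamicsConfig:
    """Integrator and host-context parameters.

    dilution_rate : per hour; growth/dilution acting on every species
        (default 0.69/h, a one-hour doubling time).
    core_production : AU/hour of core-fragment synthesis (allocated mode);
        the core pool starts at its steady level ``core_production/dilution``.
    toxicity_threshold : activity AU above which total transcriptional
        load is flagged.
    mode : ``"allocated"`` (outputs are sigma fragments sharing the core)
        or ``"unallocated"`` (outputs are complete polymerases).
    time_step : fixed RK4 step, hours.
    quasi_equilibrium : re-partition the core algebraically each step
        (default); ``False`` integrates explicit binding kinetics with
        on-rate ``binding_on_rate`` and off-rates ``binding_on_rate * kd``.
    """

    dilution_rate: float = 0.69
    core_production: float = 0.69
    toxicity_threshold: float = 1.0
    mode: str = "allocated"
    time_step: float = 0.01
    quasi_equilibrium: bool = True
    binding_on_rate: float = 1e4

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValidationError("dilution_rate must be > 0")
        if self.time_step <= 0:
            raise ValidationError("time_step must be > 0")
        if self.toxicity_threshold <= 0:
            raise ValidationError("toxicity_threshold must be > 0")
        if self.mode not in ("allocated", "unallocated"):
            raise ValidationError("mode must be 'allocated' or 'unallocated'")
        if self.core_production < 0:
            raise ValidationError("core_production must be >= 0")


@dataclass
class Trajectory:
    """Simulated time series plus threshold-crossing intervals."""

    times: np.ndarray
    sigma_totals: dict[str, np.ndarray]
    core_total: np.ndarray
    active_core_total: np.ndarray
    total_active_polymerase: np.ndarray
    activities: dict[str, np.ndarray]
    total_activity: np.ndarray
    threshold_crossings: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: (time_h, species, value)."""
        frames = []
        for name, series in (
            [("core_total", self.core_total)]
            + [(f"sigma:{k}", v) for k, v in self.sigma_totals.items()]
            + [(f"activity:{k}", v) for k, v in self.activities.items()]
            + [
                ("total_active_polymerase", self.total_active_polymerase),
                ("total_activity", self.total_activity),
            ]
        ):
            frames.append(
                pd.DataFrame({"time_h": self.times, "species": name, "value": series})
            )
        return pd.concat(frames, ignore_index=True)


def _rk4(f, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    # production rates are piecewise constant, so every stage samples the
    # rate at the step's left endpoint: events take effect from their grid
    # point on, never half a step early
    y = np.empty((len(times), len(y0)))
    y[0] = y0
    for i in range(len(times) - 1):
        t, h = times[i], times[i + 1] - times[i]
        k1 = f(t, y[i])
        k2 = f(t, y[i] + h / 2 * k1)
        k3 = f(t, y[i] + h / 2 * k2)
        k4 = f(t, y[i] + h * k3)
        y[i + 1] = y[i] + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y[i + 1])):
            raise NumericalError(
                f"integration diverged at t={times[i + 1]:.3f} h; reduce time_step"
            )
    return y


def simulate(
    system: AllocatorSystem, schedule: Schedule, config: DynamicsConfig
) -> Trajectory:
    """Integrate the schedule and report activities and threshold crossings.

    Allocated mode re-partitions the core pool among the instantaneous
    sigma totals at every step; total active polymerase (the sum of
    complexes) is therefore bounded by the instantaneous active core
    total.  Unallocated mode treats each output as a complete RNAP:
    its activity is ``efficiency * total`` and activities superpose.
    """
    sigma_names = [s.name for s in system.sigmas]
    for name in schedule.sigma_names():
        if name not in sigma_names:
            raise ValidationError(f"schedule references unknown sigma {name!r}")

    n_steps = max(int(round(schedule.horizon / config.time_step)), 1)
    times = np.linspace(0.0, schedule.horizon, n_steps + 1)
    delta = config.dilution_rate

    if config.mode == "allocated" and not config.quasi_equilibrium:
        return _simulate_explicit(system, schedule, config, times)

    # state: per-sigma totals, then core total
    def deriv(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        for i, name in enumerate(sigma_names):
            dy[i] = schedule.rate(name, t) - delta * y[i]
        dy[-1] = config.core_production - delta * y[-1]
        return dy

    y0 = np.zeros(len(sigma_names) + 1)
    y0[-1] = config.core_production / delta  # allocator constitutively on
    y = _rk4(deriv, y0, times)
    y = np.clip(y, 0.0, None)

    sigma_tot = {name: y[:, i] for i, name in enumerate(sigma_names)}
    core_tot = y[:, -1]
    n_t = len(times)
    active_core = np.empty(n_t)
    total_pol = np.empty(n_t)
    acts = {p.name: np.empty(n_t) for p in system.promoters}
    total_act = np.empty(n_t)

    for k in range(n_t):
        if config.mode == "allocated":
            sys_k = AllocatorSystem(
                core=_scaled_core(system, core_tot[k]),
                sigmas=system.sigmas,
                promoters=system.promoters,
                crosstalk=system.crosstalk,
            ).with_sigma_totals({n: float(sigma_tot[n][k]) for n in sigma_names})
            state = equilibrate(sys_k)
            active_core[k] = state.active_core_total
            total_pol[k] = sum(state.complexes.values())
            a = promoter_activities(state, sys_k)
        else:
            # complete polymerases: each output acts alone, no shared pool
            complexes = {n: float(sigma_tot[n][k]) for n in sigma_names}
            state = BoundState(0.0, complexes, sum(complexes.values()))
            active_core[k] = np.inf
            total_pol[k] = sum(complexes.values())
            a = promoter_activities(state, system)
        for pname, val in a.items():
            acts[pname][k] = val
        total_act[k] = sum(a.values())

    crossings = threshold_report_arrays(times, total_act, config.toxicity_threshold)
    return Trajectory(
        times=times,
        sigma_totals=sigma_tot,
        core_total=core_tot,
        active_core_total=active_core,
        total_active_polymerase=total_pol,
        activities=acts,
        total_activity=total_act,
        threshold_crossings=crossings,
    )


def _scaled_core(system: AllocatorSystem, total: float):
    c = system.core
    from .model import CoreSpec

    return CoreSpec(max(total, 0.0), c.requires_alpha, c.kd_alpha, c.alpha_total)


def _simulate_explicit(
    system: AllocatorSystem, schedule: Schedule, config: DynamicsConfig, times: np.ndarray
) -> Trajectory:
    """Explicit binding/unbinding kinetics (allocated mode only).

    State: free sigma_i..., complex_i..., free core.  Used to verify the
    quasi-equilibrium approximation when binding is fast relative to
    dilution.  Alpha activation is folded in by scaling core production
    (valid when alpha is constitutive over the horizon).
    """
    sigma_names = [s.name for s in system.sigmas]
    n = len(sigma_names)
    kds = np.array([s.kd_core for s in system.sigmas])
    if np.any(kds == 0):
        raise ValidationError("explicit kinetics needs finite kd_core (> 0)")
    kon = config.binding_on_rate
    koff = kon * kds
    delta = config.dilution_rate
    alpha_frac = (
        activate_core(system.core) / system.core.total if system.core.total > 0 else 1.0
    )
    core_prod = config.core_production * alpha_frac

    def make_deriv(rates: np.ndarray):
        def deriv(t: float, y: np.ndarray) -> np.ndarray:
            s, cx, f = y[:n], y[n : 2 * n], y[-1]
            bind = kon * f * s
            unbind = koff * cx
            ds = rates - delta * s - bind + unbind
            dcx = bind - unbind - delta * cx
            df = core_prod - delta * f - float(np.sum(bind - unbind))
            return np.concatenate([ds, dcx, [df]])

        return deriv

    y0 = np.zeros(2 * n + 1)
    y0[-1] = core_prod / delta
    # integrate piecewise between schedule events so the solver cannot
    # step over a production-rate discontinuity; rates are frozen per segment
    breaks = sorted({times[0], times[-1], *(t for t, _, _ in schedule.events if t < times[-1])})
    y_cur = y0
    rows = [y0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        rates = np.array([schedule.rate(nm, a) for nm in sigma_names])
        deriv = make_deriv(rates)
        eval_pts = np.concatenate([times[(times > a) & (times < b)], [b]])
        sol = solve_ivp(
            deriv, (a, b), y_cur, t_eval=eval_pts, method="LSODA",
            rtol=1e-8, atol=1e-12,
        )
        if not sol.success:
            raise NumericalError(f"explicit-kinetics integration failed: {sol.message}")
        y_cur = sol.y[:, -1]
        rows.extend(sol.y.T[i] for i, t in enumerate(eval_pts) if t in times)
    y = np.clip(np.asarray(rows), 0.0, None)
    if y.shape[0] != len(times):
        raise NumericalError("explicit-kinetics sampling mismatch")

    sigma_tot = {nm: y[:, i] + y[:, n + i] for i, nm in enumerate(sigma_names)}
    core_tot = (y[:, -1] + y[:, n : 2 * n].sum(axis=1)) / alpha_frac
    total_pol = y[:, n : 2 * n].sum(axis=1)
    acts = {p.name: np.zeros(len(times)) for p in system.promoters}
    for p in system.promoters:
        a = np.full(len(times), p.basal)
        for i, s in enumerate(system.sigmas):
            a = a + s.efficiency * system.crosstalk.get(s.name, p.name) * y[:, n + i]
        acts[p.name] = a
    total_act = sum(acts.values()) if acts else np.zeros(len(times))
    crossings = threshold_report_arrays(times, total_act, config.toxicity_threshold)
    return Trajectory(
        times=times,
        sigma_totals=sigma_tot,
        core_total=core_tot,
        active_core_total=y[:, -1] + y[:, n : 2 * n].sum(axis=1),
        total_active_polymerase=total_pol,
        activities=acts,
        total_activity=np.asarray(total_act),
        threshold_crossings=crossings,
    )


def threshold_report_arrays(
    times: np.ndarray, activity: np.ndarray, threshold: float
) -> list[tuple[float, float]]:
    """Maximal intervals where ``activity > threshold`` (strict)."""
    above = np.asarray(activity) > threshold
    crossings: list[tuple[float, float]] = []
    start = None
    for t, flag in zip(times, above):
        if flag and start is None:
            start = float(t)
        elif not flag and start is not None:
            crossings.append((start, float(t)))
            start = None
    if start is not None:
        crossings.append((start, float(times[-1])))
    return crossings


def threshold_report(traj: Trajectory, threshold: float) -> list[tuple[float, float]]:
    """Re-derive crossing intervals of total activity at a new threshold."""
    return threshold_report_arrays(traj.times, traj.total_activity, threshold)


def kinetic_steady_state(
    system: AllocatorSystem, t_final: float = 60.0, rtol: float = 1e-10, atol: float = 1e-14
) -> BoundState:
    """Steady state of the mass-action binding ODEs (no production/dilution).

    Independent check on :func:`rnapalloc.model.equilibrate`: integrates
    ``d complex_i/dt = kon_i * free_core * free_sigma_i - koff_i * complex_i``
    with ``koff_i/kon_i = kd_i`` to steady state with a stiff solver.
    On-rates are chosen per fragment (``kon_i = 1/kd_i``, so every
    off-rate is 1/h) purely to condition the integration; the fixed
    point does not depend on them.
    """
    c_active = activate_core(system.core)
    names = [s.name for s in system.sigmas]
    totals = np.array([s.total for s in system.sigmas], dtype=float)
    kds = np.array([s.kd_core for s in system.sigmas], dtype=float)
    if len(names) == 0 or c_active == 0 or totals.sum() == 0:
        return BoundState(c_active, {nm: 0.0 for nm in names}, c_active)
    if np.any(kds <= 0):
        raise ValidationError("kinetic oracle needs kd_core > 0")
    kon = 1.0 / kds
    koff = np.ones_like(kds)

    def deriv(t, cx):
        free = c_active - cx.sum()
        return kon * free * (totals - cx) - koff * cx

    sol = solve_ivp(
        deriv, (0.0, t_final), np.zeros(len(names)), method="Radau", rtol=rtol,
        atol=atol, dense_output=False,
    )
    if not sol.success:
        raise NumericalError(f"kinetic steady-state integration failed: {sol.message}")
    cx = sol.y[:, -1]
    return BoundState(float(c_active - cx.sum()), dict(zip(names, cx.tolist())), c_active)
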