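"""Numerical integration of the full system and the reduced frequency equation.

The full six-ODE system is integrated with an adaptive stiff-capable
solver (LSODA); the phage burst (B ~ 100) makes the system moderately
stiff once the epidemic takes off.  Negative excursions of order the
absolute tolerance can occur as compartments crash to zero; the raw
solver state is kept for integration and clipped to zero only in
reported output.

The reduced equation dN+/dt = alpha*V(t)*f_delta(t)*N+(1-N+) can be
driven by arbitrary callables, typically the dense interpolants of a
full-model run, which is how the full/reduced equivalence of the
cost- and mutation-free limit is checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    InvalidModelInput,
    ModelParameters,
    PopulationState,
    STATE_NAMES,
    UndefinedStatisticError,
    crispr_frequency,
    f_delta_from_densities,
    rhs,
)

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "FixationReport",
    "integrate_full",
    "integrate_reduced",
    "reduced_from_trajectory",
    "euler_integrate",
    "sign_outcome",
    "fixation_check",
    "predict_experiment",
]

#: fixed header of the trajectory CSV interface
TRAJECTORY_COLUMNS = ["time", "S_minus", "R_minus", "S_plus", "R_plus",
                      "C_plus", "V", "N_total", "N_plus_freq", "f_delta"]


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver configuration.

    ``rel_tol``/``abs_tol`` are the adaptive-solver tolerances (the
    absolute tolerance is in cells/ml, far below one cell per
    experimental volume).  ``t_end`` is the horizon in hours, default
    the 24 h competition window.  ``fixation_threshold`` is the density
    below which a sensitive population counts as collapsed (1 cell/ml).
    ``n_points`` sets the reporting grid; the dense interpolant is kept
    regardless.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-2
    t_end: float = 24.0
    max_step: float = np.inf
    clip_negative: bool = True
    fixation_threshold: float = 1.0
    n_points: int = 241
    plateau_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise InvalidModelInput("solver tolerances must be > 0")
        if not self.t_end > 0:
            raise InvalidModelInput("t_end must be > 0")
        if self.n_points < 2:
            raise InvalidModelInput("n_points must be >= 2")


class Trajectory:
    """A solved run: reporting grid, states, and recomputed derived series.

    States on the reporting grid are clipped to non-negative when the
    settings request it; ``raw_states`` keeps the solver output.  All
    derived series (N, CRISPR+ frequency, f_delta) are computed from the
    states on access, never stored independently.
    """

    def __init__(self, times: np.ndarray, raw_states: np.ndarray,
                 params: ModelParameters, settings: IntegrationSettings,
                 dense: Callable[[float], np.ndarray] | None = None):
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise InvalidModelInput("trajectory times must be strictly increasing")
        self.times = times
        self.raw_states = np.asarray(raw_states, dtype=float)  # shape (6, n)
        self.params = params
        self.settings = settings
        self._dense = dense

    # -- state access -------------------------------------------------------

    @property
    def states(self) -> np.ndarray:
        """(6, n) array of reported states, clipped to >= 0 if configured."""
        if self.settings.clip_negative:
            return np.clip(self.raw_states, 0.0, None)
        return self.raw_states

    def state_at(self, t: float, clip: bool = True) -> np.ndarray:
        """Interpolated state vector at time ``t`` (dense solver output)."""
        if self._dense is None:
            raise RuntimeError("trajectory has no dense interpolant")
        y = np.asarray(self._dense(t), dtype=float)
        return np.clip(y, 0.0, None) if clip else y

    def final_state(self) -> PopulationState:
        y = np.clip(self.raw_states[:, -1], 0.0, None)
        return PopulationState.from_array(y, t=float(self.times[-1]))

    # -- derived series -----------------------------------------------------

    @property
    def N_total(self) -> np.ndarray:
        return self.states[:5].sum(axis=0)

    @property
    def N_plus_freq(self) -> np.ndarray:
        s = self.states
        return (s[2] + s[3] + s[4]) / s[:5].sum(axis=0)

    @property
    def f_delta(self) -> np.ndarray:
        """f_delta along the run; NaN where a subpopulation is empty."""
        s = self.states
        plus = s[2] + s[3] + s[4]
        minus = s[0] + s[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            fd = np.where(plus > 0, (s[3] + s[4]) / plus, np.nan) \
                - np.where(minus > 0, s[1] / minus, np.nan)
        return fd

    def n_plus_at(self, t: float) -> float:
        y = self.state_at(t)
        return (y[2] + y[3] + y[4]) / y[:5].sum()

    def f_delta_at(self, t: float) -> float:
        y = self.state_at(t)
        return f_delta_from_densities(*y[:5])

    def v_at(self, t: float) -> float:
        return float(self.state_at(t)[5])

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        s = self.states
        return pd.DataFrame({
            "time": self.times,
            **{name: s[i] for i, name in enumerate(STATE_NAMES)},
            "N_total": self.N_total,
            "N_plus_freq": self.N_plus_freq,
            "f_delta": self.f_delta,
        })[TRAJECTORY_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def integrate_full(initial: PopulationState, params: ModelParameters,
                   settings: IntegrationSettings = IntegrationSettings()) -> Trajectory:
    """Solve the six-ODE system from ``initial`` over [t0, t0 + t_end]."""
    y0 = initial.as_array()
    t0 = initial.t
    t_span = (t0, t0 + settings.t_end)
    t_eval = np.linspace(*t_span, settings.n_points)
    sol = solve_ivp(lambda t, y: rhs(y, params), t_span, y0,
                    method="LSODA", rtol=settings.rel_tol,
                    atol=settings.abs_tol, max_step=settings.max_step,
                    t_eval=t_eval, dense_output=True)
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t={sol.t[-1] if sol.t.size else t0:.4g} h: "
            f"{sol.message}")
    return Trajectory(sol.t, sol.y, params, settings, dense=sol.sol)


def integrate_reduced(N_plus0: float,
                      f_delta_series: Callable[[float], float],
                      V_series: Callable[[float], float],
                      alpha: float,
                      settings: IntegrationSettings = IntegrationSettings(),
                      t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Solve dN+/dt = alpha*V(t)*f_delta(t)*N+(1-N+) driven by the series.

    Returns ``(times, N_plus)`` on the reporting grid.
    """
    if not 0.0 <= N_plus0 <= 1.0:
        raise InvalidModelInput(f"N_plus0 must be in [0, 1], got {N_plus0}")
    t_span = (t0, t0 + settings.t_end)
    t_eval = np.linspace(*t_span, settings.n_points)

    def f(t: float, y: np.ndarray) -> list[float]:
        n = y[0]
        return [alpha * V_series(t) * f_delta_series(t) * n * (1.0 - n)]

    sol = solve_ivp(f, t_span, [N_plus0], method="LSODA",
                    rtol=settings.rel_tol, atol=1e-14, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"reduced-equation integration failed: {sol.message}")
    return sol.t, sol.y[0]


def reduced_from_trajectory(traj: Trajectory,
                            settings: IntegrationSettings | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Reduced-equation run driven by V(t), f_delta(t) from a full-model run."""
    settings = settings or traj.settings
    t0 = float(traj.times[0])
    return integrate_reduced(
        traj.n_plus_at(t0),
        traj.f_delta_at,
        traj.v_at,
        traj.params.alpha,
        settings=settings,
        t0=t0,
    )


def euler_integrate(initial: PopulationState, params: ModelParameters,
                    t_end: float = 24.0, dt: float = 1e-4) -> PopulationState:
    """Fixed-step forward-Euler solution; brute-force cross-check."""
    y = initial.as_array()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        y = y + dt * rhs(y, params)
    return PopulationState.from_array(np.clip(y, 0.0, None),
                                      t=initial.t + n_steps * dt)


Outcome = Literal["increase", "decrease", "no_change"]


def sign_outcome(initial: PopulationState, params: ModelParameters,
                 settings: IntegrationSettings = IntegrationSettings(),
                 dead_band: float = 1e-6) -> Outcome:
    """Classify the change in CRISPR+ frequency over the horizon.

    Changes smaller than ``dead_band`` (default 1e-6, below plausible
    solver noise) are classified ``no_change``.
    """
    traj = integrate_full(initial, params, settings)
    delta = traj.N_plus_freq[-1] - crispr_frequency(initial)
    if abs(delta) < dead_band:
        return "no_change"
    return "increase" if delta > 0 else "decrease"


@dataclass(frozen=True)
class FixationReport:
    """Outcome of the sensitive-collapse check on a trajectory."""

    collapse_time: float | None     # None if never below threshold
    f_delta_end: float              # |.| small once resistance fixes both sides
    plateau: bool                   # |dN+/dt| < plateau_tol at the horizon
    dn_plus_dt_end: float


def fixation_check(traj: Trajectory) -> FixationReport:
    """Detect collapse of the sensitive compartments and the N+ plateau.

    Collapse time is the first grid time at which S- + S+ falls below
    the fixation threshold.  The f_delta reported is taken at the end of
    the run; when one side retains no resistant cells it tends to +-1
    instead of 0, which the caller interprets.
    """
    s = traj.states
    sensitive = s[0] + s[2]
    below = np.nonzero(sensitive < traj.settings.fixation_threshold)[0]
    collapse_time = float(traj.times[below[0]]) if below.size else None

    y_end = np.clip(traj.raw_states[:, -1], 0.0, None)
    try:
        fd_end = f_delta_from_densities(*y_end[:5])
    except UndefinedStatisticError:
        # one subpopulation numerically extinct at the horizon: report the
        # last grid value where the statistic was still defined (its limit)
        fd_series = traj.f_delta
        defined = np.nonzero(np.isfinite(fd_series))[0]
        fd_end = fd_series[defined[-1]] if defined.size else np.nan

    dy = rhs(y_end, traj.params)
    N = y_end[:5].sum()
    dN = dy[:5].sum()
    d_plus = dy[2] + dy[3] + dy[4]
    n_plus = (y_end[2] + y_end[3] + y_end[4]) / N
    dn_plus_dt = d_plus / N - n_plus * dN / N
    return FixationReport(
        collapse_time=collapse_time,
        f_delta_end=float(fd_end),
        plateau=bool(abs(dn_plus_dt) < traj.settings.plateau_tol),
        dn_plus_dt_end=float(dn_plus_dt),
    )


def predict_experiment(initial_frequencies, N0: float, V0: float,
                       params: ModelParameters,
                       settings: IntegrationSettings = IntegrationSettings()
                       ) -> float:
    """Predicted relative change in CRISPR+ frequency from paired runs.

    Integrates the full model twice from ``N0 * frequencies`` — once
    with phage at density ``V0`` and once without — and returns

        (N+_phage(t_end) - N+_no_phage(t_end)) / N+_no_phage(t_end),

    the response variable of the competition experiment.
    """
    state_phage = PopulationState.from_frequencies(initial_frequencies, N0, V0)
    state_blank = PopulationState.from_frequencies(initial_frequencies, N0, 0.0)
    np_phage = integrate_full(state_phage, params, settings).N_plus_freq[-1]
    np_blank = integrate_full(state_blank, params, settings).N_plus_freq[-1]
    if np_blank == 0:
        raise UndefinedStatisticError(
            "relative change undefined: no-phage CRISPR+ frequency is 0")
    return float((np_phage - np_blank) / np_blank)
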