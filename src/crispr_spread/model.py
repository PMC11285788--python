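"""Core five-genotype bacteria–phage model.

The model tracks a well-mixed bacterial population in which a CRISPR-Cas
locus is segregating, together with a lytic phage.  Five bacterial
genotypes are distinguished by (a) whether they carry the CRISPR-Cas
system (``+`` / ``-``) and (b) how they relate to the phage:

=========  ==========================================================
``S_minus``  no CRISPR-Cas, sensitive to phage
``R_minus``  no CRISPR-Cas, surface-receptor mutant (resistant)
``S_plus``   CRISPR-Cas carrier without a matching spacer (sensitive)
``R_plus``   CRISPR-Cas carrier, surface-receptor mutant (resistant)
``C_plus``   CRISPR-Cas carrier with a phage-targeting spacer (immune)
=========  ==========================================================

Double resistance (surface mutant *and* spacer) is not modelled: it is
rarely observed and confers no extra benefit.

Dynamics: logistic division at rate ``r (1 - N/K)`` (reduced by the cost
``c_R`` for receptor mutants and ``c_I`` for immune cells), mass-action
phage adsorption with rate constant ``alpha``, burst size ``B`` on lysis
of sensitive cells, spacer acquisition with probability ``A`` per
infection of a CRISPR-Cas carrier, receptor mutation with probability
``mu`` per division of a sensitive cell, and linear death/decay rates
``m_b`` (bacteria) and ``m_v`` (phage).  Receptor mutants do not adsorb
phage; immune cells adsorb (and thereby remove) phage without lysis.

Units convention: time in hours, bacterial densities in cells/ml, phage
in pfu/ml — matching a 24 h competition-experiment window.

The derived statistic at the heart of the analysis is

    f_delta = (R+ + C+)/(S+ + R+ + C+)  -  R-/(R- + S-),

the difference in the protected (resistant-or-immune) fraction between
the CRISPR+ and CRISPR- subpopulations.  In the cost- and mutation-free
limit the CRISPR+ frequency N+ obeys the replicator-type equation

    dN+/dt = alpha * V * f_delta * N+ (1 - N+),

so phage density sets the speed of selection and the sign of ``f_delta``
sets its direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParameters",
    "PopulationState",
    "DerivedStats",
    "InvalidModelInput",
    "UndefinedStatisticError",
    "STATE_NAMES",
    "derivatives",
    "rhs",
    "f_delta",
    "f_delta_from_densities",
    "crispr_frequency",
    "reduced_rhs",
    "selection_coefficient",
    "derived_stats",
    "fig1_parameters",
]

#: canonical ordering of the state vector (five genotypes, then phage)
STATE_NAMES = ("S_minus", "R_minus", "S_plus", "R_plus", "C_plus", "V")


class InvalidModelInput(ValueError):
    """A state or parameter set violates the model's domain."""


class UndefinedStatisticError(ValueError):
    """A frequency statistic is undefined (empty subpopulation)."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, costs and probabilities of the full model.

    Parameters
    ----------
    r : float
        Maximum per-capita division rate (1/h).
    K : float
        Carrying capacity (cells/ml).
    m_b : float
        Per-capita bacterial death rate (1/h).
    m_v : float
        Per-capita free-phage decay rate (1/h).
    alpha : float
        Mass-action adsorption/infection rate constant (ml/h).
    B : float
        Burst size: phage released per lysed cell (dimensionless).
    mu : float
        Probability of a receptor-resistance mutation per division of a
        sensitive cell, in [0, 1].
    A : float
        Probability of spacer acquisition per infection of a CRISPR-Cas
        carrier, in [0, 1].
    c_R : float
        Growth cost of surface resistance, in [0, 1).
    c_I : float
        Growth cost of CRISPR immunity, in [0, 1).
    """

    r: float
    K: float
    m_b: float = 0.0
    m_v: float = 0.0
    alpha: float = 0.0
    B: float = 0.0
    mu: float = 0.0
    A: float = 0.0
    c_R: float = 0.0
    c_I: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r > 0 and np.isfinite(self.r)):
            raise InvalidModelInput(f"r must be > 0, got {self.r}")
        if not (self.K > 0 and np.isfinite(self.K)):
            raise InvalidModelInput(f"K must be > 0, got {self.K}")
        for name in ("m_b", "m_v", "alpha", "B"):
            v = getattr(self, name)
            if not (v >= 0 and np.isfinite(v)):
                raise InvalidModelInput(f"{name} must be >= 0, got {v}")
        for name in ("mu", "A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidModelInput(f"{name} must be in [0, 1], got {v}")
        for name in ("c_R", "c_I"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InvalidModelInput(f"{name} must be in [0, 1), got {v}")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        return cls(**d)

    def replace(self, **kwargs: float) -> "ModelParameters":
        d = self.to_dict()
        d.update(kwargs)
        return ModelParameters(**d)


def fig1_parameters(**overrides: float) -> ModelParameters:
    """Default parameter set of the illustrative scenario.

    r=0.5/h, K=1e9 cells/ml, alpha=1e-9 ml/h, B=100, c_R=0.05, c_I=0,
    mu=A=0, m_b=m_v=0.  Any field can be overridden by keyword.
    """
    base = dict(r=0.5, K=1e9, m_b=0.0, m_v=0.0, alpha=1e-9, B=100.0,
                mu=0.0, A=0.0, c_R=0.05, c_I=0.0)
    base.update(overrides)
    return ModelParameters(**base)


@dataclass(frozen=True)
class PopulationState:
    """Densities of the five bacterial genotypes and free phage at time t."""

    S_minus: float
    R_minus: float
    S_plus: float
    R_plus: float
    C_plus: float
    V: float
    t: float = 0.0

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidModelInput(f"non-finite density in state {arr}")
        if np.any(arr < 0):
            raise InvalidModelInput(f"negative density in state {arr}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S_minus, self.R_minus, self.S_plus, self.R_plus,
             self.C_plus, self.V], dtype=float)

    @classmethod
    def from_array(cls, y: Iterable[float], t: float = 0.0) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        return cls(*y, t=t)

    @classmethod
    def from_frequencies(cls, freqs: Iterable[float], N0: float, V0: float,
                         t: float = 0.0, tol: float = 1e-6) -> "PopulationState":
        """Build a state from five genotype frequencies and total densities.

        ``freqs`` follows the canonical genotype order
        (S-, R-, S+, R+, C+) and must sum to 1 within ``tol``.
        """
        f = np.asarray(list(freqs), dtype=float)
        if f.shape != (5,):
            raise InvalidModelInput(f"expected 5 genotype frequencies, got {f.shape}")
        if np.any(f < 0) or abs(f.sum() - 1.0) > tol:
            raise InvalidModelInput(
                f"frequencies must be non-negative and sum to 1: {f} (sum={f.sum()})")
        return cls(*(N0 * f / f.sum()), V=V0, t=t)

    @property
    def N(self) -> float:
        """Total bacterial density."""
        return self.S_minus + self.R_minus + self.S_plus + self.R_plus + self.C_plus

    @property
    def crispr_plus(self) -> float:
        return self.S_plus + self.R_plus + self.C_plus

    @property
    def crispr_minus(self) -> float:
        return self.S_minus + self.R_minus


@dataclass(frozen=True)
class DerivedStats:
    """Summary statistics derived from a state (never stored, always recomputed)."""

    N_total: float
    N_plus_freq: float
    f_delta: float
    resistance_freq: float
    sel_coeff: float


# ---------------------------------------------------------------------------
# right-hand sides


def rhs(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Unvalidated right-hand side of the six ODEs; fast path for solvers.

    ``y`` is ordered as :data:`STATE_NAMES`.  Division is logistic with
    the shared crowding factor ``g = r (1 - N/K)``; the mutation factor
    ``(1 - mu)`` applies only to division of sensitive cells, which feed
    the receptor-mutant compartments at rate ``mu * g``.
    """
    Sm, Rm, Sp, Rp, Cp, V = y
    N = Sm + Rm + Sp + Rp + Cp
    g = p.r * (1.0 - N / p.K)
    a = p.alpha
    infection = a * V
    dSm = (g * (1.0 - p.mu) - infection - p.m_b) * Sm
    dRm = p.mu * g * Sm + (g * (1.0 - p.c_R) - p.m_b) * Rm
    dSp = (g * (1.0 - p.mu) - infection - p.m_b) * Sp
    dRp = p.mu * g * Sp + (g * (1.0 - p.c_R) - p.m_b) * Rp
    dCp = a * p.A * V * Sp + (g * (1.0 - p.c_I) - p.m_b) * Cp
    # phage: burst from lysed sensitives (spacer acquisition aborts the burst),
    # decay, and adsorption loss to everything that adsorbs (R cells do not)
    dV = (a * p.B * (Sm + Sp * (1.0 - p.A)) - p.m_v - a * (Sp + Sm + Cp)) * V
    return np.array([dSm, dRm, dSp, dRp, dCp, dV])


def derivatives(state: PopulationState, params: ModelParameters) -> np.ndarray:
    """Validated time-derivative vector (per hour) at ``state``.

    Returns the six components in :data:`STATE_NAMES` order.
    """
    if not isinstance(params, ModelParameters):
        params = ModelParameters(**dict(params))
    return rhs(state.as_array(), params)


# ---------------------------------------------------------------------------
# derived statistics


def f_delta_from_densities(S_minus: float, R_minus: float, S_plus: float,
                           R_plus: float, C_plus: float) -> float:
    """``f_delta`` from raw densities; raises if a subpopulation is empty."""
    plus = S_plus + R_plus + C_plus
    minus = S_minus + R_minus
    if plus <= 0 or minus <= 0:
        raise UndefinedStatisticError(
            "f_delta undefined: requires both a CRISPR+ and a CRISPR- "
            f"subpopulation (got CRISPR+ total {plus}, CRISPR- total {minus})")
    return (R_plus + C_plus) / plus - R_minus / minus


def f_delta(state: PopulationState) -> float:
    """Difference in protected fraction, CRISPR+ minus CRISPR-  (in [-1, 1])."""
    return f_delta_from_densities(state.S_minus, state.R_minus, state.S_plus,
                                  state.R_plus, state.C_plus)


def crispr_frequency(state: PopulationState) -> float:
    """Frequency N+ of CRISPR-carrying cells among all bacteria."""
    N = state.N
    if N <= 0:
        raise UndefinedStatisticError("CRISPR+ frequency undefined: no bacteria")
    return state.crispr_plus / N


def reduced_rhs(N_plus: float, f_delta: float, V: float, alpha: float) -> float:
    """dN+/dt of the reduced frequency equation: alpha*V*f_delta*N+(1-N+)."""
    if not 0.0 <= N_plus <= 1.0:
        raise InvalidModelInput(f"N_plus must be in [0, 1], got {N_plus}")
    return alpha * V * f_delta * N_plus * (1.0 - N_plus)


def selection_coefficient(state: PopulationState, params: ModelParameters) -> float:
    """Selection coefficient alpha*V*f_delta for CRISPR+ cells (1/h)."""
    return params.alpha * state.V * f_delta(state)


def derived_stats(state: PopulationState, params: ModelParameters) -> DerivedStats:
    """All derived statistics of a state in one bundle."""
    N = state.N
    fd = f_delta(state)
    return DerivedStats(
        N_total=N,
        N_plus_freq=crispr_frequency(state),
        f_delta=fd,
        resistance_freq=(state.R_minus + state.R_plus + state.C_plus) / N,
        sel_coeff=params.alpha * state.V * fd,
    )
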