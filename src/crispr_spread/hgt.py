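"""Horizontal transfer of the CRISPR-Cas locus, layered on the base model.

Transfer is modelled as mass-action conjugation-like kinetics: every
CRISPR+ cell (S+, R+, C+) is a potential donor, every CRISPR- cell a
potential recipient, with rate constant ``gamma`` (ml/h).  Recipients
keep their surface phenotype, so R- cells become R+ and S- cells become
S+ — unless the transferred locus comes with a phage-targeting spacer,
in which case an S- recipient becomes immune (C+).  The probability of
that spacer co-transfer is ``spacer_transfer_fraction`` scaled by the
share of immune cells among donors.  Transfer relabels cells, so the
total bacterial density is conserved exactly.

The quantity of interest is the instantaneous contribution of these
transfer fluxes to d(f_delta)/dt.  Writing P = R+ + C+, D = S+ + R+ + C+
and M = S- + R-, the chain rule along the transfer-only flux collapses
(the CRISPR- term cancels identically when spacer co-transfer is absent)
to

    flux = gamma * (R- * S+  -  (R+ + C+) * S-) / D  + spacer terms,

so with no spacer co-transfer the sign is set by the protected-fraction
contrast R-/S- vs (R+ + C+)/S+.  Early in an epidemic, receptor mutants
arise at the same per-capita rate in both genetic backgrounds while
spacer acquisition adds protected cells only on the CRISPR+ side; in
that regime transfer is dominated by S- -> S+ conversions and the net
effect on f_delta is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    InvalidModelInput,
    ModelParameters,
    PopulationState,
    f_delta_from_densities,
    derivatives,
)

__all__ = [
    "HgtSettings",
    "hgt_flux",
    "hgt_derivatives",
    "fdelta_hgt_flux",
    "sample_early_epidemic_states",
]


@dataclass(frozen=True)
class HgtSettings:
    """Transfer kinetics.

    gamma : mass-action transfer rate constant (ml/h), >= 0.
    spacer_transfer_fraction : probability that a locus arriving from an
        immune donor carries a working phage-targeting spacer, in [0, 1].
    """

    gamma: float = 0.0
    spacer_transfer_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.gamma >= 0 and np.isfinite(self.gamma)):
            raise InvalidModelInput(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.spacer_transfer_fraction <= 1.0:
            raise InvalidModelInput(
                "spacer_transfer_fraction must be in [0, 1], "
                f"got {self.spacer_transfer_fraction}")


def hgt_flux(state: PopulationState, hgt: HgtSettings) -> np.ndarray:
    """Transfer-only derivative vector (six components; V term is zero).

    Donors are all CRISPR+ cells.  An S- recipient becomes C+ with
    probability ``spacer_transfer_fraction * C+/D`` (a spacer-bearing
    locus from an immune donor), otherwise S+; an R- recipient always
    becomes R+.  The five bacterial components sum to zero.
    """
    D = state.crispr_plus
    if D <= 0 or hgt.gamma == 0:
        return np.zeros(6)
    phi_S = hgt.gamma * D * state.S_minus
    phi_R = hgt.gamma * D * state.R_minus
    q_immune = hgt.spacer_transfer_fraction * state.C_plus / D
    return np.array([
        -phi_S,                      # S- lost to conversion
        -phi_R,                      # R- lost to conversion
        phi_S * (1.0 - q_immune),    # S- -> S+
        phi_R,                       # R- -> R+
        phi_S * q_immune,            # S- -> C+ (spacer co-transfer)
        0.0,
    ])


def hgt_derivatives(state: PopulationState, params: ModelParameters,
                    hgt: HgtSettings) -> np.ndarray:
    """Full right-hand side including the horizontal-transfer terms."""
    return derivatives(state, params) + hgt_flux(state, hgt)


def fdelta_hgt_flux(state: PopulationState, params: ModelParameters,
                    hgt: HgtSettings) -> float:
    """Contribution of the transfer terms to d(f_delta)/dt (1/h).

    Chain rule of f_delta = P/D - R-/M along the transfer-only flux,
    with P = R+ + C+, D = S+ + R+ + C+, M = S- + R-.  ``params`` takes
    no part in the transfer flux itself; it is accepted so the call
    signature parallels :func:`hgt_derivatives`.
    """
    # validates that f_delta is defined at this state
    f_delta_from_densities(state.S_minus, state.R_minus, state.S_plus,
                           state.R_plus, state.C_plus)
    flux = hgt_flux(state, hgt)
    dSm, dRm, dSp, dRp, dCp, _ = flux
    P = state.R_plus + state.C_plus
    D = state.crispr_plus
    M = state.crispr_minus
    dP = dRp + dCp
    dD = dSp + dRp + dCp
    dM = dSm + dRm
    term_plus = (dP * D - P * dD) / D**2
    term_minus = (dRm * M - state.R_minus * dM) / M**2
    return float(term_plus - term_minus)


def sample_early_epidemic_states(n: int, rng: np.random.Generator,
                                 N0: float = 2e6,
                                 max_resistance: float = 1e-3,
                                 V: float = 1e4) -> list[PopulationState]:
    """Random rare-resistance states from the early-epidemic ensemble.

    Receptor mutation acts identically on both genetic backgrounds, so
    the mutant fraction of each sensitive pool is drawn once and shared;
    spacer acquisition adds a further protected fraction on the CRISPR+
    side only.  Total resistant+immune frequency stays below
    ``max_resistance``.
    """
    states = []
    for _ in range(n):
        crispr_freq = rng.uniform(0.1, 0.9)
        # shared per-capita mutant fraction; extra immune fraction on CRISPR+
        eps_mut = 10 ** rng.uniform(-6.5, np.log10(max_resistance / 4))
        eps_imm = 10 ** rng.uniform(-7.0, np.log10(max_resistance / 4))
        Nm = N0 * (1 - crispr_freq)
        Np = N0 * crispr_freq
        state = PopulationState(
            S_minus=Nm * (1 - eps_mut),
            R_minus=Nm * eps_mut,
            S_plus=Np * (1 - eps_mut - eps_imm),
            R_plus=Np * eps_mut,
            C_plus=Np * eps_imm,
            V=V,
        )
        states.append(state)
    return states
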