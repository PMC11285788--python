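"""Model-validation checks: the quantitative claims the pipeline must honour.

Each function recomputes one headline property of the model or pipeline
from scratch — nothing is cached or looked up — and returns plain
numbers.  They back both the validation test suite and the
``scripts/acceptance.py`` summary report.
"""

from __future__ import annotations

import numpy as np

from .model import (PopulationState, f_delta, f_delta_from_densities,
                    fig1_parameters)
from .dynamics import (IntegrationSettings, euler_integrate, fixation_check,
                       integrate_full, predict_experiment,
                       reduced_from_trajectory, sign_outcome)
from .hgt import HgtSettings, fdelta_hgt_flux, hgt_flux, sample_early_epidemic_states
from .experiment import build_initial_mixes, generate_dataset
from .inference import benjamini_hochberg, bootstrap_ci, sign_prediction_accuracy

__all__ = [
    "FIG1_MIX",
    "full_reduced_equivalence_error",
    "sign_law_agreement",
    "initial_frequency_sign_consistency",
    "no_phage_drift",
    "fixation_metrics",
    "cost_robustness_agreement",
    "euler_agreement",
    "hgt_rare_resistance_check",
    "recovery_study",
    "bh_step_up_error",
]

#: illustrative-scenario initial state: N(0)=1e6, V(0)=1e4, 50% CRISPR+,
#: protected fractions 0.30 (CRISPR+, half immune) vs 0.15 (CRISPR-),
#: so f_delta(0) = +0.15 with resistance present on both sides
FIG1_MIX = dict(S_minus=4.25e5, R_minus=0.75e5, S_plus=3.5e5,
                R_plus=0.75e5, C_plus=0.75e5)


def _fig1_state(V: float = 1e4) -> PopulationState:
    return PopulationState(**FIG1_MIX, V=V)


def full_reduced_equivalence_error() -> float:
    """Max relative gap between full-model N+(t) and the reduced equation.

    Cost- and mutation-free limit over 24 h; the reduced equation is
    driven by V(t) and f_delta(t) interpolated from the full run.
    """
    params = fig1_parameters(c_R=0.0)
    traj = integrate_full(_fig1_state(), params)
    _, n_reduced = reduced_from_trajectory(traj)
    return float(np.max(np.abs(n_reduced - traj.N_plus_freq) / traj.N_plus_freq))


def sign_law_agreement(n_mixes: int = 100, seed: int = 0,
                       min_abs_f_delta: float = 1e-3) -> tuple[float, int]:
    """Fraction of random cost-free mixes whose 24 h outcome matches sign(f_delta(0)).

    Mixes are Dirichlet-uniform over the five genotypes (resampled while
    |f_delta(0)| < ``min_abs_f_delta``, to stay clear of the measure-zero
    neutral boundary where the change is below solver resolution).
    """
    params = fig1_parameters(c_R=0.0)
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_mixes):
        while True:
            freqs = rng.dirichlet(np.ones(5))
            state = PopulationState.from_frequencies(freqs, 1e6, 1e4)
            fd0 = f_delta(state)
            if abs(fd0) >= min_abs_f_delta:
                break
        outcome = sign_outcome(state, params)
        agree += outcome == ("increase" if fd0 > 0 else "decrease")
    return agree / n_mixes, n_mixes


def initial_frequency_sign_consistency(
        frequencies=(0.01, 0.1, 0.5, 0.9)) -> tuple[float, int]:
    """Share of (protected-fraction pair, N+(0)) grids with one common outcome.

    Holds the within-subpopulation protected fractions fixed while the
    initial CRISPR+ frequency sweeps ``frequencies``; the direction of
    selection must not depend on it.
    """
    params = fig1_parameters(c_R=0.0)
    pairs = [(0.30, 0.15), (0.15, 0.30), (0.45, 0.05), (0.05, 0.45)]
    consistent = 0
    for protected_plus, resistant_minus in pairs:
        outcomes = set()
        for nf in frequencies:
            plus, minus = 1e6 * nf, 1e6 * (1 - nf)
            state = PopulationState(
                S_minus=minus * (1 - resistant_minus),
                R_minus=minus * resistant_minus,
                S_plus=plus * (1 - protected_plus),
                R_plus=plus * protected_plus / 2,
                C_plus=plus * protected_plus / 2,
                V=1e4)
            outcomes.add(sign_outcome(state, params))
        consistent += len(outcomes) == 1
    return consistent / len(pairs), len(pairs)


def no_phage_drift() -> float:
    """Max |N+(t) - N+(0)| over 24 h without phage, costs off (should be ~0)."""
    params = fig1_parameters(c_R=0.0)
    traj = integrate_full(_fig1_state(V=0.0), params)
    return float(np.max(np.abs(traj.N_plus_freq - traj.N_plus_freq[0])))


def fixation_metrics(t_end: float = 100.0) -> dict:
    """Long-horizon epidemic: sensitive collapse, residual f_delta, plateau."""
    traj = integrate_full(_fig1_state(), fig1_parameters(),
                          IntegrationSettings(t_end=t_end, n_points=1001))
    report = fixation_check(traj)
    return {
        "collapse_time_h": report.collapse_time,
        "abs_f_delta_end": abs(report.f_delta_end),
        "abs_dn_plus_dt_end": abs(report.dn_plus_dt_end),
        "plateau": report.plateau,
    }


def cost_robustness_agreement() -> tuple[float, int]:
    """Sign agreement of the +-phage response with f_delta(0), costs on.

    The six designed initial mixes, c_R=0.05 / c_I=0: the paired-arm
    relative change must still carry the sign of f_delta(0).
    """
    params = fig1_parameters()  # c_R=0.05
    mixes = build_initial_mixes()
    agree = sum(
        np.sign(predict_experiment(m.frequencies, 1e6, 1e4, params))
        == np.sign(m.f_delta0)
        for m in mixes)
    return agree / len(mixes), len(mixes)


def euler_agreement(dt: float = 1e-4) -> dict:
    """Adaptive solution vs fixed-step Euler at 24 h on the default scenario.

    Bacterial compartments are compared on the total-density scale and
    the CRISPR+ frequency directly.  The phage component is reported
    separately: forward Euler's own truncation error in V at dt=1e-4 is
    ~3e-4 (first order in dt), so it cross-checks at that level only.
    """
    params = fig1_parameters()
    state = _fig1_state()
    adaptive = integrate_full(state, params).final_state().as_array()
    euler = euler_integrate(state, params, 24.0, dt).as_array()
    scale = euler[:5].sum()
    bacterial_err = float(np.max(np.abs(adaptive[:5] - euler[:5]) / scale))
    n_plus = lambda y: (y[2] + y[3] + y[4]) / y[:5].sum()
    n_plus_err = float(abs(n_plus(adaptive) - n_plus(euler)) / n_plus(euler))
    v_err = float(abs(adaptive[5] - euler[5]) / euler[5])
    return {"bacterial_rel_err": bacterial_err, "n_plus_rel_err": n_plus_err,
            "phage_rel_err": v_err}


def hgt_rare_resistance_check(n_states: int = 100, seed: int = 0,
                              delta_t: float = 1e-6) -> dict:
    """Transfer flux on rare-resistance states: sign and oracle agreement.

    Early-epidemic ensemble (resistant+immune fraction < 1e-3, receptor
    mutants at the same per-capita frequency in both backgrounds, no
    spacer co-transfer): the analytic d(f_delta)/dt contribution must be
    <= 0 and match a central-difference transfer-only Euler step of
    ``delta_t`` hours.  The difference quotient carries a roundoff floor
    of ~1e-13/h (machine epsilon of f_delta over 2*delta_t), so relative
    disagreement is measured against max(|oracle|, 1e-9/h): deviations
    below the oracle's own resolution do not count.
    """
    params = fig1_parameters()
    hgt = HgtSettings(gamma=1e-9, spacer_transfer_fraction=0.0)
    rng = np.random.default_rng(seed)
    states = sample_early_epidemic_states(n_states, rng)
    nonpositive = 0
    worst_rel = 0.0
    for state in states:
        analytic = fdelta_hgt_flux(state, params, hgt)
        nonpositive += analytic <= 0
        y = state.as_array()
        flux = hgt_flux(state, hgt)
        fd = lambda z: f_delta_from_densities(*z[:5])
        numeric = (fd(y + delta_t * flux) - fd(y - delta_t * flux)) / (2 * delta_t)
        worst_rel = max(worst_rel,
                        abs(analytic - numeric) / max(abs(numeric), 1e-9))
    return {"fraction_nonpositive": nonpositive / n_states,
            "max_oracle_rel_err": float(worst_rel), "n": n_states}


def recovery_study(n_datasets: int = 200, seed: int = 0,
                   n_replicates: int = 6, n_boot: int = 1000) -> dict:
    """End-to-end effect recovery over many seeded synthetic datasets.

    For each dataset (6 conditions x ``n_replicates``, default noise):
    fit the response model, record whether the f_delta coefficient is
    positive with its bootstrap interval excluding zero, and score the
    per-replicate sign agreement between measured responses and the
    model predictions from the observed t0 mixes.
    """
    params = fig1_parameters()
    seeds = np.random.SeedSequence(seed).spawn(n_datasets)
    ci_hits = 0
    sign_hits = 0
    n_pairs = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        records, wide = generate_dataset(params=params,
                                         n_replicates=n_replicates, seed=rng)
        fit = bootstrap_ci(wide, n_boot=n_boot, seed=rng)
        lo, hi = fit.bootstrap_cis["f_delta0_obs"]
        ci_hits += fit.coef("f_delta0_obs") > 0 and lo > 0
        observed_t0 = {(r.condition_label, r.replicate): r.freqs_t0
                       for r in records if r.phage_added}
        predicted = [predict_experiment(observed_t0[(row.condition, row.replicate)],
                                        1e6, 1e4, params)
                     for row in wide.itertuples()]
        acc = sign_prediction_accuracy(predicted, wide["response"].to_numpy())
        sign_hits += acc * len(wide)
        n_pairs += len(wide)
    return {
        "ci_exclusion_rate": ci_hits / n_datasets,
        "sign_prediction_accuracy": sign_hits / n_pairs,
        "n_datasets": n_datasets,
        "n_pairs": n_pairs,
    }


def bh_step_up_error() -> float:
    """Max deviation of the BH adjustment from hand-applied step-up values."""
    cases = [
        (np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06]),
         np.full(6, 0.06)),
        (np.array([0.005, 0.04, 0.03, 0.9]),
         np.array([0.02, 4 * 0.04 / 3, 4 * 0.04 / 3, 0.9])),
        (np.array([0.5]), np.array([0.5])),
    ]
    worst = 0.0
    for p, expected in cases:
        worst = max(worst, float(np.max(np.abs(benjamini_hochberg(p) - expected))))
    return worst
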