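"""Synthetic competition-experiment generator.

Emulates the short-term evolution experiment: five tagged strains (one
per model genotype) mixed in six defined initial conditions, grown for
24 h with or without phage (10^4 pfu/ml), and genotype frequencies read
out at 0 h and 24 h by qPCR-like compositional measurement.

The six conditions cross the sign of the initial protected-fraction
contrast f_delta (positive / negative) with the ordering of immune vs
surface-resistant cells inside the CRISPR+ subpopulation
(C+ > R+, C+ = R+, C+ < R+).  Six replicate cultures per condition; the
two arms (phage / no phage) of a replicate are inoculated from the same
mixed culture, so they share the same (jittered) true initial mix.

Noise model:

* replicate-level pipetting variation: logistic-normal jitter of the
  true mix (independent log-normal factor per genotype, renormalised),
  sigma default 0.05;
* measurement error: Dirichlet resampling of the true composition with
  concentration kappa * truth, kappa default 200 — compositional noise
  with sd ~ sqrt(p(1-p)/kappa), the scale of qPCR frequency estimates.

Everything is driven by one seed through a numpy Generator, so a dataset
is byte-identical under the same seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    InvalidModelInput,
    ModelParameters,
    PopulationState,
    f_delta_from_densities,
)
from .dynamics import IntegrationSettings, integrate_full

__all__ = [
    "DesignParams",
    "NoiseSettings",
    "StrainMix",
    "CompetitionRecord",
    "CONDITION_LABELS",
    "GENOTYPES",
    "build_initial_mixes",
    "simulate_competition",
    "relative_change",
    "generate_dataset",
    "dataset_to_long",
    "load_long_dataset",
]

GENOTYPES = ("S_minus", "R_minus", "S_plus", "R_plus", "C_plus")

#: condition labels: sign of f_delta x ordering of C+ vs R+
CONDITION_LABELS = ("fpos_CgtR", "fpos_CeqR", "fpos_CltR",
                    "fneg_CgtR", "fneg_CeqR", "fneg_CltR")


@dataclass(frozen=True)
class DesignParams:
    """Initial-mix design.

    ``protected_high``/``protected_low`` are the protected fractions
    assigned to the CRISPR+ and CRISPR- subpopulations (swapped between
    the f_delta-positive and -negative conditions), so
    |f_delta(0)| = protected_high - protected_low (default 0.45 - 0.15
    = 0.3).  ``immune_ratios`` are the C+:R+ ratios for the three
    ordering levels (default 4:1, 1:1, 1:4).  ``crispr_freq0`` is the
    initial CRISPR+ frequency (default 0.5).
    """

    protected_high: float = 0.45
    protected_low: float = 0.15
    immune_ratios: tuple[float, float, float] = (4.0, 1.0, 0.25)
    crispr_freq0: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.protected_low < self.protected_high < 1:
            raise InvalidModelInput(
                "need 0 < protected_low < protected_high < 1, got "
                f"{self.protected_low}, {self.protected_high}")
        if not 0 < self.crispr_freq0 < 1:
            raise InvalidModelInput("crispr_freq0 must be in (0, 1)")
        if len(self.immune_ratios) != 3 or any(r <= 0 for r in self.immune_ratios):
            raise InvalidModelInput("immune_ratios must be three positive values")
        if not (self.immune_ratios[0] > self.immune_ratios[1] > self.immune_ratios[2]):
            raise InvalidModelInput(
                "immune_ratios must be strictly decreasing (C>R, C=R, C<R levels)")


@dataclass(frozen=True)
class NoiseSettings:
    """Measurement and replicate noise; ``None`` disables a component."""

    kappa: float | None = 200.0       # Dirichlet concentration of the qPCR read
    jitter_sigma: float | None = 0.05  # log-scale sd of the pipetting jitter

    def __post_init__(self) -> None:
        if self.kappa is not None and not self.kappa > 0:
            raise InvalidModelInput("kappa must be > 0 or None")
        if self.jitter_sigma is not None and not self.jitter_sigma >= 0:
            raise InvalidModelInput("jitter_sigma must be >= 0 or None")


@dataclass(frozen=True)
class StrainMix:
    """One experimental condition's intended initial genotype mix."""

    condition_label: str
    frequencies: tuple[float, float, float, float, float]  # genotype order
    f_delta0: float
    immune_resistant_ratio: float  # C+ / R+

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise InvalidModelInput(f"mix frequencies invalid: {f}")


@dataclass(frozen=True)
class CompetitionRecord:
    """One replicate arm: observed composition before and after 24 h."""

    condition_label: str
    replicate: int
    phage_added: bool
    freqs_t0: tuple[float, ...]
    freqs_t24: tuple[float, ...]
    total_cells_t24: float
    phage_titre_t24: float

    def __post_init__(self) -> None:
        for f in (self.freqs_t0, self.freqs_t24):
            arr = np.asarray(f)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise InvalidModelInput(f"observed frequencies invalid: {arr}")


def _mix_frequencies(crispr_freq: float, protected_plus: float,
                     resistant_minus: float, immune_ratio: float) -> np.ndarray:
    """Genotype frequencies from subpopulation-level design values."""
    w = immune_ratio / (1.0 + immune_ratio)  # immune share of protected CRISPR+
    plus = crispr_freq
    minus = 1.0 - crispr_freq
    f = np.array([
        minus * (1.0 - resistant_minus),        # S-
        minus * resistant_minus,                # R-
        plus * (1.0 - protected_plus),          # S+
        plus * protected_plus * (1.0 - w),      # R+
        plus * protected_plus * w,              # C+
    ])
    return f / f.sum()


def build_initial_mixes(design: DesignParams = DesignParams()) -> list[StrainMix]:
    """The six designed initial conditions (three f_delta>0, three <0)."""
    mixes = []
    for sign_label, (p_plus, p_minus) in (
            ("fpos", (design.protected_high, design.protected_low)),
            ("fneg", (design.protected_low, design.protected_high))):
        for ratio_label, ratio in zip(("CgtR", "CeqR", "CltR"),
                                      design.immune_ratios):
            f = _mix_frequencies(design.crispr_freq0, p_plus, p_minus, ratio)
            fd0 = f_delta_from_densities(*f)
            label = f"{sign_label}_{ratio_label}"
            expected_sign = 1.0 if sign_label == "fpos" else -1.0
            if np.sign(fd0) != expected_sign:
                raise InvalidModelInput(
                    f"design infeasible: condition {label} has f_delta0={fd0}")
            mixes.append(StrainMix(
                condition_label=label,
                frequencies=tuple(f),
                f_delta0=float(fd0),
                immune_resistant_ratio=float(f[4] / f[3]),
            ))
    return mixes


def _observe(freqs: np.ndarray, noise: NoiseSettings,
             rng: np.random.Generator) -> np.ndarray:
    """Apply Dirichlet compositional measurement noise to a true composition."""
    if noise.kappa is None:
        return freqs.copy()
    conc = noise.kappa * np.clip(freqs, 1e-12, None)
    obs = rng.dirichlet(conc)
    return obs / obs.sum()


def _jitter(freqs: np.ndarray, noise: NoiseSettings,
            rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal pipetting jitter on the true initial composition."""
    if noise.jitter_sigma is None or noise.jitter_sigma == 0:
        return freqs.copy()
    pert = freqs * np.exp(rng.normal(0.0, noise.jitter_sigma, size=freqs.size))
    return pert / pert.sum()


def simulate_competition(mix: StrainMix, params: ModelParameters,
                         N0: float = 1e6, V0: float = 1e4,
                         noise: NoiseSettings = NoiseSettings(),
                         rng: np.random.Generator | int | None = None,
                         replicate: int = 0,
                         settings: IntegrationSettings = IntegrationSettings(),
                         ) -> tuple[CompetitionRecord, CompetitionRecord]:
    """One replicate of one condition: paired phage / no-phage arms.

    Both arms start from the same jittered true mix (they are inoculated
    from one culture), and the t0 composition is measured once and
    shared; each arm's t24 composition carries independent measurement
    noise.  Returns ``(phage_record, no_phage_record)``.
    """
    rng = np.random.default_rng(rng)
    true0 = _jitter(np.asarray(mix.frequencies), noise, rng)
    obs0 = _observe(true0, noise, rng)

    records = []
    for phage_added in (True, False):
        initial = PopulationState.from_frequencies(
            true0, N0, V0 if phage_added else 0.0)
        traj = integrate_full(initial, params, settings)
        final = traj.states[:, -1]
        true24 = final[:5] / final[:5].sum()
        obs24 = _observe(true24, noise, rng)
        records.append(CompetitionRecord(
            condition_label=mix.condition_label,
            replicate=replicate,
            phage_added=phage_added,
            freqs_t0=tuple(obs0),
            freqs_t24=tuple(obs24),
            total_cells_t24=float(final[:5].sum()),
            phage_titre_t24=float(final[5]),
        ))
    return records[0], records[1]


def _crispr_freq(freqs: Sequence[float]) -> float:
    f = np.asarray(freqs)
    return float(f[2] + f[3] + f[4])


def relative_change(record_pair: tuple[CompetitionRecord, CompetitionRecord]
                    ) -> float:
    """Response variable: (N+ with phage - N+ without) / N+ without, at 24 h."""
    phage, blank = record_pair
    if phage.condition_label != blank.condition_label \
            or phage.replicate != blank.replicate:
        raise InvalidModelInput("records are not a matched (condition, replicate) pair")
    if not phage.phage_added or blank.phage_added:
        raise InvalidModelInput("pair must be (phage arm, no-phage arm)")
    denom = _crispr_freq(blank.freqs_t24)
    if denom == 0:
        raise InvalidModelInput("no-phage CRISPR+ frequency is 0; response undefined")
    return (_crispr_freq(phage.freqs_t24) - denom) / denom


def generate_dataset(design: DesignParams = DesignParams(),
                     params: ModelParameters | None = None,
                     noise: NoiseSettings = NoiseSettings(),
                     n_replicates: int = 6,
                     seed: int | np.random.Generator = 0,
                     N0: float = 1e6, V0: float = 1e4,
                     settings: IntegrationSettings = IntegrationSettings(),
                     ) -> tuple[list[CompetitionRecord], pd.DataFrame]:
    """Full synthetic dataset: 6 conditions x n_replicates x 2 arms.

    Returns the flat record list and a wide per-replicate table with one
    row per (condition, replicate) carrying the designed f_delta0 and
    immune:resistant ratio, the observed-at-t0 predictor values, and the
    response.  Predictor columns:

    ``f_delta0_obs``, ``immune_fraction_obs`` (C+/(C+ + R+)),
    ``immune_resistant_ratio_obs`` (C+/R+), ``initial_crispr_freq_obs``
    — all computed from the measured t0 composition, as in the real
    experiment, alongside their designed (noise-free) counterparts.
    """
    from .model import fig1_parameters
    if params is None:
        params = fig1_parameters()
    if n_replicates < 2:
        raise InvalidModelInput("need n_replicates >= 2")
    rng = np.random.default_rng(seed)
    mixes = build_initial_mixes(design)
    records: list[CompetitionRecord] = []
    rows = []
    for mix in mixes:
        for rep in range(n_replicates):
            pair = simulate_competition(
                mix, params, N0=N0, V0=V0, noise=noise, rng=rng,
                replicate=rep, settings=settings)
            records.extend(pair)
            obs0 = np.asarray(pair[0].freqs_t0)
            plus = obs0[2] + obs0[3] + obs0[4]
            rows.append({
                "condition": mix.condition_label,
                "replicate": rep,
                "f_delta0_design": mix.f_delta0,
                "immune_resistant_ratio_design": mix.immune_resistant_ratio,
                "f_delta0_obs": f_delta_from_densities(*obs0),
                "immune_resistant_ratio_obs": float(obs0[4] / obs0[3]),
                "immune_fraction_obs": float(obs0[4] / (obs0[3] + obs0[4])),
                "initial_crispr_freq_obs": float(plus),
                "response": relative_change(pair),
            })
    return records, pd.DataFrame(rows)


def dataset_to_long(records: list[CompetitionRecord]) -> pd.DataFrame:
    """Long-format table: one row per record x genotype."""
    rows = []
    for rec in records:
        for i, g in enumerate(GENOTYPES):
            rows.append({
                "condition": rec.condition_label,
                "replicate": rec.replicate,
                "phage_added": rec.phage_added,
                "genotype": g,
                "freq_t0": rec.freqs_t0[i],
                "freq_t24": rec.freqs_t24[i],
                "total_cells_t24": rec.total_cells_t24,
                "phage_titre_t24": rec.phage_titre_t24,
            })
    return pd.DataFrame(rows)


def load_long_dataset(path_or_frame) -> list[CompetitionRecord]:
    """Rebuild records from the long CSV shape (also fits external data)."""
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame)
    required = {"condition", "replicate", "phage_added", "genotype",
                "freq_t0", "freq_t24"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidModelInput(f"dataset missing columns: {sorted(missing)}")
    records = []
    keys = ["condition", "replicate", "phage_added"]
    for (cond, rep, phage), grp in df.groupby(keys, sort=False):
        grp = grp.set_index("genotype").loc[list(GENOTYPES)]
        records.append(CompetitionRecord(
            condition_label=str(cond),
            replicate=int(rep),
            phage_added=bool(phage),
            freqs_t0=tuple(grp["freq_t0"]),
            freqs_t24=tuple(grp["freq_t24"]),
            total_cells_t24=float(grp["total_cells_t24"].iloc[0])
            if "total_cells_t24" in grp else np.nan,
            phage_titre_t24=float(grp["phage_titre_t24"].iloc[0])
            if "phage_titre_t24" in grp else np.nan,
        ))
    return records
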