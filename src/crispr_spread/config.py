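"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` gathers every stage's settings in one validated
document (YAML or JSON).  Unknown keys are rejected with the offending
field path; omitted fields take the documented defaults, so a minimal
config only needs a seed.  All randomness flows from that one seed
through named per-stage substreams (`numpy` ``SeedSequence.spawn``), so
a rerun with the same config is byte-identical for every deterministic
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .model import ModelParameters, PopulationState, fig1_parameters
from .dynamics import IntegrationSettings, integrate_full, predict_experiment
from .hgt import HgtSettings
from .experiment import (DesignParams, NoiseSettings, build_initial_mixes,
                         dataset_to_long, generate_dataset)
from .inference import (baseline_tests, bootstrap_ci,
                        expected_baseline_directions, fit_glm,
                        sign_prediction_accuracy)

__all__ = ["RunConfig", "load_config", "dump_config", "run_pipeline"]

log = logging.getLogger("crispr_spread")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ModelBlock(_Block):
    r: float = 0.5
    K: float = 1e9
    m_b: float = 0.0
    m_v: float = 0.0
    alpha: float = 1e-9
    B: float = 100.0
    mu: float = 0.0
    A: float = 0.0
    c_R: float = 0.05
    c_I: float = 0.0

    def build(self) -> ModelParameters:
        return ModelParameters(**self.model_dump())


class IntegrationBlock(_Block):
    rel_tol: float = 1e-8
    abs_tol: float = 1e-2
    t_end: float = 24.0
    n_points: int = 241
    clip_negative: bool = True
    fixation_threshold: float = 1.0

    def build(self) -> IntegrationSettings:
        return IntegrationSettings(**self.model_dump())


class HgtBlock(_Block):
    gamma: float = 0.0
    spacer_transfer_fraction: float = 0.0

    def build(self) -> HgtSettings:
        return HgtSettings(**self.model_dump())


class ExperimentBlock(_Block):
    protected_high: float = 0.45
    protected_low: float = 0.15
    immune_ratios: tuple[float, float, float] = (4.0, 1.0, 0.25)
    crispr_freq0: float = 0.5
    n_replicates: int = Field(default=6, ge=2)
    N0: float = 1e6
    V0: float = 1e4
    noise_kappa: float | None = 200.0
    jitter_sigma: float | None = 0.05

    def design(self) -> DesignParams:
        return DesignParams(protected_high=self.protected_high,
                            protected_low=self.protected_low,
                            immune_ratios=tuple(self.immune_ratios),
                            crispr_freq0=self.crispr_freq0)

    def noise(self) -> NoiseSettings:
        return NoiseSettings(kappa=self.noise_kappa,
                             jitter_sigma=self.jitter_sigma)


class InferenceBlock(_Block):
    n_boot: int = Field(default=10_000, ge=1000)
    ci_level: float = 0.95
    fdr_alpha: float = 0.05
    #: encode immune-vs-resistant as bounded fraction C+/(C++R+) or raw ratio
    immune_predictor: str = Field(default="fraction", pattern="^(fraction|ratio)$")


class RunConfig(_Block):
    seed: int = Field(ge=0, lt=2**31)
    out_dir: str = "results/run"
    model: ModelBlock = ModelBlock()
    integration: IntegrationBlock = IntegrationBlock()
    hgt: HgtBlock | None = None
    experiment: ExperimentBlock = ExperimentBlock()
    inference: InferenceBlock = InferenceBlock()

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; defaults filled, unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        # re-raise with compact field paths for the CLI
        paths = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid config {path}: {paths}") from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def _spawn_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Emulate -> predict -> fit, writing all artifacts under ``out_dir``.

    Writes the long and wide dataset CSVs, the baseline-test table, the
    fit JSON and a metrics JSON; every artifact records the seed, config
    hash and package version.  Returns the metrics dict.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stamp = {"seed": config.seed, "config_hash": config.config_hash(),
             "version": __version__}
    try:
        params = config.model.build()
        settings = config.integration.build()
        exp = config.experiment
        rng_data, rng_boot = _spawn_seeds(config.seed, 2)

        log.info("stage=emulate generating %d replicates x 6 conditions",
                 exp.n_replicates)
        records, wide = generate_dataset(
            design=exp.design(), params=params, noise=exp.noise(),
            n_replicates=exp.n_replicates, seed=rng_data,
            N0=exp.N0, V0=exp.V0, settings=settings)
        dataset_to_long(records).to_csv(out / "dataset_long.csv", index=False)

        log.info("stage=predict per-replicate model predictions from observed t0")
        preds = []
        for _, row in wide.iterrows():
            rec0 = next(r for r in records
                        if r.condition_label == row["condition"]
                        and r.replicate == row["replicate"] and r.phage_added)
            preds.append(predict_experiment(rec0.freqs_t0, exp.N0, exp.V0,
                                            params, settings))
        wide = wide.assign(predicted_response=preds)
        wide.to_csv(out / "dataset_wide.csv", index=False)
        accuracy = sign_prediction_accuracy(wide["predicted_response"],
                                            wide["response"])

        log.info("stage=baseline no-phage drift tests")
        no_phage = []
        for rec in records:
            if not rec.phage_added:
                f0 = sum(rec.freqs_t0[2:5])
                f24 = sum(rec.freqs_t24[2:5])
                no_phage.append({"condition": rec.condition_label,
                                 "replicate": rec.replicate,
                                 "baseline_deviation": f24 - f0})
        baseline = baseline_tests(
            pd.DataFrame(no_phage),
            directions=expected_baseline_directions(exp.design(), params),
            alpha=config.inference.fdr_alpha)
        baseline.to_csv(out / "baseline_tests.csv", index=False)

        log.info("stage=fit GLM with %d bootstrap draws", config.inference.n_boot)
        immune_col = ("immune_fraction_obs"
                      if config.inference.immune_predictor == "fraction"
                      else "immune_resistant_ratio_obs")
        predictors = ("f_delta0_obs", immune_col, "initial_crispr_freq_obs")
        fit = bootstrap_ci(wide, predictors=predictors,
                           n_boot=config.inference.n_boot, seed=rng_boot,
                           level=config.inference.ci_level)
        with open(out / "fit.json", "w") as fh:
            json.dump({**stamp, **fit.to_dict()}, fh, indent=2)

        metrics = {
            **stamp,
            "n_records": len(records),
            "sign_prediction_accuracy": accuracy,
            "glm_coefficients": dict(zip(fit.predictors,
                                         fit.coefficients.tolist())),
            "glm_adj_r_squared": fit.adj_r_squared,
            "glm_f_statistic": fit.f_statistic,
            "glm_f_pvalue": fit.f_pvalue,
            "bootstrap_cis": {k: list(v) for k, v in fit.bootstrap_cis.items()},
            "baseline_significant": dict(zip(baseline["condition"],
                                             baseline["significant"].astype(bool))),
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        log.info("pipeline complete: accuracy=%.3f", accuracy)
        return metrics
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
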