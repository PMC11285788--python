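"""Statistical stage: baseline drift tests, linear model, bootstrap, validation.

The analysis of a competition dataset has three parts:

1. **Baseline tests.**  Without phage the model predicts no change in
   CRISPR+ frequency, so the no-phage responses are tested per condition
   against zero with one-tailed one-sample t-tests, corrected across
   conditions by the Benjamini–Hochberg step-up rule.

2. **Linear model.**  The response (relative change in CRISPR+ frequency,
   phage vs no-phage arm) is regressed on the initial protected-fraction
   contrast f_delta(0), the composition of the protected CRISPR+ cells
   (immune vs surface-resistant), and the initial CRISPR+ frequency.
   Ordinary least squares is computed directly via a QR decomposition —
   coefficients, standard errors, adjusted R^2 and the overall F-test —
   with nonparametric case-resampling bootstrap percentile intervals.
   The immune-vs-resistant predictor defaults to the bounded immune
   fraction C+/(C+ + R+); the raw ratio C+/R+ is also accepted.

3. **Validation.**  Per-replicate sign agreement between the model's
   predicted response (from observed initial frequencies) and the
   measured response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import InvalidModelInput

__all__ = [
    "FitResult",
    "fit_glm",
    "bootstrap_ci",
    "benjamini_hochberg",
    "baseline_tests",
    "expected_baseline_directions",
    "sign_prediction_accuracy",
    "DEFAULT_PREDICTORS",
]

#: default design-matrix columns for the response model
DEFAULT_PREDICTORS = ("f_delta0_obs", "immune_fraction_obs",
                      "initial_crispr_freq_obs")


@dataclass
class FitResult:
    """OLS fit summary with optional bootstrap intervals."""

    predictors: tuple[str, ...]          # includes "intercept" first
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int
    bootstrap_cis: dict[str, tuple[float, float]] | None = None
    bootstrap_redraws: int = 0

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.predictors.index(name)])

    def to_dict(self) -> dict:
        d = {
            "predictors": list(self.predictors),
            "coefficients": self.coefficients.tolist(),
            "std_errors": self.std_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
        }
        if self.bootstrap_cis is not None:
            d["bootstrap_cis"] = {k: list(v) for k, v in self.bootstrap_cis.items()}
            d["bootstrap_redraws"] = self.bootstrap_redraws
        return d


def _design_matrix(table: pd.DataFrame, predictors: tuple[str, ...],
                   response: str) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    missing = [c for c in (*predictors, response) if c not in table.columns]
    if missing:
        raise InvalidModelInput(f"table missing columns: {missing}")
    sub = table[[*predictors, response]]
    if sub.isna().any().any():
        raise InvalidModelInput("table contains missing values")
    X = np.column_stack([np.ones(len(sub)),
                         *[sub[c].to_numpy(float) for c in predictors]])
    y = sub[response].to_numpy(float)
    return X, y, ("intercept", *predictors)


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise InvalidModelInput(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """QR-based least squares; returns (beta, (X'X)^-1 diagonal, rss)."""
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    Rinv = np.linalg.solve(R, np.eye(R.shape[0]))
    xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)
    return beta, xtx_inv_diag, rss


def fit_glm(table: pd.DataFrame,
            response: str = "response",
            predictors: tuple[str, ...] = DEFAULT_PREDICTORS) -> FitResult:
    """Ordinary least squares of ``response`` on ``predictors`` + intercept."""
    X, y, names = _design_matrix(table, tuple(predictors), response)
    n, p = X.shape
    if n <= p:
        raise InvalidModelInput(f"need n_obs > {p}, got {n}")
    _check_rank(X, names)
    beta, xtx_inv_diag, rss = _ols(X, y)
    df_resid = n - p
    df_model = p - 1
    sigma2 = rss / df_resid
    se = np.sqrt(sigma2 * xtx_inv_diag)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    if rss > 0 and df_model > 0:
        f_stat = ((tss - rss) / df_model) / sigma2
        f_p = float(stats.f.sf(f_stat, df_model, df_resid))
    else:
        f_stat, f_p = np.inf, 0.0
    return FitResult(
        predictors=names, coefficients=beta, std_errors=se, t_values=tvals,
        p_values=pvals, r_squared=r2, adj_r_squared=adj_r2,
        f_statistic=float(f_stat), f_pvalue=f_p,
        df_model=df_model, df_resid=df_resid, n_obs=n)


def bootstrap_ci(table: pd.DataFrame,
                 response: str = "response",
                 predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
                 n_boot: int = 10_000,
                 seed: int | np.random.Generator = 0,
                 level: float = 0.95,
                 max_redraws: int = 100) -> FitResult:
    """Case-resampling bootstrap percentile intervals around the OLS fit.

    Rows are resampled with replacement ``n_boot`` times; a resample
    whose design matrix is rank deficient is redrawn (the count is
    reported on the result).  Deterministic under ``seed``.
    """
    if n_boot < 1000:
        raise InvalidModelInput("need n_boot >= 1000 for stable percentile intervals")
    if not 0 < level < 1:
        raise InvalidModelInput("level must be in (0, 1)")
    fit = fit_glm(table, response=response, predictors=predictors)
    X, y, names = _design_matrix(table, tuple(predictors), response)
    rng = np.random.default_rng(seed)
    n = len(y)
    p = X.shape[1]
    betas = np.empty((n_boot, p))
    redraws = 0
    for b in range(n_boot):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
            if np.linalg.matrix_rank(Xb) == p:
                break
            redraws += 1
        else:
            raise InvalidModelInput(
                "could not draw a full-rank bootstrap resample")
        betas[b] = np.linalg.lstsq(Xb, yb, rcond=None)[0]
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    cis = {name: (float(np.percentile(betas[:, j], lo)),
                  float(np.percentile(betas[:, j], hi)))
           for j, name in enumerate(names)}
    fit.bootstrap_cis = cis
    fit.bootstrap_redraws = redraws
    return fit


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or np.any((p < 0) | (p > 1)):
        raise InvalidModelInput("pvalues must be a 1-d vector in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def expected_baseline_directions(design=None, params=None) -> dict[str, str]:
    """One-tailed drift directions for the no-phage baseline, per condition.

    Without phage the CRISPR+ frequency drifts according to the cost
    burden of each subpopulation: it rises ('greater') when the mean
    growth cost carried by CRISPR+ cells (c_R on surface mutants, c_I on
    immune cells) is below the CRISPR- burden (c_R on its mutants), and
    falls ('less') otherwise.  Equal burdens give a 'two-sided' test.
    """
    from .experiment import DesignParams, build_initial_mixes
    from .model import fig1_parameters
    design = design or DesignParams()
    params = params or fig1_parameters()
    directions = {}
    for mix in build_initial_mixes(design):
        f = np.asarray(mix.frequencies)
        minus, plus = f[0] + f[1], f[2] + f[3] + f[4]
        cost_minus = params.c_R * f[1] / minus
        cost_plus = (params.c_R * f[3] + params.c_I * f[4]) / plus
        if np.isclose(cost_plus, cost_minus):
            directions[mix.condition_label] = "two-sided"
        else:
            directions[mix.condition_label] = (
                "greater" if cost_plus < cost_minus else "less")
    return directions


def baseline_tests(no_phage: pd.DataFrame,
                   value: str = "baseline_deviation",
                   condition: str = "condition",
                   directions: dict[str, str] | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-condition one-tailed t-tests of no-phage drift, BH-corrected.

    ``no_phage`` has one row per replicate with the deviation of the
    no-phage CRISPR+ frequency change from zero.  ``directions`` maps
    condition to 'greater' / 'less' (the tested tail); conditions absent
    from the map are tested 'two-sided'.  Returns a table with t, raw p,
    BH-adjusted p and the rejection flag at ``alpha``.
    """
    if directions is None:
        directions = expected_baseline_directions()
    rows = []
    for cond, grp in no_phage.groupby(condition, sort=True):
        x = grp[value].to_numpy(float)
        if x.size < 2:
            raise InvalidModelInput(f"condition {cond}: need >= 2 replicates")
        alternative = directions.get(cond, "two-sided")
        if np.std(x) == 0:
            # degenerate sample: identically zero is a clean null (t=0,
            # one-tailed p=1/2); identically nonzero has no defined t
            if x[0] != 0:
                raise InvalidModelInput(
                    f"condition {cond}: zero variance in deviations")
            t, p = 0.0, 0.5 if alternative != "two-sided" else 1.0
        else:
            t, p = stats.ttest_1samp(x, 0.0, alternative=alternative)
        rows.append({"condition": cond, "n": x.size, "mean_deviation": x.mean(),
                     "t": float(t), "p_value": float(p),
                     "alternative": alternative})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out


def sign_prediction_accuracy(predicted, observed,
                             dead_band: float = 1e-6) -> float:
    """Fraction of paired replicates with agreeing response signs.

    Values within ``dead_band`` of zero count as sign 0; a pair agrees
    when the two (dead-banded) signs are equal.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise InvalidModelInput(
            f"length mismatch: {pred.shape} predictions vs {obs.shape} observations")
    def banded_sign(x):
        s = np.sign(x)
        s[np.abs(x) < dead_band] = 0.0
        return s
    return float(np.mean(banded_sign(pred) == banded_sign(obs)))
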