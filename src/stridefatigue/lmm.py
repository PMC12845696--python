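"""Random-intercept mixed models per feature and standardized effect sizes.

For a feature value :math:`y_{ij}` of stride *i* in participant *j* the
model is

.. math:: y_{ij} = \\beta_0 + \\beta_1 \\, \\mathrm{Fatigue}_{ij} + u_{0j} + \\varepsilon_{ij},

with :math:`u_{0j} \\sim N(0, \\sigma_u^2)` participant intercepts and
:math:`\\varepsilon_{ij} \\sim N(0, \\sigma^2)` residuals, fitted by REML.
The effect-size layer derives Cohen's d (|beta_1| / sigma), the
Nakagawa-Schielzeth marginal and conditional R^2, and the partial R^2 of
the fatigue term from its Wald statistic,

.. math:: R^2_\\mathrm{partial} = z^2 / (z^2 + \\mathrm{df}),

where df approximates the effective residual degrees of freedom (default:
the total number of strides in the model, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class LmmFit:
    """One fitted random-intercept model for a single feature."""

    feature: str
    beta0: float
    beta1: float
    se0: float
    se1: float
    z: float
    pvalue: float
    ci_low: float
    ci_high: float
    group_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    converged: bool


@dataclass
class EffectSizeReport:
    feature: str
    cohen_d: float
    r2_marginal: float
    r2_conditional: float
    r2_partial: float
    df: float


def fit_random_intercept_model(table: pd.DataFrame, feature: str) -> LmmFit:
    """REML fit of the random-intercept fatigue model for one feature column.

    Unequal per-participant stride counts are handled naturally by the
    hierarchical structure.  A single-participant table is refused (the
    random intercept is not identifiable) and non-convergence is flagged on
    the result, never silently swallowed.
    """
    for col in ("participant", "condition", feature):
        if col not in table.columns:
            raise KeyError(f"feature table lacks column {col!r}")
    data = table[["participant", "condition", feature]].dropna()
    groups = data["participant"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("mixed model requires at least 2 participants")
    cond = data["condition"].to_numpy(float)
    if len(np.unique(cond)) < 2:
        raise ValueError("both conditions (NF and F) must be present")
    y = data[feature].to_numpy(float)
    exog = sm.add_constant(cond)

    model = sm.MixedLM(y, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence reported via the flag below
        result = model.fit(reml=True)

    beta0, beta1 = result.fe_params
    se0, se1 = np.asarray(result.bse_fe)
    ci = result.conf_int().to_numpy() if hasattr(result.conf_int(), "to_numpy") else np.asarray(result.conf_int())
    return LmmFit(
        feature=feature,
        beta0=float(beta0),
        beta1=float(beta1),
        se0=float(se0),
        se1=float(se1),
        z=float(beta1 / se1),
        pvalue=float(result.pvalues[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        group_var=float(np.asarray(result.cov_re)[0, 0]),
        resid_var=float(result.scale),
        n_obs=int(len(y)),
        n_groups=int(len(np.unique(groups))),
        converged=bool(result.converged),
    )


def cohen_d(fit: LmmFit) -> float:
    """Standardized fatigue effect |beta_1| / sigma (reported as a magnitude)."""
    if fit.resid_var <= 0:
        raise ValueError("residual variance must be positive")
    return abs(fit.beta1) / np.sqrt(fit.resid_var)


def r2_marginal_conditional(
    sigma_fixed2: float, sigma_group2: float, sigma_resid2: float
) -> tuple[float, float]:
    """Nakagawa-Schielzeth marginal and conditional R^2 from variance components."""
    if min(sigma_fixed2, sigma_group2, sigma_resid2) < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_fixed2 + sigma_group2 + sigma_resid2
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma_fixed2 / total, (sigma_fixed2 + sigma_group2) / total


def partial_r2(z: float, df: float) -> float:
    """Variance uniquely attributable to fatigue: z^2 / (z^2 + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return z**2 / (z**2 + df)


def effect_sizes(fit: LmmFit, condition: np.ndarray, df: float | None = None) -> EffectSizeReport:
    """Derive all standardized effect sizes from one fitted model.

    ``condition`` is the observed 0/1 design column, used for the
    fixed-effect predictor variance in the marginal R^2.  ``df`` defaults to
    the total number of strides in the model.
    """
    cond = np.asarray(condition, float)
    sigma_fixed2 = float(np.var(fit.beta0 + fit.beta1 * cond))
    r2m, r2c = r2_marginal_conditional(sigma_fixed2, fit.group_var, fit.resid_var)
    df_eff = float(fit.n_obs) if df is None else float(df)
    return EffectSizeReport(
        feature=fit.feature,
        cohen_d=cohen_d(fit),
        r2_marginal=r2m,
        r2_conditional=r2c,
        r2_partial=partial_r2(fit.z, df_eff),
        df=df_eff,
    )


def effects_table(
    table: pd.DataFrame, features: list[str], df: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every requested feature and tabulate coefficients and effect sizes.

    Per-feature failures are isolated: the failing feature gets an ``error``
    entry and the remaining features are still processed.  Returns the
    effects table and a forest-plot export (point estimate + 95% CI per
    feature).
    """
    rows, forest = [], []
    for feature in features:
        try:
            fit = fit_random_intercept_model(table, feature)
            cond = table.loc[table[feature].notna(), "condition"].to_numpy(float)
            es = effect_sizes(fit, cond, df=df)
        except Exception as exc:  # noqa: BLE001 - isolate per-feature failures
            rows.append({"feature": feature, "error": str(exc)})
            continue
        rows.append(
            {
                "feature": feature,
                "beta_fatigue": fit.beta1,
                "std_err": fit.se1,
                "z": fit.z,
                "p_value": fit.pvalue,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "group_var": fit.group_var,
                "resid_var": fit.resid_var,
                "n_obs": fit.n_obs,
                "n_groups": fit.n_groups,
                "converged": fit.converged,
                "cohen_d": es.cohen_d,
                "r2_marginal": es.r2_marginal,
                "r2_conditional": es.r2_conditional,
                "r2_partial": es.r2_partial,
                "df": es.df,
            }
        )
        forest.append(
            {
                "feature": feature,
                "estimate": fit.beta1,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(forest)
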