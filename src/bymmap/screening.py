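"""Pre-modelling covariate screen.

Each candidate covariate is tested in a univariate Poisson regression of
stratum case counts with a log-expected offset; covariates significant at
the chosen level are ranked by BIC, and pairwise Pearson correlations flag
collinearity among them.  Fits go through statsmodels' IRLS GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ScreenResult:
    name: str
    coef: float
    se: float
    p_value: float
    bic: float
    loglik: float
    selected: bool
    flag: str = ""


def poisson_glm(y, offset, x, alpha: float = 0.05, name: str = "x") -> ScreenResult:
    """Univariate Poisson regression with log-expected offset.

    BIC is -2*loglik + p*log(n) with p = 2 (intercept + slope); the Wald
    p-value tests the slope against zero.
    """
    y = np.asarray(y, dtype=float)
    offset = np.asarray(offset, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (len(y) == len(offset) == len(x)):
        raise ValueError("y, offset and x must have equal length")
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if y.sum() == 0:
        raise ValueError("all-zero counts: Poisson regression is degenerate")
    if np.ptp(x) == 0:
        return ScreenResult(name, float("nan"), float("nan"), float("nan"),
                            float("nan"), float("nan"), False,
                            flag="constant covariate: slope inestimable")

    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    try:
        fit = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise RuntimeError(f"Poisson IRLS failed for {name!r}: {exc}") from exc
    if not fit.converged:
        raise RuntimeError(f"Poisson IRLS did not converge in 100 iterations for {name!r}")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    bic = -2.0 * float(fit.llf) + 2.0 * np.log(len(y))
    return ScreenResult(name, coef, se, p, bic, float(fit.llf), p < alpha)


def poisson_loglik(y, offset, x, intercept: float, slope: float) -> float:
    """Direct Poisson log-likelihood (including the log y! term)."""
    from scipy.special import gammaln

    y = np.asarray(y, dtype=float)
    mu = np.exp(np.asarray(offset) + intercept + slope * np.asarray(x))
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def pearson_collinearity(covariates: pd.DataFrame, threshold: float = 0.8):
    """Pairwise Pearson correlations; |r| above threshold is flagged.

    Zero-variance columns get undefined (NaN) correlations and a flag
    instead of a silent zero.
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if covariates.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    corr = covariates.corr(method="pearson")
    degenerate = [c for c in covariates.columns if covariates[c].std(ddof=0) == 0]
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    flagged = []
    cols = list(covariates.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                flagged.append((a, b, float("nan"), "undefined (zero variance)"))
            elif abs(r) >= threshold:
                flagged.append((a, b, float(r), f"|r| >= {threshold}"))
    return corr, flagged


def screen_covariates(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Run the univariate screen over every covariate column.

    ``table`` is a stratum table with expected counts filled; ``covariates``
    holds area_id plus one column per candidate.  Returns one row per
    covariate (coefficient, SE, p, BIC, selected), sorted by BIC among the
    selected set first.
    """
    if (table.loc[table["cases"] > 0, "expected"] <= 0).any():
        raise ValueError("strata with cases need positive expected counts")
    merged = table.merge(covariates, on="area_id", how="left")
    y = merged["cases"].to_numpy(float)
    off = np.log(np.maximum(merged["expected"].to_numpy(float), 1e-300))
    results = []
    names = [c for c in covariates.columns if c != "area_id"]
    # age and sex enter the screen as the model's indicator codings
    merged["age_gt60"] = (merged["age_group"] == "gt60").astype(float)
    merged["sex_male"] = (merged["sex"] == "male").astype(float)
    for nm in ["age_gt60", "sex_male"] + names:
        results.append(poisson_glm(y, off, merged[nm].to_numpy(float), alpha, nm))
    df = pd.DataFrame([r.__dict__ for r in results])
    return df.sort_values(["selected", "bic"], ascending=[False, True]).reset_index(drop=True)
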