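"""Posterior summaries, convergence diagnostics, DIC and significance maps.

Coefficients are reported both on the log scale and as relative risks; RR
summaries are computed on the exponentiated draws (posterior mean of
exp(beta), not exp of the posterior mean — by Jensen's inequality the
former is never smaller).  A covariate is flagged significant when the RR's
equal-tailed 95% credible interval excludes 1.  Per-area random effects are
classified for mapping: "high" when the 5th posterior percentile is above
zero, "low" when the 95th is below zero, otherwise "none".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import (
    MCMCOutput,
    ModelData,
    ModelSpec,
    MCMCState,
    deviance as _deviance_at,
    psrf,
)


def gelman_rubin(output: MCMCOutput, params=None) -> pd.Series:
    """Potential scale reduction factor per parameter (NaN where the
    within-chain variance is zero)."""
    if len(output.chains) < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    if output.n_draws < 10:
        raise ValueError("chains too short for a PSRF")
    names = list(params) if params is not None else list(output.param_names)
    vals = {}
    for name in names:
        seqs = output.column(name)
        if all(np.var(c) == 0 for c in seqs) and np.var([c.mean() for c in seqs]) == 0:
            vals[name] = 1.0
            continue
        vals[name] = psrf(seqs)
    return pd.Series(vals, name="psrf")


@dataclass(frozen=True)
class DICReport:
    dbar: float
    d_at_mean: float
    n_excluded: int = 0

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        return self.dbar + self.pd

    def as_dict(self) -> dict:
        return {"Dbar": self.dbar, "D_at_mean": self.d_at_mean,
                "pD": self.pd, "DIC": self.dic}


def dic(output: MCMCOutput, table, graph=None, covariates=None) -> DICReport:
    """Deviance information criterion.

    Dbar is the posterior mean of the recorded deviance (-2 log likelihood);
    D_at_mean re-evaluates the deviance at the posterior mean of the full
    parameter vector, random effects included.  pD = Dbar - D_at_mean and
    DIC = Dbar + pD.  Non-finite deviance draws are excluded with a count.
    """
    if output.n_draws == 0:
        raise ValueError("no retained draws")
    dev = output.stacked("deviance")
    finite = np.isfinite(dev)
    dbar = float(dev[finite].mean())

    data = ModelData(table, output.spec, graph, covariates)
    mean_of = lambda name: float(output.stacked(name).mean())
    state = MCMCState(
        alpha=mean_of("alpha"),
        beta=np.array([mean_of(n) for n in data.coef_names]),
        u=output.area_draws("u").mean(axis=0),
        s=output.area_draws("s").mean(axis=0),
        sigma2_u=mean_of("sigma2_u"),
        sigma2_s=mean_of("sigma2_s"),
        zip_pi=mean_of("zip_pi"),
        z=np.zeros(data.m, dtype=bool),
    )
    d_at_mean = float(_deviance_at(state, data))
    return DICReport(dbar, d_at_mean, int((~finite).sum()))


def summarize(output: MCMCOutput, params=None) -> pd.DataFrame:
    """Posterior means and equal-tailed 95% CrIs; coefficients additionally
    get RR summaries from the exponentiated draws and a significance flag
    (RR CrI excludes 1)."""
    if output.n_draws == 0:
        raise ValueError("no retained draws")
    names = list(params) if params is not None else list(output.param_names)
    rows = []
    for name in names:
        draws = output.stacked(name)
        row = {
            "parameter": name,
            "mean": float(draws.mean()),
            "cri_low": float(np.quantile(draws, 0.025)),
            "cri_high": float(np.quantile(draws, 0.975)),
        }
        if name.startswith("beta"):
            rr = np.exp(draws)
            row["rr_mean"] = float(rr.mean())
            row["rr_cri_low"] = float(np.quantile(rr, 0.025))
            row["rr_cri_high"] = float(np.quantile(rr, 0.975))
            row["significant"] = bool(
                row["rr_cri_low"] > 1.0 or row["rr_cri_high"] < 1.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_areas(output: MCMCOutput) -> pd.DataFrame:
    """Per-area posterior means of u and s with three-way significance
    classes from the 5%/95% posterior quantiles (for choropleth export)."""
    rows = []
    for which in ("u", "s"):
        mat = output.area_draws(which)
        q05 = np.quantile(mat, 0.05, axis=0)
        q95 = np.quantile(mat, 0.95, axis=0)
        cls = np.where(q05 > 0, "high", np.where(q95 < 0, "low", "none"))
        rows.append(
            pd.DataFrame(
                {
                    "area_id": list(output.area_ids),
                    f"{which}_mean": mat.mean(axis=0),
                    f"{which}_q05": q05,
                    f"{which}_q95": q95,
                    f"{which}_class": cls,
                }
            )
        )
    return rows[0].merge(rows[1], on="area_id")


def diagnostics_report(output: MCMCOutput) -> str:
    """Plain-text convergence/acceptance report."""
    lines = [
        f"chains: {len(output.chains)}  draws/chain: {output.n_draws}",
        f"burn-in: {output.burn_in}  thin: {output.thin}  batches: {output.n_batches}",
        f"converged: {output.converged}",
    ]
    if output.n_draws >= 10:
        gr = gelman_rubin(output, params=output.scalar_params)
        lines.append("PSRF (scalar parameters):")
        for k, v in gr.items():
            lines.append(f"  {k}: {v:.4f}")
    for ci, acc in enumerate(output.acceptance):
        pretty = ", ".join(f"{k}={v:.2f}" for k, v in acc.items())
        lines.append(f"chain {ci} acceptance: {pretty}")
    return "\n".join(lines)
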