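"""Metropolis-within-Gibbs sampler for areal convolution models.

The likelihood is a log-linear Poisson (optionally zero-inflated) model for
stratified case counts O_ikl with expected-count offset E_ikl:

    O_ikl ~ Poisson(mu_ikl),  log mu_ikl = log E_ikl + theta_ikl
    theta_ikl = alpha + beta_age * 1{age>60} + beta_sex * 1{male}
                + beta . x_i + u_i + s_i

with u_i iid N(0, sigma2_u) (exchangeable heterogeneity) and s_i an
intrinsic-CAR structured effect whose full conditional given its neighbours
is N(mean of neighbours, sigma2_s / n_i).  Priors follow the convolution
disease-mapping convention: flat intercept, N(0, precision 1e-4)
coefficients, Gamma(0.001, 0.001) on both precisions, and Beta(1, 1) on the
zero-inflation weight.

Sampling: random-walk Metropolis for alpha, each beta, and the random
effects (the Poisson likelihood breaks conjugacy); exact conjugate Gibbs for
the two precisions and for the ZIP indicators/weight.  Random-effect
Metropolis steps are vectorised — u_i are conditionally independent, and s_i
are updated simultaneously within colour classes of the adjacency graph,
inside which no two areas are neighbours.  After every sweep the structured
effect is recentred to sum to zero with the intercept absorbing the shift
(an exactly posterior-invariant move on graphs without isolated areas; with
islands it is applied as a Metropolis move with the islands' likelihood
ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .adjacency import AdjacencyGraph, components

logger = logging.getLogger(__name__)

SCALAR_PARAMS_BASE = ("alpha",)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the standard vague prior set."""

    beta_mean: float = 0.0
    beta_precision: float = 1e-4
    tau_shape: float = 0.001
    tau_rate: float = 0.001
    zip_a: float = 1.0
    zip_b: float = 1.0

    def __post_init__(self):
        if self.beta_precision <= 0 or self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("prior precisions/shapes/rates must be positive")
        if self.zip_a <= 0 or self.zip_b <= 0:
            raise ValueError("beta prior parameters must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Model family and random-effect structure.

    effects: "unstructured" (exchangeable u only), "structured" (ICAR s
    only) or "both" (the convolution model).  Reference levels are fixed:
    age <=60 and female sex.
    """

    family: str = "poisson"
    effects: str = "both"
    covariates: tuple = ()
    include_age: bool = True
    include_sex: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.family not in ("poisson", "zip"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.effects not in ("unstructured", "structured", "both"):
            raise ValueError(f"unknown effects structure {self.effects!r}")

    @property
    def has_u(self) -> bool:
        return self.effects in ("unstructured", "both")

    @property
    def has_s(self) -> bool:
        return self.effects in ("structured", "both")


class ModelData:
    """Preprocessed design: counts, offsets, covariate matrix, graph bookkeeping."""

    def __init__(self, table: pd.DataFrame, spec: ModelSpec,
                 graph: AdjacencyGraph | None = None,
                 covariates: pd.DataFrame | None = None):
        if spec.has_s and graph is None:
            raise ValueError("structured effects require an adjacency graph")
        tab = table.reset_index(drop=True)
        if ((tab["expected"] <= 0) & (tab["cases"] > 0)).any():
            raise ValueError("strata with cases must have positive expected counts")
        dropped = int((tab["expected"] <= 0).sum())
        if dropped:
            logger.info("dropping %d strata with non-positive expected counts", dropped)
            tab = tab[tab["expected"] > 0].reset_index(drop=True)

        if graph is not None:
            self.area_ids = tuple(graph.area_ids)
            unknown = set(tab["area_id"]) - set(self.area_ids)
            if unknown:
                raise ValueError(f"areas absent from adjacency graph: {sorted(unknown)[:5]}")
        else:
            self.area_ids = tuple(pd.unique(tab["area_id"]))
        self.m = len(self.area_ids)
        idx = {a: i for i, a in enumerate(self.area_ids)}
        self.area_idx = tab["area_id"].map(idx).to_numpy(int)

        self.y = tab["cases"].to_numpy(float)
        self.logE = np.log(tab["expected"].to_numpy(float))
        self.logfact = gammaln(self.y + 1.0)
        self.n_strata = len(tab)

        cols, names = [], []
        if spec.include_age:
            cols.append((tab["age_group"] == "gt60").to_numpy(float))
            names.append("beta_age")
        if spec.include_sex:
            cols.append((tab["sex"] == "male").to_numpy(float))
            names.append("beta_sex")
        if spec.covariates:
            if covariates is None:
                raise ValueError("spec names covariates but none were supplied")
            merged = tab[["area_id"]].merge(covariates, on="area_id", how="left")
            for c in spec.covariates:
                if c not in merged.columns:
                    raise ValueError(f"covariate {c!r} missing from covariate table")
                v = merged[c].to_numpy(float)
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"covariate {c!r} has non-finite values")
                cols.append(v)
                names.append(f"beta_{c}")
        self.X = np.column_stack(cols) if cols else np.empty((self.n_strata, 0))
        self.coef_names = tuple(names)
        self.p = len(names)

        self.y_area = np.bincount(self.area_idx, weights=self.y, minlength=self.m)
        self.area_all_zero = self.y_area == 0

        self.spec = spec
        self.graph = graph
        if graph is not None:
            self.n_i = graph.n_i
            self.island = self.n_i == 0
            self.constrained = ~self.island
            self.W = graph.to_sparse()
            all_classes = graph.colour_classes()
            self.colours = [c[~self.island[c]] for c in all_classes]
            self.colours = [c for c in self.colours if len(c)]
            edges = np.array(list(graph.edges()), dtype=int).reshape(-1, 2)
            self.edge_i, self.edge_j = edges[:, 0], edges[:, 1]
            n_multi = sum(1 for comp in components(graph) if len(comp) > 1)
            self.icar_rank = int(self.constrained.sum()) - n_multi
        else:
            self.island = np.zeros(self.m, dtype=bool)
            self.constrained = np.ones(self.m, dtype=bool)

        # strata belonging to island areas (for the recentring Metropolis move)
        self.island_strata = np.flatnonzero(self.island[self.area_idx])


@dataclass
class MCMCState:
    """Current parameter values plus the derived per-stratum caches."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    s: np.ndarray
    sigma2_u: float
    sigma2_s: float
    zip_pi: float
    z: np.ndarray  # per-area structural-zero indicators (ZIP only)
    eta: np.ndarray | None = None  # log mu per stratum
    mu: np.ndarray | None = None

    def copy(self) -> "MCMCState":
        return MCMCState(
            self.alpha, self.beta.copy(), self.u.copy(), self.s.copy(),
            self.sigma2_u, self.sigma2_s, self.zip_pi, self.z.copy(),
            None if self.eta is None else self.eta.copy(),
            None if self.mu is None else self.mu.copy(),
        )


def initial_state(data: ModelData, rng: np.random.Generator,
                  jitter: float = 0.0) -> MCMCState:
    """Overdispersed start: alpha at the pooled log(sum O / sum E), jittered."""
    total_e = float(np.exp(data.logE).sum())
    base = np.log(max(data.y.sum(), 0.5) / total_e)
    st = MCMCState(
        alpha=base + (rng.normal(0.0, 0.5) * jitter if jitter else 0.0),
        beta=rng.normal(0.0, 0.25 * jitter, data.p) if jitter else np.zeros(data.p),
        u=rng.normal(0.0, 0.1 * jitter, data.m) if jitter else np.zeros(data.m),
        s=np.zeros(data.m),
        sigma2_u=1.0,
        sigma2_s=1.0,
        zip_pi=0.5 if data.spec.family == "zip" else 0.0,
        z=np.zeros(data.m, dtype=bool),
    )
    if jitter and data.spec.has_s:
        st.s = rng.normal(0.0, 0.1 * jitter, data.m)
        st.s[data.island] = 0.0
        st.s[data.constrained] -= st.s[data.constrained].mean()
    refresh(st, data)
    return st


def refresh(state: MCMCState, data: ModelData) -> None:
    """Recompute the eta/mu caches exactly from the parameters."""
    theta = state.alpha + data.X @ state.beta + state.u[data.area_idx] + state.s[data.area_idx]
    state.eta = data.logE + theta
    state.mu = np.exp(state.eta)


def linear_predictor(state: MCMCState, data: ModelData):
    """Per-stratum log relative risk theta and Poisson mean mu = E*exp(theta)."""
    theta = state.alpha + data.X @ state.beta + state.u[data.area_idx] + state.s[data.area_idx]
    return theta, np.exp(data.logE + theta)


def _active_weight(state: MCMCState, data: ModelData) -> np.ndarray:
    """Per-stratum 0/1 weight: strata of structurally-zero areas drop out."""
    if data.spec.family == "zip" and state.z.any():
        return (~state.z[data.area_idx]).astype(float)
    return np.ones(data.n_strata)


def loglik(state: MCMCState, data: ModelData) -> float:
    """Observed-data log likelihood (ZIP indicators integrated out).

    Poisson: sum(O log mu - mu - log O!).  ZIP: per area,
    log[pi0 * 1{all O = 0} + (1 - pi0) * prod Poisson].
    """
    _, mu = linear_predictor(state, data)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(data.y > 0, data.y * np.log(mu), 0.0) - mu - data.logfact
    if np.any((mu == 0) & (data.y > 0)):
        return -np.inf
    if data.spec.family == "poisson":
        return float(term.sum())
    ll_area = np.bincount(data.area_idx, weights=term, minlength=data.m)
    pi0 = state.zip_pi
    out = 0.0
    log1m = np.log1p(-pi0) if pi0 < 1 else -np.inf
    for i in range(data.m):
        if data.area_all_zero[i]:
            out += np.logaddexp(
                np.log(pi0) if pi0 > 0 else -np.inf, log1m + ll_area[i]
            )
        else:
            out += log1m + ll_area[i]
    return float(out)


def deviance(state: MCMCState, data: ModelData) -> float:
    return -2.0 * loglik(state, data)


# --- Metropolis / Gibbs updates ---------------------------------------------


def update_fixed_effects(state, data, tuning, rng, *, loglik_fn=None,
                         likelihood_on=True, sample_alpha=True):
    """One random-walk Metropolis step for alpha and for each coefficient.

    ``loglik_fn`` (state -> float) replaces the Poisson likelihood when
    given — used to validate the sampler against conjugate cases.  With the
    likelihood off, alpha is skipped (its flat prior is improper).
    """
    pri = data.spec.priors
    accepted = {}
    act = _active_weight(state, data)

    def beta_logprior(b):
        return -0.5 * pri.beta_precision * (b - pri.beta_mean) ** 2

    if loglik_fn is not None:
        blocks = ([("alpha", None)] if sample_alpha else []) + [
            (data.coef_names[j], j) for j in range(data.p)
        ]
        for name, j in blocks:
            prop = state.copy()
            d = rng.normal(0.0, tuning[name])
            lp0 = loglik_fn(state) + (0.0 if j is None else beta_logprior(state.beta[j]))
            if j is None:
                prop.alpha += d
            else:
                prop.beta[j] += d
            refresh(prop, data)
            lp1 = loglik_fn(prop) + (0.0 if j is None else beta_logprior(prop.beta[j]))
            ok = np.isfinite(lp1) and np.log(rng.random()) < lp1 - lp0
            if ok:
                state.alpha, state.beta = prop.alpha, prop.beta
                state.eta, state.mu = prop.eta, prop.mu
            accepted[name] = bool(ok)
        return accepted

    if sample_alpha and likelihood_on:
        d = rng.normal(0.0, tuning["alpha"])
        dll = d * float(act @ data.y) - np.expm1(d) * float(act @ state.mu)
        ok = np.log(rng.random()) < dll
        if ok:
            state.alpha += d
            state.eta += d
            state.mu *= np.exp(d)
        accepted["alpha"] = bool(ok)

    for j, name in enumerate(data.coef_names):
        d = rng.normal(0.0, tuning[name])
        xj = data.X[:, j]
        if likelihood_on:
            dll = d * float(act @ (data.y * xj)) - float(
                act @ (state.mu * np.expm1(d * xj))
            )
        else:
            dll = 0.0
        dlp = beta_logprior(state.beta[j] + d) - beta_logprior(state.beta[j])
        ok = np.log(rng.random()) < dll + dlp
        if ok:
            state.beta[j] += d
            state.eta += d * xj
            state.mu *= np.exp(d * xj)
        accepted[name] = bool(ok)
    return accepted


def _area_loglik_delta(state, data, d_area, likelihood_on):
    """Likelihood change per area when its random effect moves by d_area."""
    if not likelihood_on:
        return np.zeros(data.m)
    dlam = state.mu * np.expm1(d_area[data.area_idx])
    dll = d_area * data.y_area - np.bincount(
        data.area_idx, weights=dlam, minlength=data.m
    )
    if data.spec.family == "zip" and state.z.any():
        dll[state.z] = 0.0  # structurally-zero areas contribute no likelihood
    return dll


def update_unstructured(state, data, tuning, rng, *, likelihood_on=True) -> float:
    """Vectorised Metropolis step for every u_i (iid N(0, sigma2_u) prior)."""
    d = rng.normal(0.0, tuning["u"], data.m)
    dll = _area_loglik_delta(state, data, d, likelihood_on)
    dlp = -0.5 / state.sigma2_u * ((state.u + d) ** 2 - state.u**2)
    acc = np.log(rng.random(data.m)) < dll + dlp
    du = np.where(acc, d, 0.0)
    state.u += du
    state.eta += du[data.area_idx]
    state.mu *= np.exp(du[data.area_idx])
    return float(acc.mean())


def update_structured(state, data, tuning, rng, *, likelihood_on=True) -> float:
    """Metropolis step for s, colour class by colour class, targeting the
    ICAR full conditional N(neighbour mean, sigma2_s/n_i) times the area
    likelihood; finishes with the sum-to-zero recentring move."""
    n_acc, n_tot = 0, 0
    for cls in data.colours:
        d = np.zeros(data.m)
        d[cls] = rng.normal(0.0, tuning["s"], len(cls))
        dll = _area_loglik_delta(state, data, d, likelihood_on)
        nbsum = np.asarray(data.W @ state.s)
        ni = data.n_i.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            nbmean = np.where(ni > 0, nbsum / np.maximum(ni, 1), 0.0)
        dlp = -0.5 * ni / state.sigma2_s * (
            (state.s + d - nbmean) ** 2 - (state.s - nbmean) ** 2
        )
        acc = np.log(rng.random(len(cls))) < dll[cls] + dlp[cls]
        take = cls[acc]
        ds = np.zeros(data.m)
        ds[take] = d[take]
        state.s += ds
        state.eta += ds[data.area_idx]
        state.mu *= np.exp(ds[data.area_idx])
        n_acc += int(acc.sum())
        n_tot += len(cls)
    recentre_structured(state, data, rng, likelihood_on=likelihood_on)
    return n_acc / max(n_tot, 1)


def recentre_structured(state, data, rng, *, likelihood_on=True) -> bool:
    """Shift (alpha, s) -> (alpha + c, s - c) with c = mean(s) over the
    constrained areas.  The posterior density is invariant under the shift
    except for isolated areas' likelihood (their s is pinned at 0), so with
    islands present the move is accepted with the islands' likelihood ratio.
    """
    if not data.spec.has_s or not data.constrained.any():
        return False
    c = float(state.s[data.constrained].mean())
    if c == 0.0:
        return True
    if data.island_strata.size and likelihood_on:
        idx = data.island_strata
        act = _active_weight(state, data)[idx]
        dll = c * float(act @ data.y[idx]) - np.expm1(c) * float(act @ state.mu[idx])
        if not np.log(rng.random()) < dll:
            return False
        state.eta[idx] += c
        state.mu[idx] *= np.exp(c)
    state.alpha += c
    state.s[data.constrained] -= c
    return True


def update_precisions(state, data, rng, *, update_u=True, update_s=True) -> None:
    """Exact conjugate Gibbs draws for the random-effect precisions:

    tau_u ~ Gamma(a + m/2, b + sum(u^2)/2)
    tau_s ~ Gamma(a + rank(Q)/2, b + sum over edges (s_i - s_j)^2 / 2)
    """
    pri = data.spec.priors
    if update_u and data.spec.has_u:
        shape = pri.tau_shape + data.m / 2.0
        rate = pri.tau_rate + float(state.u @ state.u) / 2.0
        state.sigma2_u = 1.0 / rng.gamma(shape, 1.0 / rate)
    if update_s and data.spec.has_s:
        diffs = state.s[data.edge_i] - state.s[data.edge_j]
        shape = pri.tau_shape + data.icar_rank / 2.0
        rate = pri.tau_rate + float(diffs @ diffs) / 2.0
        state.sigma2_s = 1.0 / rng.gamma(shape, 1.0 / rate)


def update_zip(state, data, rng, *, likelihood_on=True) -> None:
    """Gibbs draw of the structural-zero indicators and the mixture weight.

    Only all-zero areas are eligible; their indicator odds are
    pi0 : (1 - pi0) * exp(-sum of the area's Poisson means).
    """
    pri = data.spec.priors
    if likelihood_on:
        mu_area = np.bincount(data.area_idx, weights=state.mu, minlength=data.m)
        p_pois = (1.0 - state.zip_pi) * np.exp(-np.minimum(mu_area, 700.0))
        p1 = np.where(
            data.area_all_zero, state.zip_pi / (state.zip_pi + p_pois), 0.0
        )
    else:
        # prior sampling: no data constraint, every indicator is Bern(pi0)
        p1 = np.full(data.m, state.zip_pi)
    state.z = rng.random(data.m) < p1
    n1 = int(state.z.sum())
    state.zip_pi = float(rng.beta(pri.zip_a + n1, pri.zip_b + data.m - n1))


# --- diagnostics helper (shared with inference summaries) --------------------


def psrf(sequences) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    sqrt(((n-1)/n * W + B/n) / W) over >=2 equal-length chains; returns NaN
    when the within-chain variance is zero (flagged, not divided).
    """
    chains = [np.asarray(c, dtype=float) for c in sequences]
    if len(chains) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n = len(chains[0])
    if any(len(c) != n for c in chains) or n < 10:
        raise ValueError("chains must have equal length >= 10")
    W = float(np.mean([c.var(ddof=1) for c in chains]))
    means = np.array([c.mean() for c in chains])
    B = n * float(means.var(ddof=1))
    if W == 0.0:
        return float("nan") if B > 0 else 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


# --- driver -------------------------------------------------------------------


@dataclass
class MCMCOutput:
    """Retained multi-chain draws with bookkeeping."""

    param_names: tuple
    chains: list  # list of (n_draws, n_params) arrays
    burn_in: int
    thin: int
    acceptance: list  # per-chain dict of mean acceptance rates
    seeds: tuple
    converged: bool
    n_batches: int
    spec: ModelSpec
    area_ids: tuple
    scalar_params: tuple

    @property
    def n_draws(self) -> int:
        return 0 if not self.chains else self.chains[0].shape[0]

    def column(self, name: str) -> list:
        j = self.param_names.index(name)
        return [c[:, j] for c in self.chains]

    def stacked(self, name: str) -> np.ndarray:
        return np.concatenate(self.column(name)) if self.chains else np.array([])

    def to_frames(self) -> list:
        return [pd.DataFrame(c, columns=list(self.param_names)) for c in self.chains]

    def area_draws(self, which: str) -> np.ndarray:
        """(total_draws, m) matrix of u or s draws across all chains."""
        cols = [f"{which}[{a}]" for a in self.area_ids]
        idx = [self.param_names.index(c) for c in cols]
        return np.concatenate([c[:, idx] for c in self.chains], axis=0)


class _ChainRunner:
    def __init__(self, data: ModelData, rng: np.random.Generator,
                 likelihood_on: bool, hold: frozenset, sample_alpha: bool):
        self.data = data
        self.rng = rng
        self.likelihood_on = likelihood_on
        self.hold = hold
        self.sample_alpha = sample_alpha and likelihood_on
        self.state = initial_state(data, rng, jitter=1.0 if likelihood_on else 0.0)
        # held random-effect blocks stay pinned at their neutral value
        if "u" in hold:
            self.state.u[:] = 0.0
        if "s" in hold:
            self.state.s[:] = 0.0
        refresh(self.state, data)
        names = ["alpha"] + list(data.coef_names) + ["u", "s"]
        self.tuning = {n: 0.1 if not n.startswith(("u", "s")) else 0.5 for n in names}
        self.acc_totals = {n: [0, 0] for n in self.tuning}

    def sweep(self, adapt: bool):
        d, st, rng = self.data, self.state, self.rng
        acc = {}
        if "fixed" not in self.hold:
            a = update_fixed_effects(
                st, d, self.tuning, rng,
                likelihood_on=self.likelihood_on, sample_alpha=self.sample_alpha,
            )
            acc.update({k: float(v) for k, v in a.items()})
        if d.spec.has_u and "u" not in self.hold:
            acc["u"] = update_unstructured(st, d, self.tuning, rng,
                                           likelihood_on=self.likelihood_on)
        if d.spec.has_s and "s" not in self.hold:
            acc["s"] = update_structured(st, d, self.tuning, rng,
                                         likelihood_on=self.likelihood_on)
        if "precisions" not in self.hold:
            update_precisions(st, d, rng)
        if d.spec.family == "zip" and "zip" not in self.hold:
            update_zip(st, d, rng, likelihood_on=self.likelihood_on)
        refresh(st, d)
        for k, v in acc.items():
            self.acc_totals.setdefault(k, [0, 0])
            self.acc_totals[k][0] += v
            self.acc_totals[k][1] += 1
        if adapt:
            for k, v in acc.items():
                # nudge each proposal scale toward the 0.2-0.4 acceptance band
                self.tuning[k] = float(
                    np.clip(self.tuning[k] * np.exp(0.5 * (v - 0.3)), 1e-4, 50.0)
                )

    def record_row(self) -> np.ndarray:
        st, d = self.state, self.data
        row = [st.alpha, *st.beta, st.sigma2_u, st.sigma2_s, st.zip_pi,
               *st.u, *st.s, deviance(st, d)]
        return np.asarray(row)

    def acceptance_rates(self) -> dict:
        return {k: (t[0] / t[1] if t[1] else float("nan"))
                for k, t in self.acc_totals.items()}


def param_names_for(data: ModelData) -> tuple:
    return tuple(
        ["alpha"] + list(data.coef_names)
        + ["sigma2_u", "sigma2_s", "zip_pi"]
        + [f"u[{a}]" for a in data.area_ids]
        + [f"s[{a}]" for a in data.area_ids]
        + ["deviance"]
    )


def run_mcmc(
    spec: ModelSpec,
    table: pd.DataFrame,
    graph: AdjacencyGraph | None = None,
    covariates: pd.DataFrame | None = None,
    *,
    chains: int = 3,
    burn_in: int = 10_000,
    iterations: int = 15_000,
    max_batches: int = 3,
    seed: int | None = None,
    thin: int = 1,
    psrf_threshold: float = 1.1,
    prior_only: bool = False,
    hold: tuple = (),
) -> MCMCOutput:
    """Fit the model by Metropolis-within-Gibbs.

    Proposal scales adapt during burn-in only (targeting the 0.2-0.4
    acceptance band).  After burn-in, batches of ``iterations`` sweeps are
    retained (thinned by ``thin``) and the Gelman-Rubin PSRF of the scalar
    parameters is checked after each batch; sampling stops early once all
    fall below ``psrf_threshold``, and the output is flagged non-converged
    if they never do within ``max_batches`` batches.  ``prior_only``
    switches the likelihood off (and pins the intercept, whose flat prior
    cannot be sampled) so marginals can be validated against the priors.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for Gelman-Rubin diagnostics")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    data = ModelData(table, spec, graph, covariates)
    names = param_names_for(data)

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    seeds = tuple(int(c.generate_state(1)[0] % (2**31)) for c in child)
    runners = [
        _ChainRunner(data, np.random.default_rng(s), not prior_only,
                     frozenset(hold), sample_alpha=True)
        for s in seeds
    ]

    scalars = ["alpha"] + list(data.coef_names) + ["deviance"]
    if data.spec.has_u:
        scalars.append("sigma2_u")
    if data.spec.has_s:
        scalars.append("sigma2_s")
    if data.spec.family == "zip":
        scalars.append("zip_pi")
    if prior_only:
        scalars = [s for s in scalars if s not in ("alpha", "deviance")]

    if iterations <= 0:
        return MCMCOutput(names, [np.empty((0, len(names))) for _ in range(chains)],
                          burn_in, thin, [r.acceptance_rates() for r in runners],
                          seeds, False, 0, spec, data.area_ids, tuple(scalars))

    for r in runners:
        for _ in range(burn_in):
            r.sweep(adapt=True)
        r.acc_totals = {k: [0, 0] for k in r.acc_totals}

    draws: list[list[np.ndarray]] = [[] for _ in runners]
    converged = False
    batch = 0
    while batch < max_batches and not converged:
        batch += 1
        for ci, r in enumerate(runners):
            for it in range(iterations):
                r.sweep(adapt=False)
                if it % thin == 0:
                    draws[ci].append(r.record_row())
        mats = [np.vstack(dc) for dc in draws]
        worst = 0.0
        for pname in scalars:
            j = names.index(pname)
            val = psrf([m[:, j] for m in mats])
            if np.isnan(val):
                continue
            worst = max(worst, val)
        converged = worst < psrf_threshold
        logger.info("batch %d: worst scalar PSRF %.4f (%s)", batch, worst,
                    "converged" if converged else "continuing")
    if not converged:
        logger.warning("MCMC flagged non-converged after %d batches", batch)

    return MCMCOutput(
        names, [np.vstack(dc) for dc in draws], burn_in, thin,
        [r.acceptance_rates() for r in runners], seeds, converged, batch,
        spec, data.area_ids, tuple(scalars),
    )
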