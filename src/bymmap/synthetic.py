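"""Truth-tagged synthetic areal cohorts.

Generates stratified screening-cohort count data with the structure the
spatial models assume: a lattice of areas, two age groups (<=60 / >60) by
two sexes per area, a rare outcome, area-level continuous covariates, and
log-linear relative risks built from fixed effects plus an exchangeable
(iid normal) and an intrinsic-CAR spatially structured random effect,
optionally zero-inflated at the area level.  Every generated dataset
carries the parameters that produced it, so recovery can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph, components, lattice_polygons, make_lattice

logger = logging.getLogger(__name__)

AGE_GROUPS = ("le60", "gt60")
SEXES = ("female", "male")

STRATUM_COLUMNS = ["area_id", "age_group", "sex", "participants", "cases", "expected"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a synthetic cohort.

    ``beta_true`` lists the log-relative-risk coefficients in model order:
    age (>60 vs <=60), sex (male vs female), then one per continuous
    area-level covariate.  ``baseline_rate`` is the marginal case fraction
    used to form the expected-count offset E = N * baseline_rate; the
    defaults mirror a large rare-outcome screening cohort (case fraction
    0.36%) at desk scale.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    alpha_true: float = 0.0
    beta_true: tuple = (1.08, 0.93)
    sigma2_u_true: float = 0.25
    sigma2_s_true: float = 1.0
    zero_inflation_pi: float = 0.0
    baseline_rate: float = 0.0036
    pop_low: int = 50
    pop_high: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.grid_rows * self.grid_cols < 4:
            raise ValueError("need at least 4 areas")
        if not (0 <= self.zero_inflation_pi <= 1):
            raise ValueError("zero_inflation_pi must lie in [0, 1]")
        if not (0 < self.baseline_rate < 1):
            raise ValueError("baseline_rate must lie in (0, 1)")
        if self.pop_low > self.pop_high or self.pop_low < 1:
            raise ValueError("require 1 <= pop_low <= pop_high")
        if self.sigma2_u_true < 0 or self.sigma2_s_true < 0:
            raise ValueError("variances must be non-negative")
        if len(self.beta_true) < 2:
            raise ValueError("beta_true needs at least age and sex coefficients")

    @property
    def n_continuous(self) -> int:
        return len(self.beta_true) - 2


@dataclass
class SyntheticDataset:
    stratum_table: pd.DataFrame
    adjacency: AdjacencyGraph
    covariates: pd.DataFrame  # area_id + x1..xk columns
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def area_ids(self) -> tuple:
        return self.adjacency.area_ids


def sample_icar(
    adjacency: AdjacencyGraph,
    sigma2_s: float,
    seed=None,
    *,
    centre_components: bool = False,
) -> np.ndarray:
    """Draw the spatially structured effect from the intrinsic CAR prior.

    The ICAR density is the improper Gaussian kernel exp(-s'Qs / (2*sigma2))
    with Q the graph Laplacian.  Sampling goes through the spectral
    decomposition of Q: coordinates along null eigenvectors (one per
    connected component, including islands) are set to zero, which is
    exactly the sum-to-zero constraint applied per component, and the
    remaining coordinates are independent N(0, sigma2/lambda_k).

    A disconnected graph is rejected unless ``centre_components`` is set,
    since the constraint is then a per-component choice the caller must own.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma2_s <= 0:
        raise ValueError("sigma2_s must be positive")
    comps = components(adjacency)
    if len(comps) > 1 and not centre_components:
        sizes = sorted(len(c) for c in comps)
        raise ValueError(
            f"graph has {len(comps)} connected components (sizes {sizes}); "
            "pass centre_components=True to centre each component separately"
        )
    Q = adjacency.laplacian()
    w, V = np.linalg.eigh(Q)
    keep = w > 1e-9 * max(w.max(), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    s = V[:, keep] @ (z / np.sqrt(w[keep])) * np.sqrt(sigma2_s)
    # numerical guard: project out any residual component-mean drift
    for comp in comps:
        idx = [adjacency.index_of(a) for a in comp]
        if len(idx) > 1:
            s[idx] -= s[idx].mean()
        else:
            s[idx] = 0.0
    return s


def icar_pseudo_covariance(adjacency: AdjacencyGraph, sigma2_s: float) -> np.ndarray:
    """Dense Moore-Penrose covariance sigma2 * Q^+ of the constrained ICAR.

    Brute-force reference for validating :func:`sample_icar`; O(m^3), meant
    for small graphs.
    """
    Q = adjacency.laplacian()
    return sigma2_s * np.linalg.pinv(Q, hermitian=True)


def _design_rows(area_ids, covariates: pd.DataFrame):
    """Cartesian (area x age x sex) frame in canonical order."""
    rows = []
    for aid in area_ids:
        for age in AGE_GROUPS:
            for sex in SEXES:
                rows.append((aid, age, sex))
    df = pd.DataFrame(rows, columns=["area_id", "age_group", "sex"])
    return df.merge(covariates, on="area_id", how="left")


def simulate_counts(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from the log-linear convolution model.

    For every area i and stratum (age k, sex l): participants N_ikl are
    uniform on [pop_low, pop_high]; the offset is E_ikl = N_ikl *
    baseline_rate; the log relative risk is theta = alpha + beta_age*1{k=gt60}
    + beta_sex*1{l=male} + beta_x . x_i + u_i + s_i; counts are Poisson with
    mean E*exp(theta), resampled if they exceed N (rare by construction).
    With probability zero_inflation_pi an area is structurally zero: all of
    its four strata report zero cases regardless of the Poisson mean.
    """
    rng = np.random.default_rng(config.seed)
    graph = make_lattice(config.grid_rows, config.grid_cols)
    m = graph.n_areas
    ids = list(graph.area_ids)

    cov = pd.DataFrame({"area_id": ids})
    for k in range(config.n_continuous):
        cov[f"x{k + 1}"] = rng.standard_normal(m)

    u = (
        rng.normal(0.0, np.sqrt(config.sigma2_u_true), m)
        if config.sigma2_u_true > 0
        else np.zeros(m)
    )
    s = (
        sample_icar(graph, config.sigma2_s_true, rng)
        if config.sigma2_s_true > 0
        else np.zeros(m)
    )
    structural_zero = rng.random(m) < config.zero_inflation_pi

    frame = _design_rows(ids, cov)
    area_idx = frame["area_id"].map({a: i for i, a in enumerate(ids)}).to_numpy()
    beta = np.asarray(config.beta_true, dtype=float)
    theta = (
        config.alpha_true
        + beta[0] * (frame["age_group"] == "gt60").to_numpy(float)
        + beta[1] * (frame["sex"] == "male").to_numpy(float)
        + u[area_idx]
        + s[area_idx]
    )
    for k in range(config.n_continuous):
        theta = theta + beta[2 + k] * frame[f"x{k + 1}"].to_numpy(float)

    n = rng.integers(config.pop_low, config.pop_high + 1, size=len(frame))
    expected = n * config.baseline_rate
    lam = expected * np.exp(theta)

    over = lam > n
    if over.mean() > 0.01:
        logger.warning(
            "expected Poisson mean exceeds participants in %.1f%% of strata; "
            "counts will be heavily truncated", 100 * over.mean()
        )

    cases = rng.poisson(lam)
    # truncate at N by resampling; falls back to clipping after 1000 rounds
    bad = cases > n
    tries = 0
    while bad.any() and tries < 1000:
        cases[bad] = rng.poisson(lam[bad])
        bad = cases > n
        tries += 1
    cases = np.minimum(cases, n)
    cases[structural_zero[area_idx]] = 0

    table = pd.DataFrame(
        {
            "area_id": frame["area_id"],
            "age_group": frame["age_group"],
            "sex": frame["sex"],
            "participants": n.astype(int),
            "cases": cases.astype(int),
            "expected": expected,
        }
    )
    truth = {
        "alpha": config.alpha_true,
        "beta": np.asarray(config.beta_true, dtype=float),
        "u": u,
        "s": s,
        "sigma2_u": config.sigma2_u_true,
        "sigma2_s": config.sigma2_s_true,
        "zero_inflation_pi": config.zero_inflation_pi,
        "structural_zero": structural_zero,
    }
    return SyntheticDataset(table, graph, cov, truth, config)


def truth_frame(ds: SyntheticDataset) -> pd.DataFrame:
    """Per-area truth table (plus scalar parameters repeated) for CSV export."""
    t = ds.truth
    df = pd.DataFrame(
        {
            "area_id": list(ds.area_ids),
            "u_true": t["u"],
            "s_true": t["s"],
            "structural_zero": t["structural_zero"].astype(int),
        }
    )
    df["alpha_true"] = t["alpha"]
    for k, b in enumerate(t["beta"]):
        df[f"beta{k + 1}_true"] = b
    df["sigma2_u_true"] = t["sigma2_u"]
    df["sigma2_s_true"] = t["sigma2_s"]
    df["zero_inflation_pi_true"] = t["zero_inflation_pi"]
    return df


def dataset_polygons(ds: SyntheticDataset) -> dict:
    cfg = ds.config
    if cfg is None:
        raise ValueError("dataset has no lattice config; polygons unavailable")
    return lattice_polygons(cfg.grid_rows, cfg.grid_cols)
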