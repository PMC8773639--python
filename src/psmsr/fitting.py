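"""Parameter estimation for PSMSR growth curves.

The model is fitted to per-channel cell counts by a real-valued genetic
algorithm (GA) minimising a Gaussian negative log-likelihood on
log-transformed counts (equivalently, lognormal multiplicative count
error); the error variance is profiled out analytically by default.  The
GA's best-of-run is then polished by a bounded quasi-Newton step so the
objective is resolved to well below the chi-square resolution that
profile-likelihood confidence intervals require.

Every objective evaluation simulates the full seeding panel, so the GA
path uses a vectorised fixed-step RK4 integrator that advances the whole
candidate population (and every series of the panel) at once; its
accuracy against the adaptive reference integrator is covered by the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import _LN19, HOURS_PER_DAY
from .params import SEARCH_BOUNDS, PhenotypeParams
from .simulate import DoseSchedule

__all__ = [
    "GrowthDataset",
    "GAConfig",
    "FitResult",
    "ProfileResult",
    "free_parameter_names",
    "condition_lock",
    "neg_log_likelihood",
    "ga_optimize",
    "profile_point",
    "profile_likelihood",
    "fit_condition",
    "simulate_series_batch",
]

REQUIRED_COLUMNS = ("condition", "ratio", "time_h", "channel", "count", "replicate")

# canonical parameter ordering of the full chromosome
PHENOTYPE_NAMES = ("K0", "Kb", "KGs0", "KGt0", "Kstr", "Kstrd", "a", "b", "g")
DRUG_NAMES = ("Sdrug", "AUC5_s", "AUC95_s", "SCALE_s", "AUC5_t", "AUC95_t", "SCALE_t")

_PENALTY = 1e8  # finite objective penalty for invalid candidates / extinct series


@dataclass
class GrowthDataset:
    """Tidy growth-curve table plus per-condition metadata.

    ``frame`` columns: condition, ratio (e.g. ``"4:1"`` sensitive:tolerant),
    time_h, channel (``red``/``green``), count, replicate.  ``conditions``
    maps condition id to a metadata dict which may carry ``schedule``
    (a :class:`~psmsr.simulate.DoseSchedule`), ``drug`` (bool),
    ``seeding`` (known initial counts per (ratio, replicate) series) and
    ``truth`` (generating parameters, for synthetic data).
    """

    frame: pd.DataFrame
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"growth table missing columns: {missing}")
        if len(self.frame) == 0:
            raise ValueError("growth table is empty")
        if (self.frame["count"] < 0).any():
            bad = self.frame.index[self.frame["count"] < 0][:5].tolist()
            raise ValueError(f"negative counts at rows {bad}")
        self.frame = self.frame.sort_values(
            ["condition", "ratio", "replicate", "channel", "time_h"]
        ).reset_index(drop=True)
        sizes = self.frame.groupby(
            ["condition", "ratio", "replicate", "channel"], sort=False
        )["time_h"].nunique()
        if (sizes < 2).any():
            raise ValueError("every series needs at least 2 time points")

    def __len__(self) -> int:
        return len(self.frame)

    def condition_names(self) -> list[str]:
        return list(self.frame["condition"].unique())

    def subset(self, condition: str) -> "GrowthDataset":
        sub = self.frame[self.frame["condition"] == condition]
        if len(sub) == 0:
            raise KeyError(f"condition {condition!r} not in dataset")
        return GrowthDataset(sub.copy(), {condition: self.conditions.get(condition, {})})

    def panels(self, condition: str | None = None) -> list[dict]:
        """Wide view per (condition, ratio, replicate) series.

        Each entry: ``{"condition", "ratio", "replicate", "times_h",
        "red", "green"}`` with red/green aligned on the series' time grid
        (either channel may be absent, e.g. monotypic wells).
        """
        frame = self.frame
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        out = []
        for (cond, ratio, rep), grp in frame.groupby(
            ["condition", "ratio", "replicate"], sort=False
        ):
            wide = grp.pivot_table(
                index="time_h", columns="channel", values="count", aggfunc="first"
            ).sort_index()
            out.append(
                {
                    "condition": cond,
                    "ratio": ratio,
                    "replicate": rep,
                    "times_h": wide.index.to_numpy(dtype=float),
                    "red": wide["red"].to_numpy(dtype=float) if "red" in wide else None,
                    "green": wide["green"].to_numpy(dtype=float) if "green" in wide else None,
                }
            )
        return out


def free_parameter_names(with_drug: bool) -> tuple[str, ...]:
    """Names of the model's free parameters: 9 drug-free, 16 with the
    cisplatin block."""
    return PHENOTYPE_NAMES + DRUG_NAMES if with_drug else PHENOTYPE_NAMES


def condition_lock(condition_meta: dict) -> dict[str, float]:
    """Parameters pinned by the condition's fitting mask.

    Drug conditions turn community cooperation off: phenotypic switching
    (Kb = 0, hence Ka = 0) and stress removal (Kstrd = 0), and the
    sensitive-growth stress coupling ``a`` is unused.
    """
    if condition_meta.get("drug", False):
        return {"Kb": 0.0, "Kstrd": 0.0, "a": 0.0}
    return {}


# ---------------------------------------------------------------------------
# fast vectorised simulation
# ---------------------------------------------------------------------------

def _rates_batch(theta: np.ndarray, C: np.ndarray, coupling: str):
    """Stress-coupled rates for a population of parameter vectors.

    ``theta`` is (m, >=9) in canonical order; ``C`` is the (m,) stress
    vector.  Mirrors :func:`psmsr.model.stress_coupled_rates`.
    """
    K0, Kb = theta[:, 0], theta[:, 1]
    KGs0, KGt0 = theta[:, 2], theta[:, 3]
    a, b, g = theta[:, 6], theta[:, 7], theta[:, 8]
    if coupling == "linear":
        KGS = KGs0 - a * C
        KGT = KGt0 - b * C
        K = K0 + g * C
    elif coupling == "sigmoidal":
        with np.errstate(divide="ignore", invalid="ignore"):
            KGS = KGs0 - np.where(KGs0 > 0, KGs0 * np.tanh(a * C / np.maximum(KGs0, 1e-300)), 0.0)
            KGT = KGt0 - np.where(KGt0 > 0, KGt0 * np.tanh(b * C / np.maximum(KGt0, 1e-300)), 0.0)
            K = K0 + np.where(K0 > 0, K0 * np.tanh(g * C / np.maximum(K0, 1e-300)), 0.0)
    else:
        raise ValueError(f"unknown coupling mode {coupling!r}")
    return KGS, KGT, K, K * Kb, Kb


def _kill_batch(theta: np.ndarray, AUC: np.ndarray):
    """Drug kill rates for a (m, 16) parameter population at exposure AUC."""
    a5s, a95s, scs = theta[:, 10], theta[:, 11], theta[:, 12]
    a5t, a95t, sct = theta[:, 13], theta[:, 14], theta[:, 15]
    zs = _LN19 * (1.0 - 2.0 * (AUC - a5s) / np.maximum(a95s - a5s, 1e-12))
    zt = _LN19 * (1.0 - 2.0 * (AUC - a5t) / np.maximum(a95t - a5t, 1e-12))
    exposed = AUC > 0.0  # no kill before any exposure (see model.death_rates)
    dS = exposed * scs / (1.0 + np.exp(np.clip(zs, -700, 700)))
    dT = exposed * sct / (1.0 + np.exp(np.clip(zt, -700, 700)))
    return dS, dT


def _rhs_batch(y: np.ndarray, theta: np.ndarray, conc: float, coupling: str) -> np.ndarray:
    """Vectorised PSMSR right-hand side; y is (m, 6)."""
    Rs, Rt, Gs, Gt, C, AUC = (y[:, i] for i in range(6))
    # extreme candidates can overflow the fixed-step integrator; those
    # states are capped upstream, so arithmetic here stays finite
    KGS, KGT, K, Ka, Kb = _rates_batch(theta, np.maximum(C, 0.0), coupling)
    if theta.shape[1] >= 16:
        dthS, dthT = _kill_batch(theta, AUC)  # memory effect persists after washout
    else:
        dthS = dthT = 0.0
    out = np.empty_like(y)
    out[:, 0] = -Ka * Rs + Kb * Rt + KGS * Rs - dthS * Rs
    out[:, 1] = +Ka * Rs - Kb * Rt + KGT * Rt - dthT * Rt
    out[:, 2] = -Ka * Gs + Kb * Gt + KGS * Gs - dthS * Gs
    out[:, 3] = +Ka * Gs - Kb * Gt + KGT * Gt - dthT * Gt
    dC = theta[:, 4] * (Rs + Gs) - theta[:, 5] * (Rt + Gt)
    # stress floor: removal saturates once the stress pool is empty
    out[:, 4] = np.where((C <= 0.0) & (dC < 0.0), 0.0, dC)
    out[:, 5] = HOURS_PER_DAY * conc
    return out


def _rk4_batch(y0, theta, times_days, schedule, coupling, substeps):
    """Fixed-step RK4 over a shared reporting grid; y0 and theta are row-
    aligned (one row per candidate x series)."""
    y = y0.copy()
    out = np.empty((y0.shape[0], times_days.size, 6))
    out[:, 0] = y
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(times_days.size - 1):
            t0, t1 = times_days[i], times_days[i + 1]
            h = (t1 - t0) / substeps
            for s in range(substeps):
                ts = t0 + s * h
                conc = schedule.concentration(ts + 0.5 * h) if schedule else 0.0
                k1 = _rhs_batch(y, theta, conc, coupling)
                k2 = _rhs_batch(y + 0.5 * h * k1, theta, conc, coupling)
                k3 = _rhs_batch(y + 0.5 * h * k2, theta, conc, coupling)
                k4 = _rhs_batch(y + h * k3, theta, conc, coupling)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                # cap runaway candidates so NaN/inf never propagates; the
                # likelihood penalises these trajectories anyway
                y = np.nan_to_num(y, nan=-1e30, posinf=1e30, neginf=-1e30)
                np.clip(y, -1e30, 1e30, out=y)
            out[:, i + 1] = y
    return out


def simulate_series_batch(
    theta: np.ndarray,
    times_days: np.ndarray,
    red0: float,
    green0: float,
    schedule: DoseSchedule | None = None,
    *,
    coupling: str = "linear",
    substeps: int = 3,
) -> np.ndarray:
    """Fixed-step RK4 integration of a whole candidate population.

    ``theta`` is (m, 9) or (m, 16) in canonical parameter order; the
    drug-kill block is active iff 16 columns are present.  Returns states
    of shape (m, n_times, 6).  Each reporting interval is subdivided into
    ``substeps`` RK4 steps; the drug concentration is evaluated at substep
    midpoints, so schedules should switch on reporting-grid boundaries.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    times_days = np.asarray(times_days, dtype=float)
    y0 = np.zeros((theta.shape[0], 6))
    y0[:, 0] = red0
    y0[:, 3] = green0
    return _rk4_batch(y0, theta, times_days, schedule, coupling, substeps)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _theta_from_params(p: PhenotypeParams, d=None) -> np.ndarray:
    vec = [getattr(p, n) for n in PHENOTYPE_NAMES]
    if d is not None:
        vec += [getattr(d, n) for n in DRUG_NAMES]
    return np.asarray(vec, dtype=float)


def _series_cache(data: GrowthDataset, condition: str | None):
    """Group observation series by shared (time grid, schedule).

    Series in a group are stacked into the batch dimension of the RK4
    integrator, so a whole seeding panel costs one vectorised sweep per
    candidate population.  Each group is a dict with ``times`` (days),
    ``schedule``, ``inits`` (s, 2) seeding counts, and ``obs`` — a list of
    (series_index, channel_index, log_counts).
    """
    groups: dict = {}
    for panel in data.panels(condition):
        times_days = panel["times_h"] / HOURS_PER_DAY
        meta = data.conditions.get(panel["condition"], {})
        schedule = meta.get("schedule")
        key = (times_days.tobytes(), id(schedule))
        g = groups.setdefault(
            key, {"times": times_days, "schedule": schedule, "inits": [], "obs": []}
        )
        red = panel["red"]
        green = panel["green"]
        idx = len(g["inits"])
        # seeded counts are design metadata when available (exact initial
        # conditions); otherwise fall back to the observed t0 counts
        seeded = meta.get("seeding", {}).get((panel["ratio"], panel["replicate"]))
        if seeded is not None:
            g["inits"].append((float(seeded[0]), float(seeded[1])))
        else:
            g["inits"].append(
                (float(red[0]) if red is not None else 0.0,
                 float(green[0]) if green is not None else 0.0)
            )
        if red is not None:
            g["obs"].append((idx, 0, np.log(np.maximum(red, 1e-12))))
        if green is not None:
            g["obs"].append((idx, 1, np.log(np.maximum(green, 1e-12))))
    out = []
    for g in groups.values():
        g["inits"] = np.asarray(g["inits"], dtype=float)
        out.append(g)
    return out


def _nll_batch(
    theta: np.ndarray,
    cache: list,
    *,
    sigma: float | None,
    coupling: str,
    substeps: int,
) -> np.ndarray:
    """Vectorised negative log-likelihood over a candidate population."""
    theta = np.atleast_2d(theta)
    m = theta.shape[0]
    sse = np.zeros(m)
    penalty = np.zeros(m)
    n_obs = 0
    if theta.shape[1] >= 16:  # exposure ordering must hold for the kill sigmoid
        bad = (theta[:, 10] >= theta[:, 11]) | (theta[:, 13] >= theta[:, 14])
        penalty += _PENALTY * bad
    for g in cache:
        s = g["inits"].shape[0]
        y0 = np.zeros((m * s, 6))
        y0[:, 0] = np.tile(g["inits"][:, 0], m)
        y0[:, 3] = np.tile(g["inits"][:, 1], m)
        theta_rep = np.repeat(theta, s, axis=0)
        states = _rk4_batch(y0, theta_rep, g["times"], g["schedule"], coupling, substeps)
        states = states.reshape(m, s, g["times"].size, 6)
        red_sim = states[:, :, :, 0] + states[:, :, :, 1]
        green_sim = states[:, :, :, 2] + states[:, :, :, 3]
        for idx, channel, log_obs in g["obs"]:
            sim = red_sim[:, idx] if channel == 0 else green_sim[:, idx]
            penalty += _PENALTY * (sim <= 0).sum(axis=1)
            resid = np.log(np.maximum(sim, 1e-12)) - log_obs[None, :]
            sse += np.einsum("ij,ij->i", resid, resid)
            n_obs += log_obs.size
    sse = np.nan_to_num(sse, nan=1e12, posinf=1e12)
    if sigma is None:
        # sigma profiled out analytically: n/2 * (log(2*pi*sse/n) + 1)
        nll = 0.5 * n_obs * (np.log(2 * np.pi * np.maximum(sse, 1e-300) / n_obs) + 1.0)
    else:
        nll = 0.5 * n_obs * np.log(2 * np.pi * sigma**2) + sse / (2 * sigma**2)
    return nll + penalty


def neg_log_likelihood(
    params,
    data: GrowthDataset,
    *,
    drug=None,
    condition: str | None = None,
    sigma: float | None = None,
    coupling: str = "linear",
    substeps: int = 3,
) -> float:
    """Gaussian negative log-likelihood on log-transformed counts.

    ``params`` is a :class:`~psmsr.params.PhenotypeParams` (optionally
    with ``drug``) or a raw parameter vector in canonical order.  With
    ``sigma=None`` the noise SD is profiled out analytically (its MLE is
    plugged in), which is the objective the GA minimises; a fixed sigma
    gives the plain Gaussian log-density.  Simulated counts that hit zero
    or below at an observation time incur a large finite penalty instead
    of producing NaN.  Lower is better; deterministic given inputs.
    """
    if isinstance(params, PhenotypeParams):
        theta = _theta_from_params(params, drug)
    else:
        theta = np.asarray(params, dtype=float)
    cache = _series_cache(data, condition)
    return float(
        _nll_batch(theta[None, :], cache, sigma=sigma, coupling=coupling, substeps=substeps)[0]
    )


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAConfig:
    """Real-valued GA hyperparameters (common package defaults)."""

    pop_size: int = 100
    generations: int = 300
    crossover: float = 0.8      # per-pair BLX crossover probability
    mutation: float = 0.1       # per-gene Gaussian mutation probability
    elitism: int = 5
    seed: int = 0
    tournament: int = 3
    blx_alpha: float = 0.5
    mutation_scale: float = 0.1  # SD as a fraction of each bound range

    def __post_init__(self) -> None:
        for name in ("crossover", "mutation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"GAConfig.{name} must be in [0, 1]")
        if self.elitism >= self.pop_size:
            raise ValueError("elitism must be smaller than pop_size")

    def replace(self, **kw) -> "GAConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class FitResult:
    """Outcome of a GA run (plus, after profiling, confidence intervals)."""

    names: tuple
    x: np.ndarray
    fun: float
    trace: np.ndarray          # best-so-far objective per generation
    seed: int
    condition: str | None = None
    cis: dict = field(default_factory=dict)   # name -> (lo, hi)
    fixed: dict = field(default_factory=dict)  # locked parameters

    def as_dict(self) -> dict:
        out = {n: float(v) for n, v in zip(self.names, self.x)}
        out.update(self.fixed)
        return out

    def phenotype_params(self) -> PhenotypeParams:
        full = self.as_dict()
        return PhenotypeParams(**{n: full[n] for n in PHENOTYPE_NAMES})


def ga_optimize(
    objective,
    bounds,
    cfg: GAConfig,
    *,
    vectorized: bool = False,
    init: np.ndarray | None = None,
    names: tuple | None = None,
) -> FitResult:
    """Minimise ``objective`` over a box with a real-valued GA.

    Tournament selection, BLX-alpha blend crossover, bounded Gaussian
    mutation and elitism; fully reproducible under ``cfg.seed``.  With
    ``vectorized=True`` the objective receives the whole (pop, k)
    candidate matrix and returns (pop,) values.  ``init`` rows (k,) or
    (r, k) are injected into the initial population (used to warm-start
    profile re-optimisation).  Non-convergence is visible in the trace,
    never raised.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    k = lo.size
    rng = np.random.default_rng(cfg.seed)
    pop = lo + (hi - lo) * rng.random((cfg.pop_size, k))
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        r = min(init.shape[0], cfg.pop_size)
        pop[:r] = np.clip(init[:r], lo, hi)

    def evaluate(P):
        if vectorized:
            return np.asarray(objective(P), dtype=float)
        return np.array([objective(row) for row in P], dtype=float)

    fit = evaluate(pop)
    order = np.argsort(fit)
    pop, fit = pop[order], fit[order]
    trace = np.empty(cfg.generations + 1)
    trace[0] = fit[0]
    mut_sd = cfg.mutation_scale * (hi - lo)

    for gen in range(cfg.generations):
        # tournament selection of parents
        idx = rng.integers(0, cfg.pop_size, size=(cfg.pop_size, cfg.tournament))
        parents = pop[idx[np.arange(cfg.pop_size), np.argmin(fit[idx], axis=1)]]
        children = parents.copy()
        # BLX-alpha blend crossover on consecutive pairs
        for i in range(0, cfg.pop_size - 1, 2):
            if rng.random() < cfg.crossover:
                p1, p2 = parents[i], parents[i + 1]
                cmin = np.minimum(p1, p2)
                span = np.abs(p1 - p2)
                low = cmin - cfg.blx_alpha * span
                high = cmin + span + cfg.blx_alpha * span
                children[i] = low + (high - low) * rng.random(k)
                children[i + 1] = low + (high - low) * rng.random(k)
        # bounded Gaussian mutation
        mask = rng.random(children.shape) < cfg.mutation
        children = children + mask * rng.normal(0.0, 1.0, children.shape) * mut_sd
        children = np.clip(children, lo, hi)
        # elitism: best individuals survive unchanged
        children[: cfg.elitism] = pop[: cfg.elitism]
        child_fit = evaluate(children)
        order = np.argsort(child_fit)
        pop, fit = children[order], child_fit[order]
        trace[gen + 1] = min(trace[gen], fit[0])
    return FitResult(
        names=tuple(names) if names else tuple(f"x{i}" for i in range(k)),
        x=pop[0].copy(),
        fun=float(fit[0]),
        trace=trace,
        seed=cfg.seed,
    )


def _quasi_newton_polish(objective, x0, bounds, *, maxiter: int = 80):
    """Bounded L-BFGS-B refinement with a batched forward-difference
    gradient (one vectorised objective call per gradient).

    Works in box-scaled coordinates so every parameter has unit range.
    Returns ``(x, fun)``; falls back to the start point if no improvement.
    """
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    k = lo.size
    h = 1e-7

    def fun_grad(z):
        x = lo + z * span
        P = np.vstack([x, np.tile(x, (k, 1)) + np.diag(h * span)])
        vals = np.asarray(objective(P), dtype=float)
        return vals[0], (vals[1:] - vals[0]) / h

    z0 = np.clip((np.asarray(x0, dtype=float) - lo) / np.where(span > 0, span, 1.0), 0.0, 1.0)
    res = minimize(
        fun_grad, z0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * k, options={"maxiter": maxiter},
    )
    f0 = float(np.asarray(objective(np.asarray(x0)[None, :]))[0])
    if res.fun < f0:
        return lo + res.x * span, float(res.fun)
    return np.asarray(x0, dtype=float), f0


# ---------------------------------------------------------------------------
# condition-level fitting and profile likelihood
# ---------------------------------------------------------------------------

def _build_objective(
    data: GrowthDataset,
    condition: str | None,
    free_names: tuple,
    fixed: dict,
    *,
    with_drug: bool,
    coupling: str,
    substeps: int,
    sigma: float | None = None,
):
    """Vectorised objective over the free-parameter subvector."""
    all_names = free_parameter_names(with_drug)
    cache = _series_cache(data, condition)
    n_full = len(all_names)
    free_idx = np.array([all_names.index(n) for n in free_names])
    base = np.zeros(n_full)
    for n, v in fixed.items():
        base[all_names.index(n)] = v

    def objective(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        theta = np.tile(base, (P.shape[0], 1))
        theta[:, free_idx] = P
        return _nll_batch(theta, cache, sigma=sigma, coupling=coupling, substeps=substeps)

    return objective


def fit_condition(
    data: GrowthDataset,
    condition: str,
    cfg: GAConfig | None = None,
    *,
    fixed: dict | None = None,
    coupling: str = "linear",
    substeps: int = 3,
    polish: bool = True,
) -> FitResult:
    """GA fit of one cohabitation condition.

    Applies the condition's parameter-locking mask (drug conditions pin
    Kb, Kstrd and a to zero), optimises the remaining parameters inside
    the published search ranges with the GA and, by default, polishes the
    best-of-run with a bounded quasi-Newton step.  Returns the result
    tagged with the condition; additional ``fixed`` values extend the
    mask.
    """
    cfg = cfg or GAConfig()
    meta = data.conditions.get(condition, {})
    with_drug = bool(meta.get("drug", False))
    lock = condition_lock(meta)
    if fixed:
        lock.update(fixed)
    all_names = free_parameter_names(with_drug)
    free_names = tuple(n for n in all_names if n not in lock)
    bounds = np.array([SEARCH_BOUNDS[n] for n in free_names])
    objective = _build_objective(
        data, condition, free_names, lock,
        with_drug=with_drug, coupling=coupling, substeps=substeps,
    )
    res = ga_optimize(objective, bounds, cfg, vectorized=True, names=free_names)
    if polish:
        res.x, res.fun = _quasi_newton_polish(objective, res.x, bounds)
    res.condition = condition
    res.fixed = dict(lock)
    return res


@dataclass
class ProfileResult:
    """Log-likelihood profile of one parameter."""

    param: str
    grid: np.ndarray
    nll: np.ndarray
    nll_min: float
    ci: tuple
    flat: bool  # True when the profile cannot bound the parameter

    CHI2_95 = 3.841458820694124  # chi-square(1) 95% quantile

    def contains(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]


def profile_point(
    data: GrowthDataset,
    fit: FitResult,
    param: str,
    value: float,
    *,
    cfg: GAConfig | None = None,
    coupling: str = "linear",
    substeps: int = 3,
    warm: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Profiled NLL at one pinned value of ``param``.

    Re-optimises every other free parameter — a short warm-started GA for
    basin escape followed by the quasi-Newton polish — and returns
    ``(nll, reoptimised_free_vector)``.  The 95% profile CI contains
    ``value`` iff ``2 * (nll - nll_min) <= ProfileResult.CHI2_95``.
    """
    if param not in fit.names:
        raise KeyError(f"{param!r} is not a free parameter of this fit")
    cfg = cfg or GAConfig(pop_size=24, generations=12, elitism=3, seed=fit.seed + 1)
    condition = fit.condition
    meta = data.conditions.get(condition, {}) if condition else {}
    with_drug = bool(meta.get("drug", False))
    free_names = tuple(n for n in fit.names if n != param)
    fixed = dict(fit.fixed)
    fixed[param] = float(value)
    if not free_names:
        objective = _build_objective(
            data, condition, (param,), fit.fixed,
            with_drug=with_drug, coupling=coupling, substeps=substeps,
        )
        return float(objective(np.array([[value]]))[0]), np.empty(0)
    if warm is None:
        j = fit.names.index(param)
        warm = np.delete(fit.x, j)
    objective = _build_objective(
        data, condition, free_names, fixed,
        with_drug=with_drug, coupling=coupling, substeps=substeps,
    )
    bounds = np.array([SEARCH_BOUNDS[n] for n in free_names])
    res = ga_optimize(objective, bounds, cfg, vectorized=True, init=warm, names=free_names)
    start = res.x if res.fun < np.inf else warm
    x, fun = _quasi_newton_polish(objective, start, bounds)
    # the warm start itself may still be the better basin
    xw, fw = _quasi_newton_polish(objective, warm, bounds)
    if fw < fun:
        x, fun = xw, fw
    return fun, x


def profile_likelihood(
    data: GrowthDataset,
    fit: FitResult,
    param: str,
    grid,
    *,
    cfg: GAConfig | None = None,
    coupling: str = "linear",
    substeps: int = 3,
) -> ProfileResult:
    """Profile the likelihood over ``param`` with re-optimisation.

    For each grid value the parameter is pinned and all other free
    parameters are re-optimised (see :func:`profile_point`).  The 95%
    confidence interval is the set of grid values with
    ``2 * (NLL - NLL_min) <= 3.84`` (chi-square with 1 df), with linear
    interpolation at the cutoff crossings.  A profile that never rises
    above the cutoff is flagged flat (parameter not identifiable; the CI
    spans the whole grid).
    """
    if param not in fit.names:
        raise KeyError(f"{param!r} is not a free parameter of this fit")
    cfg = cfg or GAConfig(pop_size=24, generations=12, elitism=3, seed=fit.seed + 1)
    grid = np.asarray(grid, dtype=float)
    j = fit.names.index(param)
    warm = np.delete(fit.x, j)

    nll = np.empty(grid.size)
    for i, value in enumerate(grid):
        nll[i], new_warm = profile_point(
            data, fit, param, value,
            cfg=cfg.replace(seed=cfg.seed + i),
            coupling=coupling, substeps=substeps, warm=warm,
        )
        if new_warm.size:
            warm = new_warm  # walk the warm start along the grid

    nll_min = float(min(nll.min(), fit.fun))
    dev = 2.0 * (nll - nll_min)
    cutoff = ProfileResult.CHI2_95
    inside = dev <= cutoff
    if inside.all():
        return ProfileResult(param, grid, nll, nll_min, (grid[0], grid[-1]), flat=True)
    if not inside.any():
        # profile minimum sits between grid points; fall back to the
        # best grid point as a degenerate interval
        i = int(np.argmin(nll))
        return ProfileResult(param, grid, nll, nll_min, (grid[i], grid[i]), flat=False)

    def _cross(i_out, i_in):
        d0, d1 = dev[i_out], dev[i_in]
        w = (cutoff - d0) / (d1 - d0) if d1 != d0 else 0.0
        return grid[i_out] + w * (grid[i_in] - grid[i_out])

    first = int(np.argmax(inside))
    last = int(len(inside) - 1 - np.argmax(inside[::-1]))
    lo = grid[0] if first == 0 else _cross(first - 1, first)
    hi = grid[-1] if last == len(grid) - 1 else _cross(last + 1, last)
    return ProfileResult(param, grid, nll, nll_min, (float(lo), float(hi)), flat=False)
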