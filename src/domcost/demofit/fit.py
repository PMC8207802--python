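"""Composite-likelihood fitting of joint-SFS demographic models.

Sites are treated as independent (composite likelihood).  The default
objective is the multinomial likelihood of the observed spectrum given the
model-predicted proportions, with the overall scale theta profiled out
analytically (theta_hat = sum(data)/sum(model)); a Poisson objective is
available by flag and gives the same theta_hat and the same rankings on a
fixed data set.

Optimization is derivative-free Nelder-Mead in log-parameter space, in three
rounds of increasing focus: (1) coarse multi-start from log-uniform draws
within the bounds (or around a supplied initial guess), (2) restarts
perturbed around the round-1 best, (3) a single polish with tightened
tolerances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .engine import EngineConfig
from .models import DemographicModelSpec
from .sfs import JointSFS, expected_sfs, joint_sfs

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "ScalingConstants",
    "loglikelihood",
    "fit_model",
    "model_select",
    "bootstrap_ci",
    "scale_to_physical",
]


@dataclass(frozen=True)
class OptimizerConfig:
    restarts: tuple[int, int, int] = (20, 10, 1)
    maxiter: tuple[int, int, int] = (200, 400, 2500)
    perturb_sd: float = 0.4          # log-space sd for round-2 restarts
    fatol: tuple[float, float, float] = (1e-2, 1e-4, 1e-9)
    xatol: tuple[float, float, float] = (1e-2, 1e-3, 1e-7)
    likelihood: str = "multinomial"  # or "poisson"
    engine: str = "deterministic"
    engine_config: EngineConfig | None = None


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    loglik: float
    theta_hat: float
    k: int
    aic: float
    seed: int | None
    data_id: str
    trace: list = field(default_factory=list)
    at_bound: list = field(default_factory=list)
    delta_aic: float | None = None

    def spec(self) -> DemographicModelSpec:
        return DemographicModelSpec(self.model_id, dict(self.params))


def _data_id(sfs: JointSFS) -> str:
    h = hashlib.sha256(np.ascontiguousarray(sfs.matrix).tobytes())
    h.update(f"{sfs.n1},{sfs.n2}".encode())
    return h.hexdigest()[:16]


def loglikelihood(
    model: np.ndarray, data: JointSFS, likelihood: str = "multinomial"
) -> tuple[float, float]:
    """Composite log-likelihood of the data spectrum and optimal theta_hat.

    theta_hat = sum(data)/sum(model) over unmasked entries.
    """
    mask = data.mask
    m = np.asarray(model, dtype=float)[mask]
    d = data.matrix[mask]
    msum = m.sum()
    if not np.isfinite(msum) or msum <= 0:
        return -np.inf, np.nan
    theta_hat = d.sum() / msum
    # numerical floor: cells the engine rounds to zero still carry a tiny
    # positive probability so that a stray observed site penalizes rather
    # than annihilates the likelihood
    m = np.maximum(m, 1e-10 * msum)
    pos = d > 0
    if likelihood == "multinomial":
        p = m / msum
        ll = float(
            d[pos] @ np.log(p[pos])
            + gammaln(d.sum() + 1)
            - gammaln(d + 1).sum()
        )
    elif likelihood == "poisson":
        mu = theta_hat * m
        ll = float((d[pos] * np.log(mu[pos])).sum() - mu.sum() - gammaln(d + 1).sum())
    else:
        raise ValueError(f"unknown likelihood {likelihood!r}")
    return ll, float(theta_hat)


def _objective_factory(data: JointSFS, spec: DemographicModelSpec, cfg: OptimizerConfig):
    names = spec.param_names
    lo = np.array([spec.bounds[n][0] for n in names])
    hi = np.array([spec.bounds[n][1] for n in names])
    llo, lhi = np.log(lo), np.log(hi)

    def objective(z: np.ndarray) -> float:
        zc = np.clip(z, llo, lhi)
        penalty = 1e4 * float(np.sum((z - zc) ** 2))
        p = np.exp(zc)
        try:
            model = expected_sfs(
                spec.with_params(p),
                data.n1,
                data.n2,
                engine=cfg.engine,
                config=cfg.engine_config,
            )
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            return 1e12
        ll, _ = loglikelihood(model, data, cfg.likelihood)
        if not np.isfinite(ll):
            return 1e12
        return -ll + penalty

    return objective, llo, lhi


def fit_model(
    data: JointSFS,
    spec: DemographicModelSpec,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    p0: dict[str, float] | np.ndarray | None = None,
) -> FitResult:
    """Maximize the composite likelihood of one model on one spectrum.

    p0, when given, seeds round 1 with log-normal perturbations of the guess
    instead of global log-uniform draws (the usual warm-start workflow for
    bootstrap replicates and refinement runs).
    """
    cfg = config or OptimizerConfig()
    if data.n_sites <= 0:
        raise ValueError("empty spectrum")
    rng = np.random.default_rng(seed)
    objective, llo, lhi = _objective_factory(data, spec, cfg)
    names = spec.param_names

    if p0 is not None:
        if isinstance(p0, dict):
            z0 = np.log([p0[n] for n in names])
        else:
            z0 = np.log(np.asarray(p0, dtype=float))
        z0 = np.clip(z0, llo, lhi)
    else:
        z0 = None

    trace: list[dict] = []
    best_z, best_f = None, np.inf

    def run_nm(z_start, round_idx):
        nonlocal best_z, best_f
        res = minimize(
            objective,
            z_start,
            method="Nelder-Mead",
            options={
                "maxiter": cfg.maxiter[round_idx],
                "fatol": cfg.fatol[round_idx],
                "xatol": cfg.xatol[round_idx],
                "adaptive": True,
            },
        )
        trace.append(
            {
                "round": round_idx + 1,
                "fun": float(res.fun),
                "nit": int(res.nit),
                "converged": bool(res.success),
            }
        )
        if res.fun < best_f:
            best_f, best_z = float(res.fun), np.asarray(res.x)

    # round 1: coarse multi-start; with a warm start, the guess itself leads
    # off and the remaining starts alternate local perturbations with global
    # log-uniform draws
    for r in range(max(1, cfg.restarts[0])):
        if z0 is not None and r == 0:
            start = z0.copy()
        elif z0 is not None and r % 2 == 1:
            start = np.clip(z0 + rng.normal(0, cfg.perturb_sd, len(names)), llo, lhi)
        else:
            start = rng.uniform(llo, lhi)
        run_nm(start, 0)
    # round 2: perturbed restarts around the round-1 best
    anchor = best_z.copy()
    for _ in range(max(1, cfg.restarts[1])):
        start = np.clip(anchor + rng.normal(0, cfg.perturb_sd, len(names)), llo, lhi)
        run_nm(start, 1)
    # round 3: polish
    for _ in range(max(1, cfg.restarts[2])):
        run_nm(best_z.copy(), 2)

    zfit = np.clip(best_z, llo, lhi)
    pfit = np.exp(zfit)
    model = expected_sfs(
        spec.with_params(pfit), data.n1, data.n2, engine=cfg.engine, config=cfg.engine_config
    )
    ll, theta_hat = loglikelihood(model, data, cfg.likelihood)
    at_bound = [
        names[i]
        for i in range(len(names))
        if zfit[i] - llo[i] < 1e-6 or lhi[i] - zfit[i] < 1e-6
    ]
    k = spec.k
    return FitResult(
        model_id=spec.model_id,
        params={n: float(v) for n, v in zip(names, pfit)},
        loglik=ll,
        theta_hat=theta_hat,
        k=k,
        aic=2 * k - 2 * ll,
        seed=seed,
        data_id=_data_id(data),
        trace=trace,
        at_bound=at_bound,
    )


def _nested_seed(model_id: str, parent: FitResult) -> dict[str, float]:
    """Embed a fitted simpler model into the parameter space of the next
    model up the nesting chain A < B < C < D."""
    p = dict(parent.params)
    if model_id == "B":
        # from A: near-zero gene flow; interior rather than at the bound so
        # the warm start does not trap restarts in the m=0 corner
        return {**p, "m12": 0.01, "m21": 0.01}
    if model_id == "C":  # from B: start with no size change
        return {**p, "nu1F": p["nu1"], "nu2F": p["nu2"]}
    if model_id == "D":  # from C: change epoch covers most of the history
        return {**p, "T2": 0.9 * p["T"]}
    raise ValueError(model_id)


_D_T2_FRACTIONS = (0.9, 0.5, 0.25)  # extra seeds for D's weakly-identified epoch split


def fit_models_nested(
    data: JointSFS,
    model_ids=("A", "B", "C", "D"),
    config: OptimizerConfig | None = None,
    seed: int | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> list[FitResult]:
    """Fit the nested model ladder, warm-starting each model from the
    previous one's optimum (in addition to its own multi-start rounds).

    Seeding each model at the embedding of its parent guarantees the
    likelihood is non-decreasing along the nesting chain, which cold
    multi-starts cannot promise on the ridged growth-model surfaces.
    """
    rng = np.random.default_rng(seed)
    fits: list[FitResult] = []
    parent: FitResult | None = None
    for mid in model_ids:
        spec = DemographicModelSpec(mid, bounds=dict(bounds or {}))
        seeds: list[dict[str, float] | None] = [None]
        if parent is not None and mid in ("B", "C", "D"):
            p0 = _nested_seed(mid, parent)
            if mid == "D":
                seeds = [dict(p0, T2=f * p0["T"]) for f in _D_T2_FRACTIONS]
            else:
                seeds = [p0]
            seeds = [
                {n: float(np.clip(v, *spec.bounds[n])) for n, v in s.items() if n in spec.param_names}
                for s in seeds
            ]
        fit = None
        for s in seeds:
            cand = fit_model(
                data, spec, config=config, seed=int(rng.integers(0, 2**31 - 1)), p0=s
            )
            if fit is None or cand.loglik > fit.loglik:
                fit = cand
        fits.append(fit)
        parent = fit
    return fits


def model_select(fits: list[FitResult]):
    """Rank fitted models by AIC (ascending); sets delta_aic on each fit.

    All fits must have been computed on the same spectrum.
    """
    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    ids = {f.data_id for f in fits}
    if len(ids) != 1:
        raise ValueError("fits were computed on different spectra")
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best
    ranked = sorted(fits, key=lambda f: f.aic)
    import pandas as pd

    return pd.DataFrame(
        {
            "model": [f.model_id for f in ranked],
            "k": [f.k for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "theta_hat": [f.theta_hat for f in ranked],
            "AIC": [f.aic for f in ranked],
            "deltaAIC": [f.delta_aic for f in ranked],
        }
    )


def bootstrap_ci(
    region_spectra: list[np.ndarray],
    fit: FitResult,
    B: int = 100,
    level: float = 0.95,
    seed: int | None = None,
    config: OptimizerConfig | None = None,
    max_dropped_frac: float = 0.2,
):
    """Non-parametric block bootstrap over regions.

    region_spectra: per-region joint-SFS matrices (same shape); regions are
    resampled with replacement, summed, and refit warm-started from the point
    estimate (rounds 2-3 of the optimizer scheme).  Returns a DataFrame of
    percentile intervals per parameter.
    """
    if len(region_spectra) < 20:
        raise ValueError("bootstrap needs at least 20 regions")
    cfg = config or OptimizerConfig(restarts=(3, 2, 1))
    rng = np.random.default_rng(seed)
    shape = region_spectra[0].shape
    n1, n2 = shape[0] - 1, shape[1] - 1
    stack = np.stack(region_spectra)
    spec = fit.spec()
    draws: list[dict[str, float]] = []
    dropped = 0
    for b in range(B):
        idx = rng.integers(0, len(region_spectra), len(region_spectra))
        mat = stack[idx].sum(axis=0)
        mat[0, 0] = 0.0
        mat[n1, n2] = 0.0
        try:
            rep_sfs = JointSFS(mat, n1, n2)
            if rep_sfs.n_sites == 0:
                raise ValueError("empty bootstrap spectrum")
            res = fit_model(
                rep_sfs,
                spec,
                config=cfg,
                seed=int(rng.integers(0, 2**31 - 1)),
                p0=fit.params,
            )
            draws.append(res.params)
        except (ValueError, RuntimeError):
            dropped += 1
    if dropped > max_dropped_frac * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed to converge")
    import pandas as pd

    alpha = (1 - level) / 2
    rows = []
    for name in spec.param_names:
        vals = np.array([d[name] for d in draws])
        rows.append(
            {
                "parameter": name,
                "point": fit.params[name],
                "lower": float(np.quantile(vals, alpha)),
                "upper": float(np.quantile(vals, 1 - alpha)),
                "n_replicates": len(draws),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScalingConstants:
    """Constants for converting diffusion units to physical units."""

    mu_per_site_per_year: float = 1.91e-9
    generation_time_years: float = 1.0
    total_bp: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_per_site_per_year <= 0 or self.generation_time_years <= 0:
            raise ValueError("scaling constants must be positive")

    @property
    def mu_per_site_per_generation(self) -> float:
        return self.mu_per_site_per_year * self.generation_time_years


def scale_to_physical(fit: FitResult, consts: ScalingConstants) -> dict[str, float]:
    """Convert a fit to diploid sizes and years.

    Nanc = theta_hat / (4 * mu_gen * L); sizes scale by Nanc; times scale by
    2*Nanc generations times the generation time.
    """
    if fit.theta_hat <= 0 or consts.total_bp <= 0:
        raise ValueError("need positive theta_hat and callable length")
    mu_gen = consts.mu_per_site_per_generation
    nanc = fit.theta_hat / (4.0 * mu_gen * consts.total_bp)
    out = {"N_anc": nanc, "theta_hat": fit.theta_hat}
    for name, v in fit.params.items():
        if name.startswith("nu"):
            out["N_" + name[2:]] = v * nanc
        elif name.startswith("T"):
            out[name + "_years"] = v * 2.0 * nanc * consts.generation_time_years
        elif name.startswith("m"):
            out[name + "_per_generation"] = v / (2.0 * nanc)
    return out
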