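"""Maximum-likelihood fitting and the four-extinction-scenario protocol.

Extinction rates estimated from molecular phylogenies are notoriously close
to zero, contradicting the fossil record, so the range-evolution model never
tries to estimate ``mu`` from the tree.  Instead the protocol brackets it:

1. fit a standard constant-rate birth–death (BD) model to the tree and take
   its speciation-rate estimate, called ``BD_mu``, as a tentative long-term
   mean extinction rate (fossil-complete datasets suggest extinction is
   nearly as frequent as speciation);
2. analyse the data under four fixed extinction levels —
   0, BD_mu/10, BD_mu and 10 x BD_mu — crossing each with the DEC and DIVA
   cladogenesis conventions (eight fits in total).

Within each fit the four remaining rates (in-situ speciation, vicariance,
dispersal, extirpation) are free, optimized on the log scale with seeded
multi-starts.  DEC and DIVA carry the same number of parameters, so their
likelihoods are directly comparable per extinction level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import (
    LikelihoodOptions,
    LikelihoodResult,
    ModelTables,
    RateParams,
    compute_loglik,
)
from .statespace import RangeState, StateSpace
from .trees import IndexedTree, index_tree

__all__ = [
    "BDFit",
    "OptimizerSettings",
    "RangeModelFit",
    "ScenarioGrid",
    "bd_loglik",
    "fit_bd",
    "fit_range_model",
    "run_scenarios",
    "compare_models",
    "MU_LEVEL_NAMES",
]

MU_LEVEL_NAMES = ("zero", "low", "intermediate", "high")


# ---------------------------------------------------------------- birth-death

def _bd_log_phi(t: float, lam: float, mu: float) -> float:
    """log of the single-lineage D propagator Phi(t) for constant-rate BD.

    Phi solves dD/dt = -(lam+mu) D + 2 lam E(t) D with Phi(0) = 1:
    Phi(t) = exp(-r t) r^2 / (lam - mu exp(-r t))^2, r = lam - mu, with the
    critical-case limit 1 / (1 + lam t)^2 as r -> 0.
    """
    r = lam - mu
    if abs(r) < 1e-9 * max(lam, mu, 1e-30):
        return -2.0 * np.log1p(lam * t)
    with np.errstate(over="ignore", invalid="ignore"):
        denom = lam - mu * np.exp(-r * t)
        val = -r * t + 2.0 * (np.log(abs(r)) - np.log(abs(denom)))
    return float(val) if np.isfinite(val) else -np.inf


def _bd_E(t: float, lam: float, mu: float) -> float:
    """Probability a single lineage at age t leaves no extant descendant."""
    r = lam - mu
    if abs(r) < 1e-9 * max(lam, mu, 1e-30):
        return lam * t / (1.0 + lam * t)
    with np.errstate(over="ignore", invalid="ignore"):
        E = mu * (1.0 - np.exp(-r * t)) / (lam - mu * np.exp(-r * t))
    # deeply subcritical regimes overflow exp(-r t); extinction is then certain
    return float(E) if np.isfinite(E) else 1.0


def bd_loglik(tree, lam: float, mu: float, condition_on_survival: bool = True) -> float:
    """Closed-form constant-rate birth–death log-likelihood of a crown tree.

    Uses the same pruning convention as the range model restricted to one
    area: each branch carries the propagator Phi, each of the n - 1 internal
    nodes a factor lam, the crown age is treated as given, and conditioning
    on survival divides by (1 - E(root age))^2.  The single-area range model
    must reduce to this exactly.
    """
    if lam <= 0 or mu < 0:
        raise ValueError("need lam > 0 and mu >= 0")
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    T = itree.root_age
    nonroot_internal_ages = itree.ages[itree.internal_nodes[:-1]]  # root is last
    ll = (itree.n_tips - 1) * np.log(lam) + 2.0 * _bd_log_phi(T, lam, mu)
    ll += sum(_bd_log_phi(t, lam, mu) for t in nonroot_internal_ages)
    if condition_on_survival:
        surv = 1.0 - _bd_E(T, lam, mu)
        if surv <= 0:
            return -np.inf
        ll -= 2.0 * np.log(surv)
    return float(ll)


@dataclass(frozen=True)
class BDFit:
    """Constant-rate birth–death fit; ``bd_mu`` is the speciation estimate.

    The protocol deliberately recycles the *speciation* rate as the
    intermediate assumed extinction level, on the premise that extinction has
    been nearly as frequent as speciation over the long run.
    """

    lambda_hat: float
    mu_hat: float
    loglik: float
    n_tips: int

    @property
    def bd_mu(self) -> float:
        return self.lambda_hat


def fit_bd(tree, pin_mu: float | None = None,
           condition_on_survival: bool = True) -> BDFit:
    """Maximum-likelihood constant-rate birth–death fit to a chronogram.

    The crown age is treated as given and the likelihood conditions on
    survival of both crown lineages by default.  ``pin_mu`` fixes the
    extinction rate (e.g. 0 for a pure-birth fit) and optimizes speciation
    alone.  Requires at least three tips — a two-tip tree carries no
    information about rates beyond its depth.
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    if itree.n_tips < 3:
        raise ValueError("birth–death fit needs at least 3 tips")
    if itree.root_age <= 0:
        raise ValueError("degenerate tree: zero height")
    # Yule-style moment start: internal nodes per unit of (branch + root) time
    lam0 = (itree.n_tips - 1) / (itree.total_branch_length() + itree.root_age)

    if pin_mu is not None:
        def nll1(x):
            return -bd_loglik(itree, float(np.exp(x[0])), pin_mu, condition_on_survival)

        res = minimize(nll1, [np.log(lam0)], method="L-BFGS-B", bounds=[(-14, 7)])
        lam = float(np.exp(res.x[0]))
        return BDFit(lam, pin_mu, -float(res.fun), itree.n_tips)

    def nll(x):
        lam, mu = np.exp(x)
        v = -bd_loglik(itree, float(lam), float(mu), condition_on_survival)
        return v if np.isfinite(v) else 1e10

    best = None
    for mu0 in (lam0 * 1e-4, lam0 * 0.3, lam0 * 0.8):
        res = minimize(nll, [np.log(lam0), np.log(mu0)], method="L-BFGS-B",
                       bounds=[(-14, 7), (-16, 7)])
        if best is None or res.fun < best.fun:
            best = res
    lam, mu = (float(v) for v in np.exp(best.x))
    if mu < 1e-7:  # at the boundary: report a hard zero
        mu = 0.0
    return BDFit(lam, mu, -float(best.fun), itree.n_tips)


# ------------------------------------------------------------ range-model ML

@dataclass(frozen=True)
class OptimizerSettings:
    """Multi-start L-BFGS-B settings for the four free log-rates.

    ``ftol`` and ``fd_eps`` are matched to the likelihood's numerical
    precision (~1e-6 log units): tighter values make the finite-difference
    gradients chase integrator noise instead of signal.
    """

    bounds: tuple[float, float] = (1e-6, 1e2)
    n_starts: int = 5
    seed: int = 0
    maxiter: int = 300
    ftol: float = 1e-8
    fd_eps: float = 1e-6
    x0: tuple[float, float, float, float] | None = None  # explicit base start

    def __post_init__(self) -> None:
        if self.bounds[0] <= 0 or self.bounds[1] <= self.bounds[0]:
            raise ValueError("bounds must be positive and increasing")
        if self.n_starts < 1:
            raise ValueError("need at least one start")


@dataclass
class RangeModelFit:
    """One fitted cell: model x fixed extinction level."""

    result: LikelihoodResult
    mu_fixed: float
    converged: bool
    n_starts: int
    start_logliks: tuple[float, ...]
    speciation_exceeds_extinction: bool

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def params(self) -> RateParams:
        return self.result.params

    @property
    def model(self) -> str:
        return self.result.model


def _start_points(lam0: float, T: float, settings: OptimizerSettings) -> list[np.ndarray]:
    rng = np.random.default_rng(settings.seed)
    lo, hi = np.log(settings.bounds[0]), np.log(settings.bounds[1])
    raw = settings.x0 if settings.x0 is not None else [lam0, lam0 / 4.0, 1.0 / T, 0.5 / T]
    base = np.log(np.clip(raw, settings.bounds[0] * 1.01, settings.bounds[1] * 0.99))
    pts = [base]
    for _ in range(settings.n_starts - 1):
        pts.append(np.clip(base + rng.normal(0.0, 1.2, size=4), lo + 0.01, hi - 0.01))
    return pts


def fit_range_model(tree, tip_ranges: Mapping[str, RangeState], space: StateSpace,
              model: str, mu_fixed: float,
              settings: OptimizerSettings | None = None,
              options: LikelihoodOptions | None = None,
              tables: ModelTables | None = None) -> RangeModelFit:
    """Maximize the range-model likelihood with extinction clamped.

    Optimizes (lambda_is, lambda_vic, d, e) on the log scale under bound
    constraints, from one heuristic start plus seeded random perturbations.
    ``mu_fixed`` is never adjusted.  If the fitted total speciation rate
    (lambda_is + lambda_vic) fails to exceed ``mu_fixed`` a warning flag is
    set — expected of plausible fits, but not enforced as a constraint.
    """
    if mu_fixed < 0:
        raise ValueError("mu_fixed must be non-negative")
    settings = settings or OptimizerSettings()
    opts = options or LikelihoodOptions()
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    tbl = tables if tables is not None else ModelTables(space, model)
    lo, hi = np.log(settings.bounds[0]), np.log(settings.bounds[1])
    lam0 = (itree.n_tips - 1) / (itree.total_branch_length() + itree.root_age)
    if opts.dt_max is None:
        # freeze the integration grid for the whole fit: a parameter-dependent
        # grid makes the objective piecewise and finite differences unusable
        T = itree.root_age
        rate0 = mu_fixed + 6.0 * lam0
        opts = replace(opts, dt_max=max(min(T / 60.0, 0.2 / rate0), T / 1500.0))

    def nll(x: np.ndarray) -> float:
        params = RateParams.from_free(np.exp(x), mu_fixed)
        ll = compute_loglik(itree, tip_ranges, params, tbl, opts,
                            retain_partials=False).loglik
        return -ll if np.isfinite(ll) else 1e10

    best = None
    start_lls: list[float] = []
    any_ok = False
    for x0 in _start_points(lam0, itree.root_age, settings):
        res = minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 4,
                       options={"maxiter": settings.maxiter, "ftol": settings.ftol,
                                "eps": settings.fd_eps})
        start_lls.append(-float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_ok and best.fun >= 1e10:
        raise RuntimeError("range-model optimization failed from every start")
    params = RateParams.from_free(np.exp(best.x), mu_fixed)
    result = compute_loglik(itree, tip_ranges, params, tbl, opts, retain_partials=True)
    exceeds = params.lambda_is + params.lambda_vic > mu_fixed
    if not exceeds and mu_fixed > 0:
        warnings.warn(
            f"fitted total speciation {params.lambda_is + params.lambda_vic:.4g} "
            f"does not exceed the assumed extinction rate {mu_fixed:.4g}",
            stacklevel=2,
        )
    return RangeModelFit(result=result, mu_fixed=mu_fixed,
                    converged=bool(best.success or any_ok),
                    n_starts=settings.n_starts,
                    start_logliks=tuple(start_lls),
                    speciation_exceeds_extinction=exceeds)


# ------------------------------------------------------------- scenario grid

@dataclass
class ScenarioGrid:
    """Eight fitted cells: {0, BD_mu/10, BD_mu, 10 BD_mu} x {DEC, DIVA}."""

    bd: BDFit
    mu_levels: dict[str, float]  # level name -> assumed extinction rate
    models: tuple[str, ...]
    cells: dict[tuple[str, str], RangeModelFit]  # (level name, model) -> fit
    selected: dict[str, str] = field(default_factory=dict)  # level -> model

    def cell(self, level: str, model: str) -> RangeModelFit:
        return self.cells[(level, model)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (level, model), fit in self.cells.items():
            p = fit.params
            rows.append({
                "mu_level": level, "mu": fit.mu_fixed, "model": model,
                "loglik": fit.loglik, "lambda_is": p.lambda_is,
                "lambda_vic": p.lambda_vic, "d": p.d, "e": p.e,
                "converged": fit.converged,
                "selected": self.selected.get(level) == model,
            })
        return pd.DataFrame(rows)


def scenario_mu_levels(bd_mu: float) -> dict[str, float]:
    """The four assumed extinction levels derived from the BD speciation rate."""
    return {"zero": 0.0, "low": bd_mu / 10.0, "intermediate": bd_mu,
            "high": 10.0 * bd_mu}


def run_scenarios(tree, tip_ranges: Mapping[str, RangeState], space: StateSpace,
                  settings: OptimizerSettings | None = None,
                  options: LikelihoodOptions | None = None,
                  models: Sequence[str] = ("DEC", "DIVA")) -> ScenarioGrid:
    """Calibrate BD_mu, then fit every (extinction level x model) cell.

    Per level the higher-likelihood model is marked selected (DEC on exact
    ties, recorded as such in the output).  Errors in individual cells are
    re-raised annotated with the cell identity.
    """
    itree = tree if isinstance(tree, IndexedTree) else index_tree(tree)
    bd = fit_bd(itree)
    levels = scenario_mu_levels(bd.bd_mu)
    tbls = {m: ModelTables(space, m) for m in models}
    cells: dict[tuple[str, str], RangeModelFit] = {}
    for level, mu in levels.items():
        for m in models:
            try:
                cells[(level, m)] = fit_range_model(itree, tip_ranges, space, m, mu,
                                              settings, options, tables=tbls[m])
            except Exception as err:  # annotate, keep the traceback
                raise RuntimeError(f"scenario cell (mu={level}, model={m}) failed") from err
    grid = ScenarioGrid(bd=bd, mu_levels=levels, models=tuple(models), cells=cells)
    for level in levels:
        lls = {m: cells[(level, m)].loglik for m in models}
        top = max(lls.values())
        # tie-break in favour of DEC, by documented convention
        order = [m for m in ("DEC", "DIVA") if m in models] or list(models)
        grid.selected[level] = next(m for m in order if lls[m] == top)
    return grid


def compare_models(grid: ScenarioGrid) -> pd.DataFrame:
    """Per extinction level: delta log-likelihood (DEC - DIVA) and selection.

    Both conventions spend the same four free parameters, so raw likelihoods
    are directly comparable; AIC (k = 4) is emitted for reference only.
    """
    if not grid.cells:
        raise ValueError("empty scenario grid")
    rows = []
    for level, mu in grid.mu_levels.items():
        row: dict = {"mu_level": level, "mu": mu}
        for m in grid.models:
            if (level, m) not in grid.cells:
                raise ValueError(f"incomplete grid: missing cell ({level}, {m})")
            ll = grid.cells[(level, m)].loglik
            row[f"loglik_{m}"] = ll
            row[f"aic_{m}"] = 2.0 * 4 - 2.0 * ll
        if "DEC" in grid.models and "DIVA" in grid.models:
            row["delta_loglik"] = row["loglik_DEC"] - row["loglik_DIVA"]
            row["tie"] = row["delta_loglik"] == 0.0
        row["selected"] = grid.selected[level]
        rows.append(row)
    return pd.DataFrame(rows)
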