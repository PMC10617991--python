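"""Fit model-predicted stinging to behavioral discharge data.

The behavioral assay counts discharged nematocysts per animal across
feeding conditions (days of food deprivation).  To compare with the model,
days starved are mapped affinely onto the starvation axis (day 0 at s = 0,
the last assayed day at a chosen s_last < 1, since assayed animals are
never severely starved), the model's optimal action curve a*(s) is scaled
by a single normalization lambda onto the observed discharge fractions,
and the full-discharge cost parameters (c0_base, slope) are chosen to
minimize the weighted squared error.  lambda has a closed-form weighted
least-squares solution for any candidate cost, so the search runs over the
two cost parameters only (coarse grid plus Nelder-Mead refinement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .defense_solver import defense_closed_form_increasing_cost
from .model_spec import CostSpec, DefenseConfig, PredationMDP
from .predation_solver import value_iteration

__all__ = [
    "BehaviorDataset",
    "FitResult",
    "map_days_to_starvation",
    "normalize_model_to_data",
    "model_action_curve",
    "fit_increasing_cost",
    "fit_shared_cost",
    "goodness_of_fit",
]

_COLUMNS = ["species", "days_starved", "animal_id", "discharged_count", "assay_scale"]


@dataclass
class BehaviorDataset:
    """Per-animal discharge counts across feeding conditions.

    ``data`` has one row per animal x condition with columns
    species, days_starved, animal_id, discharged_count, assay_scale
    (capsules at risk in the assay).
    """

    data: pd.DataFrame
    species: str = "defensive_model"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"behavior table missing columns: {missing}")
        if (self.data["discharged_count"] < 0).any():
            raise ValueError("discharge counts must be >= 0")
        scale = self.data["assay_scale"]
        if (self.data["discharged_count"] > scale).any():
            raise ValueError("discharge counts cannot exceed the assay scale")

    @classmethod
    def read_csv(cls, path: str | Path, species: str | None = None) -> "BehaviorDataset":
        df = pd.read_csv(path)
        sp = species or (df["species"].iloc[0] if "species" in df else "defensive_model")
        return cls(df, species=sp)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def condition_summary(self) -> pd.DataFrame:
        """Mean discharge fraction and SEM per feeding condition."""
        df = self.data.assign(fraction=self.data["discharged_count"] / self.data["assay_scale"])
        g = df.groupby("days_starved")["fraction"]
        out = pd.DataFrame(
            {
                "days_starved": g.mean().index,
                "n_animals": g.size().values,
                "mean_fraction": g.mean().values,
                "sem_fraction": g.sem().values,
            }
        ).reset_index(drop=True)
        return out.sort_values("days_starved", ignore_index=True)


@dataclass
class FitResult:
    """Fitted cost parameters, normalization scale and residuals."""

    cost: CostSpec
    scale_lambda: float
    residuals: np.ndarray
    objective: float
    s_values: np.ndarray
    fitted_curve: np.ndarray
    model: str
    extras: dict = field(default_factory=dict)


def map_days_to_starvation(
    days: np.ndarray, s_last: float, grid: np.ndarray | None = None
) -> np.ndarray:
    """Affine map from days starved onto the starvation axis.

    Day 0 maps to s = 0 and the last assayed day to ``s_last`` (< 1: the
    animals are never severely starved during the assay).  If ``grid`` is
    given, values are snapped to the nearest grid state.
    """
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("days must be non-empty")
    if days.size > 1 and np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if not (0.0 < s_last < 1.0):
        raise ValueError("s_last must lie strictly between 0 and 1")
    if days.size == 1 or days[-1] == 0:
        s = np.full(days.shape, s_last)
    else:
        s = days * (s_last / days[-1])
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        s = grid[np.argmin(np.abs(s[:, None] - grid[None, :]), axis=1)]
    return s


def normalize_model_to_data(
    model_actions: np.ndarray,
    observed_fractions: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Closed-form weighted least-squares scale lambda for lambda * a*(s) ~ y."""
    a = np.asarray(model_actions, dtype=float)
    y = np.asarray(observed_fractions, dtype=float)
    if a.shape != y.shape:
        raise ValueError("model and observed arrays must have equal length")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    denom = float(np.sum(w * a * a))
    if denom == 0.0:
        raise ValueError("model actions are all zero; scale is undefined")
    return float(np.sum(w * y * a) / denom)


def model_action_curve(
    cost: CostSpec,
    model: str,
    base_config: PredationMDP | DefenseConfig,
    s_values: np.ndarray,
    V0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Optimal action at the requested starvation values for a candidate cost.

    Returns ``(actions, V)`` where V is the value table for warm-starting
    subsequent predation solves (None for the defensive closed form).
    """
    s_values = np.asarray(s_values, dtype=float)
    if model == "defense":
        cfg = replace(base_config, cost=cost)
        sol = defense_closed_form_increasing_cost(cfg, s_grid=s_values)
        return np.asarray(sol.a_star, dtype=float), None
    if model == "predation":
        mdp = replace(base_config, cost=cost)
        sol = value_iteration(mdp, tol=1e-8, V0=V0)
        idx = np.rint(s_values * (mdp.n_states - 1)).astype(int)
        return sol.a_star[idx], sol.V
    raise ValueError(f"unknown model {model!r}")


def _condition_inputs(dataset: BehaviorDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    summ = dataset.condition_summary()
    y = summ["mean_fraction"].to_numpy()
    sem = summ["sem_fraction"].to_numpy()
    if np.any(~np.isfinite(sem)) or np.any(sem <= 0):
        w = np.ones_like(y)  # uniform weights when SEMs are unavailable
    else:
        w = 1.0 / sem**2
    return summ["days_starved"].to_numpy(), y, w


def _cost_candidate(c0_base: float, slope: float) -> CostSpec:
    form = "constant" if slope == 0 else "linear_increasing"
    return CostSpec(c0_base=c0_base, slope=slope, form=form)


def fit_increasing_cost(
    dataset: BehaviorDataset,
    model: str,
    base_config: PredationMDP | DefenseConfig,
    s_last: float = 0.5,
    c0_range: tuple[float, float] = (0.1, 1.55),
    slope_max: float = 1.5,
    n_grid: int = 9,
    fix_c0_base: float | None = None,
) -> FitResult:
    """Fit (c0_base, slope, lambda) to condition-mean discharge fractions.

    Weighted least squares (inverse squared SEM weights) over a coarse
    (c0_base, slope) grid followed by Nelder-Mead refinement; lambda is
    profiled out in closed form at every candidate.  Candidates whose model
    solve fails (e.g. an all-zero policy) are skipped.

    With few conditions the three free parameters trade off along a nearly
    flat ridge (a lower base cost, steeper slope and smaller scale produce
    almost the same curve), which inflates the variance of the recovered
    slope.  ``fix_c0_base`` anchors the base cost -- typically at the value
    already calibrated for the constant-cost model, since both cost
    functions share c0(0) -- and fits only (slope, lambda), which is the
    well-conditioned variant recommended for slope estimation.
    """
    days, y, w = _condition_inputs(dataset)
    if len(days) < 3:
        raise ValueError("need at least 3 feeding conditions to fit a cost trend")
    s_values = map_days_to_starvation(days, s_last)
    warm: dict = {"V": None}

    def score(params: np.ndarray) -> float:
        c0_base, slope = params
        if fix_c0_base is None and not (c0_range[0] <= c0_base <= c0_range[1]):
            return np.inf
        if not (0.0 <= slope <= slope_max):
            return np.inf
        try:
            a, V = model_action_curve(_cost_candidate(c0_base, slope), model, base_config, s_values, V0=warm["V"])
            if V is not None:
                warm["V"] = V
            lam = normalize_model_to_data(a, y, w)
        except (ValueError, ArithmeticError):
            return np.inf  # candidate skipped: no usable model solution
        return float(np.sum(w * (lam * a - y) ** 2))

    if fix_c0_base is not None:
        c0s = np.array([fix_c0_base])
        slopes = np.linspace(0.0, slope_max, max(n_grid, 41))
    else:
        c0s = np.linspace(*c0_range, n_grid)
        slopes = np.linspace(0.0, slope_max, n_grid)
    best, best_sse = None, np.inf
    for c0_base in c0s:
        for slope in slopes:
            sse = score(np.array([c0_base, slope]))
            if sse < best_sse:
                best, best_sse = (c0_base, slope), sse
    if best is None or not np.isfinite(best_sse):
        raise ValueError("no admissible cost candidate produced a usable fit")
    if fix_c0_base is not None:
        res = minimize(lambda m: score(np.array([fix_c0_base, m[0]])), np.asarray(best[1:]), method="Nelder-Mead", options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 200})
        c0_base, slope = (fix_c0_base, float(res.x[0])) if np.isfinite(res.fun) and res.fun <= best_sse else best
    else:
        res = minimize(score, np.asarray(best), method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200})
        c0_base, slope = res.x if np.isfinite(res.fun) and res.fun <= best_sse else best
    slope = max(float(slope), 0.0)
    cost = _cost_candidate(float(c0_base), slope)
    a, _ = model_action_curve(cost, model, base_config, s_values)
    lam = normalize_model_to_data(a, y, w)
    fitted = lam * a
    return FitResult(
        cost=cost,
        scale_lambda=lam,
        residuals=y - fitted,
        objective=float(np.sum(w * (fitted - y) ** 2)),
        s_values=s_values,
        fitted_curve=fitted,
        model=model,
        extras={"days": days, "observed": y, "weights": w, "s_last": s_last},
    )


def fit_shared_cost(
    predatory: BehaviorDataset,
    defensive: BehaviorDataset,
    predation_config: PredationMDP,
    defense_config: DefenseConfig,
    s_last: float = 0.5,
    c0_range: tuple[float, float] = (0.1, 1.55),
    slope_max: float = 1.5,
    n_grid: int = 7,
) -> tuple[FitResult, FitResult]:
    """Fit one shared cost function to both species jointly.

    A single (c0_base, slope) is scored on the summed weighted SSE of the
    predatory and defensive datasets, each with its own closed-form scale
    lambda.  Returns the per-dataset fit results at the shared optimum.
    """
    inputs = []
    for ds, model, cfg in (
        (predatory, "predation", predation_config),
        (defensive, "defense", defense_config),
    ):
        days, y, w = _condition_inputs(ds)
        inputs.append((model, cfg, map_days_to_starvation(days, s_last), y, w))
    warm: dict = {"V": None}

    def score(params: np.ndarray) -> float:
        c0_base, slope = params
        if not (c0_range[0] <= c0_base <= c0_range[1]) or not (0.0 <= slope <= slope_max):
            return np.inf
        total = 0.0
        for model, cfg, s_values, y, w in inputs:
            try:
                a, V = model_action_curve(_cost_candidate(c0_base, slope), model, cfg, s_values, V0=warm["V"] if model == "predation" else None)
                if V is not None:
                    warm["V"] = V
                lam = normalize_model_to_data(a, y, w)
            except (ValueError, ArithmeticError):
                return np.inf
            total += float(np.sum(w * (lam * a - y) ** 2))
        return total

    c0s = np.linspace(*c0_range, n_grid)
    slopes = np.linspace(0.0, slope_max, n_grid)
    best, best_sse = None, np.inf
    for c0_base in c0s:
        for slope in slopes:
            sse = score(np.array([c0_base, slope]))
            if sse < best_sse:
                best, best_sse = (c0_base, slope), sse
    if best is None or not np.isfinite(best_sse):
        raise ValueError("no admissible shared cost candidate produced a usable fit")
    res = minimize(score, np.asarray(best), method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 150})
    c0_base, slope = res.x if np.isfinite(res.fun) and res.fun <= best_sse else best
    cost = _cost_candidate(float(c0_base), max(float(slope), 0.0))
    results = []
    for (model, cfg, s_values, y, w), ds in zip(inputs, (predatory, defensive)):
        a, _ = model_action_curve(cost, model, cfg, s_values)
        lam = normalize_model_to_data(a, y, w)
        fitted = lam * a
        results.append(
            FitResult(
                cost=cost,
                scale_lambda=lam,
                residuals=y - fitted,
                objective=float(np.sum(w * (fitted - y) ** 2)),
                s_values=s_values,
                fitted_curve=fitted,
                model=model,
                extras={"observed": y, "weights": w, "shared": True, "s_last": s_last},
            )
        )
    return results[0], results[1]


def goodness_of_fit(fit: FitResult, dataset: BehaviorDataset | None = None) -> dict:
    """Deterministic fit report: SSE, residuals and fitted-curve trend."""
    diffs = np.diff(fit.fitted_curve)
    tol = 1e-9
    if np.all(np.abs(diffs) <= tol):
        trend = "flat"
    elif np.all(diffs >= -tol):
        trend = "increasing"
    elif np.all(diffs <= tol):
        trend = "decreasing"
    else:
        trend = "mixed"
    return {
        "sse": float(np.sum(fit.residuals**2)),
        "weighted_sse": fit.objective,
        "residuals": fit.residuals.tolist(),
        "trend": trend,
        "model": fit.model,
        "c0_base": fit.cost.c0_base,
        "slope": fit.cost.slope,
        "scale_lambda": fit.scale_lambda,
    }
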