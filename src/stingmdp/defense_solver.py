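"""Solvers for the two-state defensive stinging problem.

Safety (L) yields a unit reward on a successful sting and stays safe;
a failed sting drops the agent into absorbing danger (D, value 0) with
penalty -1.  Starvation never changes through defensive stinging -- it
enters only parametrically, through the full-discharge cost ``c0(s)``.

With ``p(a) = pM a (2 - a)`` and linear cost, the optimal action has the
closed form

    a*(s) = K(s) - sqrt(K(s)^2 - C(s)),
    K(s) = eps / c0(s),  eps = (2 - gamma) / gamma,
    C(s) = -1 / (pM gamma) + 2 eps / c0(s),

valid (interior) whenever ``c0(s) < 2 pM (2 - gamma)``; outside that bound
the optimum sits at a = 0 or a = 1, resolved by comparing the safety-state
values of the two endpoint actions.  For constant cost the action is the
same at every starvation state; for a cost that increases with starvation
it decreases with s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_spec import DefenseConfig

__all__ = [
    "DefenseSolution",
    "defense_value_iteration",
    "defense_closed_form",
    "defense_closed_form_increasing_cost",
    "safety_value_for_action",
]


@dataclass
class DefenseSolution:
    """Optimal defensive action (scalar or per-starvation-state array)."""

    a_star: float | np.ndarray
    V_L: float | np.ndarray
    regime: str | np.ndarray  # interior / boundary_zero / boundary_one
    constants: dict = field(default_factory=dict)
    method: str = "closed_form"
    iterations: int = 0
    final_residual: float = 0.0
    converged: bool = True

    def to_frame(self, s_grid: np.ndarray):
        import pandas as pd

        a = np.broadcast_to(np.asarray(self.a_star, dtype=float), np.shape(s_grid))
        v = np.broadcast_to(np.asarray(self.V_L, dtype=float), np.shape(s_grid))
        reg = np.broadcast_to(np.asarray(self.regime), np.shape(s_grid))
        return pd.DataFrame({"s": s_grid, "a_star": a, "regime": reg, "V_L": v})


def safety_value_for_action(a: float, c0: float, gamma: float, pM: float) -> float:
    """Safety-state value of playing the fixed action ``a`` forever.

    Solving V = p(a)(-c0 a + gamma V + 1) + (1 - p(a))(-1 - c0 a) for V gives
    V = (2 p(a) - 1 - c0 a) / (1 - gamma p(a)).
    """
    p = pM * a * (2.0 - a)
    return (2.0 * p - 1.0 - c0 * a) / (1.0 - gamma * p)


def _solve_one_c0(c0: float, gamma: float, pM: float) -> tuple[float, float, str, dict]:
    bound = 2.0 * pM * (2.0 - gamma)
    eps = (2.0 - gamma) / gamma
    if c0 <= 0:
        return 1.0, safety_value_for_action(1.0, c0, gamma, pM), "boundary_one", {}
    K = eps / c0
    C = -1.0 / (pM * gamma) + 2.0 * eps / c0
    consts = {"K": K, "A": C, "epsilon": eps, "C": C}
    if c0 < bound:
        disc = K * K - C
        if disc < 0:
            raise ArithmeticError(
                "negative discriminant inside the existence region; "
                "inconsistent closed-form constants"
            )
        a = K - np.sqrt(disc)
        return float(a), safety_value_for_action(a, c0, gamma, pM), "interior", consts
    v0 = safety_value_for_action(0.0, c0, gamma, pM)
    v1 = safety_value_for_action(1.0, c0, gamma, pM)
    if v1 > v0:
        return 1.0, v1, "boundary_one", consts
    return 0.0, v0, "boundary_zero", consts


def defense_closed_form(cfg: DefenseConfig) -> DefenseSolution:
    """Closed-form optimal defensive action for a constant cost.

    The action does not depend on starvation; a single scalar is returned.
    """
    if cfg.cost.form != "constant":
        raise ValueError("defense_closed_form requires a constant cost")
    a, v, regime, consts = _solve_one_c0(cfg.cost.c0_base, cfg.gamma, cfg.success.pM)
    return DefenseSolution(a, v, regime, consts, method="closed_form")


def defense_closed_form_increasing_cost(
    cfg: DefenseConfig, s_grid: np.ndarray | None = None
) -> DefenseSolution:
    """Closed-form defensive policy under a starvation-dependent cost.

    Evaluates the closed form at each starvation value of ``s_grid`` with
    ``c0(s) = c0_base + slope * s``.  Requires a non-decreasing cost; the
    resulting action profile is non-increasing in s.
    """
    if cfg.cost.slope < 0:
        raise ValueError("c0(s) must be non-decreasing in starvation")
    grid = cfg.starvation_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    a = np.empty_like(grid)
    v = np.empty_like(grid)
    regime = np.empty(grid.shape, dtype=object)
    Ks = np.empty_like(grid)
    Cs = np.empty_like(grid)
    for j, s in enumerate(grid):
        c0_s = float(cfg.cost.c0(s))
        a[j], v[j], regime[j], consts = _solve_one_c0(c0_s, cfg.gamma, cfg.success.pM)
        Ks[j] = consts.get("K", np.nan)
        Cs[j] = consts.get("C", np.nan)
    consts = {
        "epsilon": (2.0 - cfg.gamma) / cfg.gamma,
        "K": Ks,
        "C": Cs,
        "A": Cs,
    }
    return DefenseSolution(a, v, regime, consts, method="closed_form")


def defense_value_iteration(
    cfg: DefenseConfig,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    action_grid: int = 1001,
    s_grid: np.ndarray | None = None,
) -> DefenseSolution:
    """Fixed-point iteration on the safety-state value.

    Iterates V <- max_a [ p(a)(-c0 a + gamma V + 1) + (1 - p(a))(-1 - c0 a) ]
    (a contraction with factor gamma * pM) and returns the greedy action on
    an even action grid.  With a starvation-dependent cost the fixed point
    is solved independently at each grid starvation value.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pM, gamma = cfg.success.pM, cfg.gamma
    acts = np.linspace(0.0, 1.0, action_grid)
    p = pM * acts * (2.0 - acts)

    def solve_scalar(c0: float) -> tuple[float, float, int, float, bool]:
        V = 0.0
        for it in range(1, max_iter + 1):
            Q = p * (-c0 * acts + gamma * V + 1.0) + (1.0 - p) * (-1.0 - c0 * acts)
            V_new = float(Q.max())
            res = abs(V_new - V)
            V = V_new
            if res <= tol:
                return float(acts[int(Q.argmax())]), V, it, res, True
        return float(acts[int(Q.argmax())]), V, max_iter, res, False

    if cfg.cost.form == "constant" and s_grid is None:
        a, v, it, res, ok = solve_scalar(cfg.cost.c0_base)
        regime = "interior" if 0.0 < a < 1.0 else ("boundary_zero" if a == 0.0 else "boundary_one")
        return DefenseSolution(a, v, regime, {}, "value_iteration", it, res, ok)

    grid = cfg.starvation_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    a = np.empty_like(grid)
    v = np.empty_like(grid)
    regime = np.empty(grid.shape, dtype=object)
    its, res_max, ok_all = 0, 0.0, True
    for j, s in enumerate(grid):
        a[j], v[j], it, res, ok = solve_scalar(float(cfg.cost.c0(s)))
        regime[j] = (
            "interior" if 0.0 < a[j] < 1.0 else ("boundary_zero" if a[j] == 0.0 else "boundary_one")
        )
        its = max(its, it)
        res_max = max(res_max, res)
        ok_all = ok_all and ok
    return DefenseSolution(a, v, regime, {}, "value_iteration", its, res_max, ok_all)
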