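"""Solvers for the predatory starvation MDP.

Two routes to the optimal stinging intensity a*(s):

* exact **value iteration** on the Bellman optimality operator, a
  gamma-contraction in the sup norm, with the absorbing most-starved state
  pinned at V = 0;
* the **asymptotic** first-order relation obtained by assuming a*(s) varies
  slowly across neighbouring states, which collapses the coupled optimality
  conditions to a per-state scalar equation

      c'(a*) / p'(a*) = (r(s-1) - r(s+1)) / (1 - gamma).

The asymptotic route is an approximation: it is accurate when the implied
optimal actions are moderate (so p'(a) is well away from zero) and the
occupation of the chain is spread over interior states.  When the reward
differential dwarfs 1 - gamma the exact policy saturates near a = 1 and
pools mass at the satiation boundary, and the approximation degrades there
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model_spec import PredationMDP

__all__ = [
    "PolicySolution",
    "bellman_update",
    "value_iteration",
    "asymptotic_policy",
    "solve_with_increasing_cost",
    "policy_monotonicity_report",
]


@dataclass
class PolicySolution:
    """Optimal value function and policy with solver diagnostics."""

    V: np.ndarray
    a_star: np.ndarray
    iterations: int
    final_residual: float
    method: str
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def to_frame(self, mdp: PredationMDP):
        import pandas as pd

        return pd.DataFrame(
            {"s": mdp.state_grid, "V": self.V, "a_star": self.a_star, "method": self.method}
        )


def _q_matrix(V: np.ndarray, mdp: PredationMDP) -> np.ndarray:
    """State-by-action matrix of Bellman action values (absorbing row excluded later)."""
    idx = np.arange(mdp.n_states)
    up = np.maximum(idx - 1, 0)          # landing index on success
    dn = np.minimum(idx + 1, mdp.absorbing_index)  # landing index on failure
    r = mdp.reward_array()
    a = mdp.action_values
    p = mdp.success(a)
    gain = r[up] + mdp.gamma * V[up]     # per-state value of success landing
    loss = r[dn] + mdp.gamma * V[dn]
    cost = mdp.cost(a[None, :], mdp.state_grid[:, None])
    return p[None, :] * gain[:, None] + (1.0 - p[None, :]) * loss[:, None] - cost


def bellman_update(V: np.ndarray, mdp: PredationMDP) -> tuple[np.ndarray, np.ndarray]:
    """One sweep of the Bellman optimality operator.

    Returns the updated value array and the greedy action per state.  The
    absorbing state keeps value 0 and action 0; ties in the argmax resolve
    to the smallest action on the grid.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != (mdp.n_states,):
        raise ValueError(f"value array must have length {mdp.n_states}")
    Q = _q_matrix(V, mdp)
    best = Q.argmax(axis=1)  # first maximizer = smallest action
    V_new = Q[np.arange(mdp.n_states), best]
    a_new = mdp.action_values[best]
    V_new[mdp.absorbing_index] = 0.0
    a_new[mdp.absorbing_index] = 0.0
    return V_new, a_new


def value_iteration(
    mdp: PredationMDP,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    V0: np.ndarray | None = None,
) -> PolicySolution:
    """Solve the predatory MDP by value iteration.

    Iterates the Bellman operator until the sup-norm update falls below
    ``tol`` (or ``max_iter`` sweeps, flagged as non-converged).  ``V0``
    warm-starts the iteration, useful when scanning nearby cost parameters.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    V = np.zeros(mdp.n_states) if V0 is None else np.asarray(V0, dtype=float).copy()
    V[mdp.absorbing_index] = 0.0
    a = np.zeros(mdp.n_states)
    residual = np.inf
    for it in range(1, max_iter + 1):
        V_new, a = bellman_update(V, mdp)
        residual = float(np.max(np.abs(V_new - V)))
        V = V_new
        if residual <= tol:
            return PolicySolution(V, a, it, residual, "value_iteration", True)
    return PolicySolution(V, a, max_iter, residual, "value_iteration", False)


def _policy_value(a_star: np.ndarray, mdp: PredationMDP, tol: float = 1e-10) -> np.ndarray:
    """Evaluate a fixed stationary policy by solving the linear value equations."""
    n = mdp.n_states
    idx = np.arange(n)
    up = np.maximum(idx - 1, 0)
    dn = np.minimum(idx + 1, mdp.absorbing_index)
    r = mdp.reward_array()
    p = np.asarray(mdp.success(a_star), dtype=float)
    c = np.asarray(mdp.cost(a_star, mdp.state_grid), dtype=float)
    A = np.eye(n)
    b = np.zeros(n)
    for i in range(n - 1):
        A[i, up[i]] -= mdp.gamma * p[i]
        A[i, dn[i]] -= mdp.gamma * (1.0 - p[i])
        b[i] = p[i] * r[up[i]] + (1.0 - p[i]) * r[dn[i]] - c[i]
    return np.linalg.solve(A, b)


def asymptotic_policy(mdp: PredationMDP, root_tol: float = 1e-8) -> PolicySolution:
    """Slow-policy asymptotic solution of the predatory MDP.

    For each non-absorbing state, solves ``p'(a) * q(s) = c'(a, s)`` with
    ``q(s) = (r(s-1) - r(s+1)) / (1 - gamma)`` by bracketing (tolerance
    ``root_tol``); the reward difference is one-sided (scaled to the
    two-step span) at the grid edges.  If no interior root exists, the
    boundary action maximizing the asymptotic surrogate objective
    ``p(a) q(s) - c(a, s)`` is chosen.  Valid under non-increasing reward,
    concave p and convex c.
    """
    r = mdp.reward_array()
    if np.any(np.diff(r[:-1]) > 1e-12):
        raise ValueError("asymptotic solution requires a non-increasing reward")
    n = mdp.n_states
    s_grid = mdp.state_grid
    a_star = np.zeros(n)
    for i in range(n - 1):
        if 0 < i < n - 1:
            delta = r[i - 1] - r[i + 1]
        else:  # one-sided at the satiation edge, scaled to the central span
            delta = 2.0 * (r[i] - r[i + 1])
        q = delta / (1.0 - mdp.gamma)
        c0_s = float(mdp.cost.c0(s_grid[i]))

        def foc(a, q=q, c0_s=c0_s):
            return mdp.success.derivative(a) * q - c0_s

        if q <= 0 or foc(0.0) <= 0:
            # no interior stationary point: compare the surrogate at the endpoints
            a_star[i] = 1.0 if mdp.success(1.0) * q - c0_s > 0.0 else 0.0
        elif foc(1.0) >= 0:
            a_star[i] = 1.0
        else:
            a_star[i] = brentq(foc, 0.0, 1.0, xtol=root_tol)
    V = _policy_value(a_star, mdp)
    return PolicySolution(V, a_star, 0, 0.0, "asymptotic", True)


def solve_with_increasing_cost(mdp: PredationMDP, **kwargs) -> PolicySolution:
    """Value iteration with the starvation-dependent cost c(a, s) = c0(s) a.

    Identical to :func:`value_iteration` (which already evaluates the cost
    per state); additionally reports whether the resulting policy still
    increases with starvation, the regime boundary the model predicts for
    moderate versus steep cost growth.
    """
    if mdp.cost.slope < 0:
        raise ValueError("cost slope must be >= 0")
    sol = value_iteration(mdp, **kwargs)
    sol.extras["monotonicity"] = policy_monotonicity_report(sol)
    return sol


def policy_monotonicity_report(sol: PolicySolution | np.ndarray, atol: float = 1e-9) -> dict:
    """Summarize the direction of a policy over non-absorbing states.

    Counts sign changes of successive action differences; ``violations`` is
    the number of steps moving against the dominant direction.
    """
    a = sol.a_star if isinstance(sol, PolicySolution) else np.asarray(sol, dtype=float)
    diffs = np.diff(a[:-1])  # exclude the absorbing state's placeholder action
    pos = int(np.sum(diffs > atol))
    neg = int(np.sum(diffs < -atol))
    if pos == 0 and neg == 0:
        direction = "constant"
    elif neg == 0:
        direction = "increasing"
    elif pos == 0:
        direction = "decreasing"
    else:
        direction = "mixed"
    return {
        "direction": direction,
        "violations": min(pos, neg),
        "n_increasing_steps": pos,
        "n_decreasing_steps": neg,
    }
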