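"""Independent brute-force oracles used to validate the solvers.

Everything here recomputes results from the model definition alone
(rewards, costs, success probabilities, transition rule) without calling
any solver code, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def evaluate_stationary_policy(mdp, actions: np.ndarray) -> np.ndarray:
    """Exact value of a fixed policy via the linear value equations.

    For each non-absorbing state i with action a_i the value satisfies
    V_i = p(a_i) (r_up + g V_up) + (1 - p(a_i)) (r_dn + g V_dn) - c(a_i, s_i)
    with the absorbing state pinned at 0; solved directly as a linear
    system.
    """
    n = mdp.n_states
    r = mdp.reward_array()
    s = mdp.state_grid
    A = np.eye(n)
    b = np.zeros(n)
    for i in range(n - 1):
        up = max(i - 1, 0)
        dn = min(i + 1, n - 1)
        p = float(mdp.success(actions[i]))
        A[i, up] -= mdp.gamma * p
        A[i, dn] -= mdp.gamma * (1.0 - p)
        b[i] = p * r[up] + (1.0 - p) * r[dn] - float(mdp.cost(actions[i], s[i]))
    return np.linalg.solve(A, b)


def enumerate_optimal_values(mdp) -> np.ndarray:
    """Optimal value function by exhaustive stationary-policy enumeration.

    Evaluates every assignment of grid actions to non-absorbing states
    (|A|^(n-1) policies) and takes the state-wise maximum, which equals the
    optimal value function since some stationary policy dominates all
    others state-wise.
    """
    n = mdp.n_states
    acts = mdp.action_values
    best = np.full(n, -np.inf)
    best[-1] = 0.0
    for combo in itertools.product(acts, repeat=n - 1):
        actions = np.append(np.asarray(combo, dtype=float), 0.0)
        V = evaluate_stationary_policy(mdp, actions)
        best = np.maximum(best, V)
    return best
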