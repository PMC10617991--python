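"""Stochastic agent simulations through the predatory MDP.

Agents sting sequentially: each event draws a success with probability
p(a), moving one grid state toward satiation on success (clamped at the
least-starved state) and one toward starvation on failure, until the
absorbing most-starved state or the event horizon.  Policies are either a
per-state action table (e.g. from value iteration) or a
:class:`RandomPolicy` drawing a fresh uniform action every event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_spec import PredationMDP

__all__ = [
    "RandomPolicy",
    "AgentTrajectory",
    "simulate_agent",
    "simulate_cohort",
    "matched_random_policy",
]


@dataclass(frozen=True)
class RandomPolicy:
    """Uniform random stinging intensity on [a_min, a_max]."""

    a_min: float = 0.0
    a_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_min <= self.a_max <= 1.0):
            raise ValueError("require 0 <= a_min <= a_max <= 1")

    @property
    def mean(self) -> float:
        return 0.5 * (self.a_min + self.a_max)

    def sample(self, rng: np.random.Generator) -> float:
        if self.a_min == self.a_max:
            return self.a_min
        return float(rng.uniform(self.a_min, self.a_max))


@dataclass
class AgentTrajectory:
    """Per-event record of one simulated agent.

    ``states`` holds the state index *after* each event; ``absorbed_at`` is
    the number of events performed when the absorbing state was first
    entered (0 if the agent started there), or None if never absorbed
    within the horizon.
    """

    states: np.ndarray
    actions: np.ndarray
    successes: np.ndarray
    costs: np.ndarray
    start_index: int
    absorbed_at: int | None
    seed: int | None = None

    @property
    def n_events(self) -> int:
        return len(self.actions)

    def to_frame(self, mdp: PredationMDP, agent: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent": agent,
                "event": np.arange(1, self.n_events + 1),
                "s": mdp.state_grid[self.states],
                "a": self.actions,
                "success": self.successes,
                "cost": self.costs,
            }
        )


def _snap_to_grid(s0: float, mdp: PredationMDP) -> int:
    if not (0.0 <= s0 <= 1.0):
        raise ValueError("initial starvation must lie in [0, 1]")
    return int(round(s0 * (mdp.n_states - 1)))


def _action_for(policy, i: int, rng: np.random.Generator) -> float:
    if isinstance(policy, RandomPolicy):
        return policy.sample(rng)
    if callable(policy):
        return float(policy(i, rng))
    return float(np.asarray(policy, dtype=float)[i])


def simulate_agent(
    mdp: PredationMDP,
    policy,
    s0: float,
    n_events: int,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> AgentTrajectory:
    """Simulate one agent for up to ``n_events`` stinging events.

    ``policy`` is a per-state action array, a :class:`RandomPolicy`, or a
    callable ``(state_index, rng) -> action``.  The trajectory stops
    recording once the absorbing state is entered.  Runs are reproducible
    given the seed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i = _snap_to_grid(s0, mdp)
    states, actions, successes, costs = [], [], [], []
    absorbed_at = None
    if i == mdp.absorbing_index:
        absorbed_at = 0
    else:
        for _ in range(n_events):
            a = _action_for(policy, i, rng)
            if not (0.0 <= a <= 1.0):
                raise ValueError("policy produced an action outside [0, 1]")
            success = rng.random() < mdp.success(a)
            i = mdp.success_index(i) if success else mdp.failure_index(i)
            states.append(i)
            actions.append(a)
            successes.append(success)
            costs.append(float(mdp.cost(a, mdp.state_grid[i])))
            if i == mdp.absorbing_index:
                absorbed_at = len(actions)
                break
    return AgentTrajectory(
        states=np.asarray(states, dtype=int),
        actions=np.asarray(actions, dtype=float),
        successes=np.asarray(successes, dtype=bool),
        costs=np.asarray(costs, dtype=float),
        start_index=_snap_to_grid(s0, mdp),
        absorbed_at=absorbed_at,
        seed=None if isinstance(seed, (np.random.Generator, np.random.SeedSequence)) else int(seed),
    )


def simulate_cohort(
    mdp: PredationMDP,
    policy,
    s0: float,
    n_agents: int,
    n_events: int,
    seed: int = 0,
) -> dict:
    """Simulate a cohort and summarize it.

    Per-agent generators are spawned deterministically from the master seed,
    so summaries do not depend on agent ordering.  The long-run mean
    starvation is pooled over the second half of the horizon of non-absorbed
    agents; absorbed agents contribute +inf to the events-to-absorption
    median.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(n_agents)
    trajectories = []
    events_to_absorption = np.full(n_agents, np.inf)
    longrun_means = []
    all_actions = []
    for k in range(n_agents):
        traj = simulate_agent(mdp, policy, s0, n_events, np.random.default_rng(streams[k]))
        trajectories.append(traj)
        if traj.absorbed_at is not None:
            events_to_absorption[k] = traj.absorbed_at
        elif traj.n_events:
            tail = traj.states[traj.n_events // 2 :]
            longrun_means.append(float(np.mean(mdp.state_grid[tail])))
        if traj.n_events:
            all_actions.append(traj.actions)
    pooled = np.concatenate(all_actions) if all_actions else np.array([])
    return {
        "n_agents": n_agents,
        "n_events": n_events,
        "seed": seed,
        "median_events_to_absorption": float(np.median(events_to_absorption)),
        "fraction_absorbed": float(np.mean(np.isfinite(events_to_absorption))),
        "longrun_mean_s": float(np.mean(longrun_means)) if longrun_means else float("nan"),
        "mean_action": float(pooled.mean()) if pooled.size else float("nan"),
        "trajectories": trajectories,
    }


def cohort_frame(summary: dict, mdp: PredationMDP) -> pd.DataFrame:
    """Long-format event table (agent, event, s, a, success) for a cohort."""
    frames = [
        t.to_frame(mdp, agent=k) for k, t in enumerate(summary["trajectories"]) if t.n_events
    ]
    if not frames:
        return pd.DataFrame(columns=["agent", "event", "s", "a", "success", "cost"])
    return pd.concat(frames, ignore_index=True)


def matched_random_policy(mean_action: float | dict) -> RandomPolicy:
    """Uniform policy whose mean action matches an optimal cohort's.

    Bounds are centered at the target mean with the widest half-width that
    keeps them inside [0, 1]; a mean outside (0, 1) degenerates to a point
    policy.
    """
    abar = mean_action["mean_action"] if isinstance(mean_action, dict) else float(mean_action)
    if not (0.0 < abar < 1.0):
        a = float(np.clip(abar, 0.0, 1.0))
        return RandomPolicy(a, a)
    w = min(abar, 1.0 - abar)
    return RandomPolicy(abar - w, abar + w)
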