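"""Model ingredients for the stinging decision problems.

A sea anemone that stings must hedge the intensity of each attack: firing a
fraction ``a`` of its single-use nematocysts costs resources (each capsule
must be regenerated) but raises the probability that the attack succeeds.
This module houses the three ingredients shared by the predatory and
defensive formulations --

* a reward ``r(s)`` expressing the desirability of a nutritional
  (starvation) state ``s in [0, 1]``, non-increasing in ``s``;
* a cost ``c(a, s) = c0(s) * a`` linear in the fraction of nematocysts
  fired, with a full-discharge cost ``c0`` that may rise with starvation;
* a success probability ``p(a) = pM * a * (2 - a)``, concave, saturating at
  ``pM`` for a full discharge --

and the two problem containers built from them: the discretized predatory
:class:`PredationMDP` (starvation chain with an absorbing most-starved
state) and the two-state defensive :class:`DefenseConfig` (safety/danger).

All costs and rewards are expressed in units of the starvation penalty, so
landing in the absorbing most-starved state is worth exactly -1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "RewardSpec",
    "CostSpec",
    "SuccessSpec",
    "PredationMDP",
    "DefenseConfig",
    "build_reward",
    "build_cost",
    "build_success",
    "load_config",
    "predation_mdp_from_config",
    "defense_config_from_config",
    "STARVATION_PENALTY",
]

#: Reward of landing in the absorbing most-starved state, in normalized units.
STARVATION_PENALTY = -1.0

_REWARD_FORMS = ("atan_example", "cos_example", "custom_tabulated")
_COST_FORMS = ("constant", "linear_increasing")

# Prefactors of the two built-in reward examples, as used in the figures.
_DEFAULT_SCALES = {"atan_example": 10.0, "cos_example": 5.0}


@dataclass(frozen=True)
class RewardSpec:
    """Desirability of the nutritional state.

    ``atan_example`` is ``scale * atan(1 - s)`` (default scale 10);
    ``cos_example`` is ``scale * cos(s * pi / 2)`` (default scale 5);
    ``custom_tabulated`` interpolates a user table of ``(s, r)`` pairs,
    normalized so the most-starved entry equals -1.
    """

    form: str = "cos_example"
    scale: float | None = None
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.form not in _REWARD_FORMS:
            raise ValueError(f"unknown reward form {self.form!r}")
        if self.form == "custom_tabulated":
            if self.table is None or len(self.table) < 2:
                raise ValueError("custom_tabulated requires a table of >=2 (s, r) pairs")
            s, r = self._table_arrays()
            if np.any(np.diff(s) <= 0):
                raise ValueError("custom reward table: s values must be strictly increasing")
            if s[0] < 0 or s[-1] != 1.0:
                raise ValueError("custom reward table must cover s up to 1 within [0, 1]")
            if np.any(np.diff(r) > 0):
                raise ValueError("reward must be non-increasing in starvation")
            if r[-1] >= 0:
                raise ValueError("custom reward table needs a negative penalty at s=1")
        elif self.table is not None:
            raise ValueError("table is only valid for the custom_tabulated form")

    def _table_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.table, dtype=float)
        return arr[:, 0], arr[:, 1]

    @property
    def effective_scale(self) -> float:
        return self.scale if self.scale is not None else _DEFAULT_SCALES.get(self.form, 1.0)

    def __call__(self, s: np.ndarray | float) -> np.ndarray | float:
        """Evaluate r(s); custom tables are normalized so r(1) = -1."""
        s = np.asarray(s, dtype=float)
        if self.form == "atan_example":
            return self.effective_scale * np.arctan(1.0 - s)
        if self.form == "cos_example":
            return self.effective_scale * np.cos(s * np.pi / 2.0)
        xs, ys = self._table_arrays()
        return np.interp(s, xs, ys) / abs(ys[-1])


@dataclass(frozen=True)
class CostSpec:
    """Linear discharge cost ``c(a, s) = c0(s) * a`` with ``c0(s) = c0_base + slope * s``."""

    c0_base: float = 1.0
    slope: float = 0.0
    form: str = "constant"

    def __post_init__(self) -> None:
        if self.form not in _COST_FORMS:
            raise ValueError(f"unknown cost form {self.form!r}")
        if self.c0_base < 0:
            raise ValueError("c0_base must be >= 0")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.form == "constant" and self.slope != 0:
            raise ValueError("constant cost must have slope == 0")

    def c0(self, s: np.ndarray | float) -> np.ndarray | float:
        """Full-discharge cost at starvation s."""
        return self.c0_base + self.slope * np.asarray(s, dtype=float)

    def __call__(self, a, s):
        return self.c0(s) * np.asarray(a, dtype=float)


@dataclass(frozen=True)
class SuccessSpec:
    """Concave success probability ``p(a) = pM * a * (2 - a)``, ``p(1) = pM``."""

    pM: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.pM <= 1.0):
            raise ValueError("pM must lie in (0, 1]")

    def __call__(self, a: np.ndarray | float) -> np.ndarray | float:
        a = np.asarray(a, dtype=float)
        return self.pM * a * (2.0 - a)

    def derivative(self, a: np.ndarray | float) -> np.ndarray | float:
        """p'(a) = 2 pM (1 - a)."""
        return 2.0 * self.pM * (1.0 - np.asarray(a, dtype=float))


def build_reward(spec: RewardSpec, grid: Sequence[float] | np.ndarray) -> np.ndarray:
    """Tabulate the reward on a starvation grid.

    Parameters
    ----------
    spec
        Reward specification.
    grid
        Strictly increasing starvation values in [0, 1].

    Returns
    -------
    numpy.ndarray
        ``r(s_i)``, non-increasing.  Built-in example forms are returned
        exactly as printed (no renormalization); custom tables come back
        scaled so that ``r(1) = -1``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D array with at least two points")
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("grid values must lie in [0, 1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    r = np.asarray(spec(grid), dtype=float)
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("reward must be non-increasing on the grid")
    return r


def build_cost(spec: CostSpec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Return the callable ``c(a, s)``; validation happens in :class:`CostSpec`."""
    return spec.__call__


def build_success(spec: SuccessSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return the callable ``p(a)``; validation happens in :class:`SuccessSpec`."""
    return spec.__call__


@dataclass(frozen=True)
class PredationMDP:
    """Discretized starvation-state decision problem for predatory stinging.

    States are ``s_i = i / (n_states - 1)``.  A successful sting moves one
    grid index toward satiation (clamped at the least-starved state, where
    satiation cannot improve further); a failed sting moves one index toward
    starvation.  The most-starved index is absorbing, with value 0 and a
    landing penalty of -1.
    """

    n_states: int = 21
    gamma: float = 0.99
    reward: RewardSpec = field(default_factory=RewardSpec)
    cost: CostSpec = field(default_factory=CostSpec)
    success: SuccessSpec = field(default_factory=SuccessSpec)
    action_grid: int = 1001

    def __post_init__(self) -> None:
        if self.n_states < 3:
            raise ValueError("n_states must be >= 3")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.action_grid < 2:
            raise ValueError("action_grid must be >= 2")

    @property
    def absorbing_index(self) -> int:
        return self.n_states - 1

    @property
    def state_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_states)

    @property
    def action_values(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.action_grid)

    def reward_array(self) -> np.ndarray:
        """Landing rewards per state; the absorbing entry is the starvation penalty."""
        r = build_reward(self.reward, self.state_grid).copy()
        r[self.absorbing_index] = STARVATION_PENALTY
        return r

    def success_index(self, i: np.ndarray | int) -> np.ndarray | int:
        """Landing index after a successful sting (absorbing state self-loops)."""
        i = np.asarray(i)
        out = np.where(i == self.absorbing_index, i, np.maximum(i - 1, 0))
        return out if out.ndim else int(out)

    def failure_index(self, i: np.ndarray | int) -> np.ndarray | int:
        """Landing index after a failed sting."""
        i = np.asarray(i)
        out = np.minimum(i + 1, self.absorbing_index)
        return out if out.ndim else int(out)


@dataclass(frozen=True)
class DefenseConfig:
    """Two-state defensive problem: safety (L) versus absorbing danger (D).

    Stinging does not alter starvation here; starvation enters only
    parametrically through the cost ``c0(s)`` evaluated on ``s_grid``.
    Success keeps the agent in L with unit reward, failure drops it into D
    with penalty -1, and V(D) = 0.
    """

    gamma: float = 0.99
    success: SuccessSpec = field(default_factory=SuccessSpec)
    cost: CostSpec = field(default_factory=CostSpec)
    s_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must lie in (0, 1)")
        if self.s_grid is not None:
            g = np.asarray(self.s_grid, dtype=float)
            if g.ndim != 1 or g.size == 0 or g.min() < 0 or g.max() > 1:
                raise ValueError("s_grid values must lie in [0, 1]")

    def starvation_grid(self) -> np.ndarray:
        if self.s_grid is None:
            return np.linspace(0.0, 1.0, 21)
        return np.asarray(self.s_grid, dtype=float)

    @property
    def existence_bound(self) -> float:
        """Largest full-discharge cost admitting an interior optimal action."""
        return 2.0 * self.success.pM * (2.0 - self.gamma)


# ---------------------------------------------------------------------------
# configuration files


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON key-value model configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _reward_from_config(cfg: dict) -> RewardSpec:
    rc = cfg.get("reward", {})
    table = rc.get("table")
    return RewardSpec(
        form=rc.get("form", "cos_example"),
        scale=rc.get("scale"),
        table=tuple(map(tuple, table)) if table is not None else None,
    )


def _cost_from_config(cfg: dict) -> CostSpec:
    cc = cfg.get("cost", {})
    return CostSpec(
        c0_base=float(cc.get("c0_base", 1.0)),
        slope=float(cc.get("slope", 0.0)),
        form=cc.get("form", "constant"),
    )


def _success_from_config(cfg: dict) -> SuccessSpec:
    return SuccessSpec(pM=float(cfg.get("success", {}).get("pM", 0.8)))


def predation_mdp_from_config(cfg: dict) -> PredationMDP:
    """Build a :class:`PredationMDP` from a configuration mapping."""
    return PredationMDP(
        n_states=int(cfg.get("n_states", 21)),
        gamma=float(cfg.get("gamma", 0.99)),
        reward=_reward_from_config(cfg),
        cost=_cost_from_config(cfg),
        success=_success_from_config(cfg),
        action_grid=int(cfg.get("action_grid", 1001)),
    )


def defense_config_from_config(cfg: dict) -> DefenseConfig:
    """Build a :class:`DefenseConfig` from a configuration mapping."""
    s_grid = cfg.get("s_grid")
    return DefenseConfig(
        gamma=float(cfg.get("gamma", 0.99)),
        success=_success_from_config(cfg),
        cost=_cost_from_config(cfg),
        s_grid=tuple(s_grid) if s_grid is not None else None,
    )
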