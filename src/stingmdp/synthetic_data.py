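"""Synthetic behavioral datasets and toy model instances.

The behavioral assay behind the discharge data reports, per animal and
feeding condition, how many nematocysts fired into a gelatin-coated
coverslip.  No denominator ("capsules at risk") is observable in that
assay, so the generator draws bounded counts: condition means follow the
chosen model's optimal policy scaled by a normalization lambda, and
per-animal counts are binomial (beta-binomial when an overdispersion is
requested) on a configurable capsules-at-risk denominator.

Three species profiles mirror the behavioral contrast: discharge rising
with starvation for a predatory animal, and flat or slightly decreasing
discharge for a defensive, symbiont-bearing animal (n = 10 animals per
condition, deprivation up to 5 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior_fit import BehaviorDataset, map_days_to_starvation, model_action_curve
from .model_spec import CostSpec, DefenseConfig, PredationMDP, RewardSpec, SuccessSpec

__all__ = ["GeneratorSpec", "generate_behavior_dataset", "generate_toy_mdp_fixtures"]

_PROFILES = ("increasing_predatory", "flat_defensive", "slightly_decreasing_defensive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Study design of a synthetic discharge assay."""

    species_profile: str = "slightly_decreasing_defensive"
    n_animals: int = 10
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    capsules_at_risk: int = 200
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_profile not in _PROFILES:
            raise ValueError(f"unknown species profile {self.species_profile!r}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if len(self.days) == 0:
            raise ValueError("days must be non-empty")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _default_truth(profile: str) -> dict:
    """Generating parameters per profile; the cost slope carries the contrast."""
    if profile == "increasing_predatory":
        cost = CostSpec(c0_base=1.0, slope=0.0, form="constant")
        model = "predation"
    elif profile == "flat_defensive":
        cost = CostSpec(c0_base=1.0, slope=0.0, form="constant")
        model = "defense"
    else:  # slightly_decreasing_defensive
        cost = CostSpec(c0_base=1.0, slope=0.4, form="linear_increasing")
        model = "defense"
    return {
        "model": model,
        "cost": cost,
        "reward": RewardSpec(form="cos_example"),
        "gamma": 0.99,
        "pM": 0.8,
        "scale_lambda": 0.8,
        "s_last": 0.5,
    }


def _base_config(truth: dict) -> PredationMDP | DefenseConfig:
    success = SuccessSpec(pM=truth["pM"])
    if truth["model"] == "predation":
        return PredationMDP(gamma=truth["gamma"], reward=truth["reward"], cost=truth["cost"], success=success)
    return DefenseConfig(gamma=truth["gamma"], cost=truth["cost"], success=success)


def generate_behavior_dataset(
    spec: GeneratorSpec, truth: dict | None = None
) -> tuple[BehaviorDataset, dict]:
    """Generate a discharge dataset from a known model truth.

    Solves the chosen model, maps days onto the starvation axis, sets the
    per-condition mean fraction to ``lambda * a*(s)`` and draws per-animal
    counts.  Returns the dataset together with the generating truth (for
    parameter-recovery tests).
    """
    truth = {**_default_truth(spec.species_profile), **(truth or {})}
    cfg = _base_config(truth)
    days = np.asarray(spec.days, dtype=float)
    s_values = map_days_to_starvation(days, truth["s_last"])
    actions, _ = model_action_curve(truth["cost"], truth["model"], cfg, s_values)
    means = truth["scale_lambda"] * actions
    if np.any(means > 1.0):
        raise ValueError("scaled mean fraction exceeds 1; lower scale_lambda")
    rng = np.random.default_rng(spec.seed)
    rows = []
    species = "predatory_model" if truth["model"] == "predation" else "defensive_model"
    for day, mu in zip(spec.days, means):
        if spec.dispersion > 0 and 0.0 < mu < 1.0:
            # beta-binomial with intraclass correlation rho = dispersion
            nu = 1.0 / spec.dispersion - 1.0
            ps = rng.beta(mu * nu, (1.0 - mu) * nu, size=spec.n_animals)
        else:
            ps = np.full(spec.n_animals, mu)
        counts = rng.binomial(spec.capsules_at_risk, ps)
        for animal, count in enumerate(counts):
            rows.append(
                {
                    "species": species,
                    "days_starved": int(day),
                    "animal_id": animal,
                    "discharged_count": int(count),
                    "assay_scale": spec.capsules_at_risk,
                }
            )
    dataset = BehaviorDataset(pd.DataFrame(rows), species=species)
    truth_record = {
        "model": truth["model"],
        "c0_base": truth["cost"].c0_base,
        "slope": truth["cost"].slope,
        "gamma": truth["gamma"],
        "pM": truth["pM"],
        "scale_lambda": truth["scale_lambda"],
        "s_last": truth["s_last"],
        "condition_means": means.tolist(),
        "seed": spec.seed,
    }
    return dataset, truth_record


def generate_toy_mdp_fixtures() -> list[PredationMDP]:
    """Small predatory MDPs amenable to exhaustive policy enumeration.

    Four states and a three-point action grid give 3^3 = 27 stationary
    policies, few enough to evaluate every one exactly via the linear value
    equations.  Parameters vary the reward form, discount, cost and success
    ceiling so the set exercises interior and boundary optima.
    """
    step_table = ((0.0, 0.0), (0.95, 0.0), (1.0, -1.0))
    fixtures = [
        PredationMDP(n_states=4, action_grid=3, gamma=0.9),
        PredationMDP(n_states=4, action_grid=3, gamma=0.5, reward=RewardSpec(form="atan_example")),
        PredationMDP(n_states=4, action_grid=3, gamma=0.8, cost=CostSpec(c0_base=3.0)),
        PredationMDP(n_states=4, action_grid=3, gamma=0.95, success=SuccessSpec(pM=0.3)),
        PredationMDP(
            n_states=4,
            action_grid=3,
            gamma=0.7,
            reward=RewardSpec(form="custom_tabulated", table=step_table),
            cost=CostSpec(c0_base=5.0),
        ),
        PredationMDP(
            n_states=4,
            action_grid=3,
            gamma=0.9,
            cost=CostSpec(c0_base=0.5, slope=2.0, form="linear_increasing"),
        ),
    ]
    return fixtures
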