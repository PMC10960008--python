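"""Run configuration files and the badge color scale.

Configs are YAML or JSON mappings with optional sections ``seed``,
``n_per_cell``, ``stimulus``, ``dynamics``, ``agents`` and ``conditions``;
anything omitted falls back to the calibrated defaults. The badge color
scale maps integer credibility scores to the ten named decile colors used
for source-credibility badges (cosmetic: names, not exact hues).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .agents import CONDITIONS, AgentParams, CohortDistribution, Condition
from .dynamics import DeltaParams, DynamicsParams, EngagementAction
from .experiment import ExperimentConfig
from .stimuli import (
    CommentLikesParams,
    DisplayCountParams,
    FollowerCountParams,
    SourceCredibilityParams,
    StimulusParams,
)

__all__ = ["BADGE_COLORS", "badge_color", "load_config", "config_to_dict"]

#: decile color names, dark red (lowest) to dark blue (highest)
BADGE_COLORS = (
    "dark red",      # [0, 10)
    "red",           # [10, 20)
    "orange red",    # [20, 30)
    "orange",        # [30, 40)
    "gold",          # [40, 50)
    "turquoise",     # [50, 60)
    "sky blue",      # [60, 70)
    "blue",          # [70, 80)
    "royal blue",    # [80, 90)
    "dark blue",     # [90, 100]
)


def badge_color(credibility: int) -> str:
    """Color name for a credibility score.

    Decile bins are half-open ([0,10), ..., [80,90)) with the top bin
    closed ([90,100]); the shared boundary 50 belongs to the upper half
    (turquoise).
    """
    c = int(credibility)
    if c != credibility or not 0 <= c <= 100:
        raise ValueError("credibility must be an integer in [0, 100]")
    return BADGE_COLORS[min(c // 10, 9)]


def _build(cls, section: dict | None, **extra):
    if section is None:
        section = {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**section, **extra})


def _dynamics_from_dict(section: dict | None) -> DynamicsParams:
    if not section:
        return DynamicsParams()
    table = dict(DynamicsParams().table)
    for key, vals in section.items():
        vlabel, alabel = key.rsplit("_", 1)
        veracity = {"true": True, "false": False}[vlabel.lower()]
        table[(veracity, EngagementAction(alabel))] = DeltaParams(**vals)
    return DynamicsParams(table=table)


def _agents_from_dict(section: dict | None) -> CohortDistribution:
    if not section:
        return CohortDistribution()
    section = dict(section)
    mean_kwargs = section.pop("mean", {})
    if "action_intercepts" in mean_kwargs:
        mean_kwargs["action_intercepts"] = tuple(mean_kwargs["action_intercepts"])
    if "action_slopes" in mean_kwargs:
        mean_kwargs["action_slopes"] = tuple(mean_kwargs["action_slopes"])
    return _build(CohortDistribution, section, mean=_build(AgentParams, mean_kwargs))


def load_config(path: str | Path | None = None, seed: int | None = None) -> ExperimentConfig:
    """Load an ExperimentConfig from YAML/JSON; ``seed`` overrides the file."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    stim_section = dict(data.get("stimulus") or {})
    stimulus = StimulusParams(
        n_true=stim_section.get("n_true", 40),
        n_false=stim_section.get("n_false", 40),
        display=_build(DisplayCountParams, stim_section.get("display")),
        credibility=_build(SourceCredibilityParams, stim_section.get("credibility")),
        comment_likes=_build(CommentLikesParams, stim_section.get("comment_likes")),
        followers=_build(FollowerCountParams, stim_section.get("followers")),
    )
    conditions = tuple(
        Condition(badge=bool(c["badge"]), norm=bool(c["norm"]))
        for c in data.get("conditions", [])
    ) or CONDITIONS
    return ExperimentConfig(
        seed=seed if seed is not None else int(data.get("seed", 0)),
        n_per_cell=int(data.get("n_per_cell", 104)),
        stimulus=stimulus,
        dynamics=_dynamics_from_dict(data.get("dynamics")),
        cohort=_agents_from_dict(data.get("agents")),
        conditions=conditions,
    )


def config_to_dict(config: ExperimentConfig) -> dict:
    """Round-trippable plain-dict form of a config (JSON/YAML friendly)."""
    return {
        "seed": config.seed,
        "n_per_cell": config.n_per_cell,
        "stimulus": dataclasses.asdict(config.stimulus),
        "dynamics": {
            f"{'true' if v else 'false'}_{a.value}": dataclasses.asdict(p)
            for (v, a), p in config.dynamics.table.items()
        },
        "agents": dataclasses.asdict(config.cohort),
        "conditions": [
            {"badge": c.badge, "norm": c.norm} for c in config.conditions
        ],
        "config_hash": config.config_hash(),
    }
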