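"""Dynamic follower-count and credibility-score feedback.

Every non-skip engagement (like, share, flag) triggers stochastic integer
changes to the participant's follower count and credibility score. Follower
changes reward activity regardless of veracity (except that flagging false
posts tends to gain followers); credibility changes are antisymmetric in
veracity — endorsing true content or flagging false content raises
credibility, and vice versa. Skipping changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "EngagementAction",
    "DeltaParams",
    "DynamicsParams",
    "ParticipantState",
    "sample_engagement_deltas",
    "apply_engagement",
    "expected_credibility_drift",
]


class EngagementAction(str, Enum):
    FLAG = "flag"
    SKIP = "skip"
    LIKE = "like"
    SHARE = "share"


ACTIVE_ACTIONS = (EngagementAction.LIKE, EngagementAction.SHARE, EngagementAction.FLAG)


@dataclass(frozen=True)
class DeltaParams:
    """Mean/sd of the normal change distribution for one (veracity, action)."""

    follower_mean: float
    follower_sd: float
    credibility_mean: float
    credibility_sd: float


def _default_table() -> dict[tuple[bool, EngagementAction], DeltaParams]:
    L, S, F = EngagementAction.LIKE, EngagementAction.SHARE, EngagementAction.FLAG
    return {
        (True, L): DeltaParams(1.0, 0.75, 0.5, 0.5),
        (True, S): DeltaParams(2.0, 1.0, 1.0, 0.5),
        (True, F): DeltaParams(0.0, 0.25, -1.5, 0.5),
        (False, L): DeltaParams(1.0, 0.75, -0.5, 0.5),
        (False, S): DeltaParams(2.0, 1.0, -1.0, 0.5),
        (False, F): DeltaParams(0.5, 0.25, 1.5, 0.5),
    }


@dataclass(frozen=True)
class DynamicsParams:
    """Change distributions per (veracity, active action).

    Defaults encode the study conditions: like/share follower gains are
    identical across veracity, flagging false posts gains followers while
    flagging true posts does not, and credibility means are antisymmetric
    across veracity for every action.
    """

    table: Mapping[tuple[bool, EngagementAction], DeltaParams] = field(
        default_factory=_default_table
    )

    def __post_init__(self):
        for v in (True, False):
            for a in ACTIVE_ACTIONS:
                if (v, a) not in self.table:
                    raise ValueError(f"missing delta parameters for ({v}, {a.value})")

    def delta(self, veracity: bool, action: EngagementAction) -> DeltaParams:
        return self.table[(bool(veracity), action)]


@dataclass
class ParticipantState:
    """Evolving simulation state for one participant.

    ``credibility`` is only displayed in badge conditions but is tracked
    uniformly; it lives on a 0-100 scale and is clamped there, as is the
    follower count at zero. ``history`` records every engagement with its
    pre-clamp deltas so trajectories can be audited or replayed.
    """

    follower_count: int = 0
    credibility: int = 50
    history: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if self.follower_count < 0 or not 0 <= self.credibility <= 100:
            raise ValueError("state out of bounds")


def sample_engagement_deltas(
    veracity: bool,
    action: EngagementAction,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Integer (follower delta, credibility delta) for one engagement.

    Skips are exactly (0, 0); active actions round a normal draw with the
    (veracity, action) parameters half-to-even.
    """
    action = EngagementAction(action)
    if action is EngagementAction.SKIP:
        return 0, 0
    p = params.delta(veracity, action)
    # Python round() is round-half-to-even, matching the display convention
    d_f = round(float(rng.normal(p.follower_mean, p.follower_sd)))
    d_c = round(float(rng.normal(p.credibility_mean, p.credibility_sd)))
    return d_f, d_c


def apply_engagement(
    state: ParticipantState,
    veracity: bool,
    action: EngagementAction,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> ParticipantState:
    """Apply one engagement in place: sample deltas, update, clamp, log."""
    d_f, d_c = sample_engagement_deltas(veracity, action, params, rng)
    state.follower_count = max(0, state.follower_count + d_f)
    state.credibility = min(100, max(0, state.credibility + d_c))
    state.history.append(
        {
            "veracity": bool(veracity),
            "action": EngagementAction(action).value,
            "d_followers": d_f,
            "d_credibility": d_c,
            "follower_count": state.follower_count,
            "credibility": state.credibility,
        }
    )
    return state


def expected_credibility_drift(
    action_mix: Mapping[bool, Mapping[EngagementAction, float]],
    params: DynamicsParams,
    atol: float = 1e-9,
) -> float:
    """Closed-form expected credibility change per post, ignoring clamping.

    ``action_mix`` maps each veracity class to a probability distribution
    over the four actions; classes present are weighted equally. Useful for
    calibrating agent policies against the feedback table.
    """
    if not action_mix:
        raise ValueError("action_mix must cover at least one veracity class")
    drifts = []
    for veracity, probs in action_mix.items():
        total = float(sum(probs.values()))
        if abs(total - 1.0) > atol:
            raise ValueError(f"action probabilities for veracity={veracity} sum to {total}")
        drift = 0.0
        for action, p in probs.items():
            action = EngagementAction(action)
            if action is EngagementAction.SKIP:
                continue
            drift += p * params.delta(veracity, action).credibility_mean
        drifts.append(drift)
    return float(np.mean(drifts))
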