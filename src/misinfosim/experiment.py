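"""Run the full 2x2 simulated experiment and emit tidy record tables.

One shared stimulus set (fixed source-post pairings) is shown to every
participant. Each participant sees the posts in a private random order,
engages with each (flag / skip / like / share) while follower count — and,
in badge cells, credibility — update dynamically, then rates belief in
every claim (0-10) in a fresh random order. Outputs are tidy per-trial and
per-rating tables plus a metadata record, all byte-reproducible under a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import (
    CONDITIONS,
    AgentParams,
    CohortDistribution,
    Condition,
    choose_action,
    evidence_mean,
    make_cohort,
    rate_belief,
)
from .dynamics import DynamicsParams, EngagementAction, ParticipantState, sample_engagement_deltas
from .stimuli import Post, StimulusParams, generate_stimulus_set

__all__ = [
    "ExperimentConfig",
    "run_participant",
    "run_experiment",
    "ExperimentResult",
]

TRIAL_COLUMNS = [
    "participant_id", "badge", "norm", "trial_index", "claim_id", "veracity",
    "action", "d_followers", "d_credibility", "follower_count_after",
    "credibility_after",
]
BELIEF_COLUMNS = ["participant_id", "badge", "norm", "claim_id", "veracity", "rating"]


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    n_per_cell: int = 104
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    cohort: CohortDistribution = field(default_factory=CohortDistribution)
    conditions: tuple[Condition, ...] = CONDITIONS

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["dynamics"] = {
            f"{v}_{a.value}": asdict(p) for (v, a), p in self.dynamics.table.items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_participant(
    agent: AgentParams,
    condition: Condition,
    posts: Sequence[Post],
    dynamics: DynamicsParams,
    rng: np.random.Generator,
    participant_id: str = "p000",
) -> tuple[list[dict], list[dict], ParticipantState]:
    """Simulate one participant: engagement phase then belief phase.

    Engagement: posts in a seeded random order; each trial draws perceived
    evidence, picks an action from the softmax policy, and applies the
    dynamic follower/credibility feedback (credibility only tracked and
    recorded in badge cells — without a badge the participant has no
    credibility score and its fields are left as missing sentinels).

    Belief: all claims revisited in a fresh random order; the belief-phase
    evidence shares the engagement-phase noise with correlation ``rho``
    (a memory readout rather than an independent judgement).
    """
    if len(posts) == 0:
        raise ValueError("posts must be nonempty")
    n = len(posts)
    state = ParticipantState(follower_count=0, credibility=50)
    order = rng.permutation(n)
    z_eng = rng.standard_normal(n)  # engagement-phase evidence noise per post

    trials: list[dict] = []
    mus = np.empty(n)
    for t, idx in enumerate(order, start=1):
        post = posts[idx]
        mu = evidence_mean(agent, post, condition)
        mus[idx] = mu
        e = mu + agent.sigma * z_eng[idx]
        action = choose_action(agent, e, post, condition, rng)
        veracity = post.claim.veracity
        d_f, d_c = sample_engagement_deltas(veracity, action, dynamics, rng)
        state.follower_count = max(0, state.follower_count + d_f)
        if condition.badge:
            state.credibility = min(100, max(0, state.credibility + d_c))
        state.history.append(
            {"action": action.value, "d_followers": d_f, "d_credibility": d_c}
        )
        trials.append(
            {
                "participant_id": participant_id,
                "badge": condition.badge,
                "norm": condition.norm,
                "trial_index": t,
                "claim_id": post.claim.claim_id,
                "veracity": veracity,
                "action": action.value,
                "d_followers": d_f,
                "d_credibility": d_c if condition.badge else math.nan,
                "follower_count_after": state.follower_count,
                "credibility_after": state.credibility if condition.badge else math.nan,
            }
        )

    beliefs: list[dict] = []
    belief_order = rng.permutation(n)
    z_new = rng.standard_normal(n)
    rho = agent.rho
    mix = math.sqrt(max(0.0, 1.0 - rho * rho))
    for idx in belief_order:
        post = posts[idx]
        z_b = rho * z_eng[idx] + mix * z_new[idx]
        e_b = mus[idx] + agent.sigma * z_b
        rating = rate_belief(agent, e_b, condition, refuted=not post.claim.veracity)
        beliefs.append(
            {
                "participant_id": participant_id,
                "badge": condition.badge,
                "norm": condition.norm,
                "claim_id": post.claim.claim_id,
                "veracity": post.claim.veracity,
                "rating": rating,
            }
        )
    return trials, beliefs, state


@dataclass
class ExperimentResult:
    trials: pd.DataFrame
    beliefs: pd.DataFrame
    posts: list[Post]
    cohort: list[tuple[AgentParams, Condition]]
    meta: dict

    def write(self, outdir: str | Path) -> None:
        """Write trials.csv, beliefs.csv and run_meta.json (byte-stable)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.beliefs.to_csv(outdir / "beliefs.csv", index=False)
        (outdir / "run_meta.json").write_text(
            json.dumps(self.meta, indent=2, sort_keys=True) + "\n"
        )


def run_experiment(config: ExperimentConfig | None = None, **overrides) -> ExperimentResult:
    """Run the full experiment for every included design cell.

    A single stimulus set is generated once and shared by all participants;
    the cohort is blocked so each cell receives exactly ``n_per_cell``
    agents. Every source of randomness descends from ``config.seed`` via a
    SeedSequence spawn per participant, so results are deterministic and
    independent of evaluation order.
    """
    if config is None:
        config = ExperimentConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")
    if config.n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")

    root = np.random.SeedSequence(config.seed)
    ss_stim, ss_cohort, ss_participants = root.spawn(3)
    posts = generate_stimulus_set(config.stimulus, rng=np.random.default_rng(ss_stim))
    cohort = make_cohort(
        config.n_per_cell,
        dist=config.cohort,
        conditions=config.conditions,
        rng=np.random.default_rng(ss_cohort),
    )

    trial_rows: list[dict] = []
    belief_rows: list[dict] = []
    child_seeds = ss_participants.spawn(len(cohort))
    counters: dict[str, int] = {}
    for (agent, condition), child in zip(cohort, child_seeds):
        counters[condition.label] = counters.get(condition.label, 0) + 1
        pid = f"{condition.label}_{counters[condition.label]:03d}"
        t_rows, b_rows, _ = run_participant(
            agent, condition, posts, config.dynamics,
            np.random.default_rng(child), participant_id=pid,
        )
        trial_rows.extend(t_rows)
        belief_rows.extend(b_rows)

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    beliefs = pd.DataFrame(belief_rows, columns=BELIEF_COLUMNS)
    meta = {
        "seed": config.seed,
        "n_per_cell": config.n_per_cell,
        "n_participants": len(cohort),
        "n_posts": len(posts),
        "config_hash": config.config_hash(),
        "package": "misinfosim",
    }
    return ExperimentResult(
        trials=trials, beliefs=beliefs, posts=posts, cohort=cohort, meta=meta
    )
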