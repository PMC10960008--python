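"""Synthetic participants for the simulated social-media experiment.

Real participants saw 80 posts, chose to flag/skip/like/share each one, and
later rated their belief in each claim on a 0-10 scale. This module supplies
a generative stand-in: each agent forms a noisy latent *perceived evidence*
for a claim's truth from (i) its own discrimination ability, (ii) the
fact-check comments, and (iii) — when credibility badges are shown — the
source's credibility score; actions follow a softmax policy over the
evidence, and belief ratings are a noisy memory readout of the same
evidence.

Intervention effects are structural, not painted on:

* **badge** — the source-credibility signal (``w_src``) and an attention
  boost (``diligence_badge``) sharpen evidence, and a caution term shifts
  the policy toward flagging and away from endorsing dubious posts;
* **norm** — a caution term does the same, and the norm message downshifts
  belief in claims the feed refuted (``delta_norm``).

The defaults are calibrated so the emergent statistics of a simulated
cohort reproduce the qualitative pattern observed with human participants:
badges raise belief in true claims, lower belief in false claims, improve
ROC discrimination, and cut liking/sharing (raising flagging) of false
posts; norms lower false belief and improve discrimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .dynamics import EngagementAction
from .stimuli import CommentKind, Direction, Post

__all__ = [
    "AgentParams",
    "Condition",
    "CONDITIONS",
    "CohortDistribution",
    "null_cohort_distribution",
    "evidence_mean",
    "perceived_evidence",
    "rate_belief",
    "action_probabilities",
    "choose_action",
    "make_cohort",
]

#: canonical action order for intercept/slope vectors
ACTION_ORDER = (
    EngagementAction.FLAG,
    EngagementAction.SKIP,
    EngagementAction.LIKE,
    EngagementAction.SHARE,
)


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 between-subjects design."""

    badge: bool
    norm: bool

    @property
    def label(self) -> str:
        return ("badge" if self.badge else "nobadge") + "_" + ("norm" if self.norm else "nonorm")


CONDITIONS = (
    Condition(badge=False, norm=False),
    Condition(badge=False, norm=True),
    Condition(badge=True, norm=False),
    Condition(badge=True, norm=True),
)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of one synthetic participant.

    Attributes
    ----------
    d : float
        Latent discrimination: half the true-false separation of the
        evidence distribution contributed by the claim itself.
    w_fc : float
        Weight on the net fact-check signal (strong = ±1, weak = ±0.5;
        the strongest comment in a thread dominates).
    w_src : float
        Weight on the standardized source-credibility score, active only
        when the badge is displayed.
    sigma : float
        Evidence noise standard deviation (> 0).
    g : float
        Gain mapping evidence onto the 0-10 belief scale.
    rho : float
        Correlation between the engagement-phase and belief-phase noise
        (belief is a memory readout, not a fresh judgement).
    delta_norm : float
        Norm-condition downshift applied to belief in refuted claims.
    diligence_badge : float
        Fractional boost to d and w_fc when the badge is present
        (badges prompt more careful reading, akin to an accuracy nudge).
    action_intercepts, action_slopes : tuple of 4 floats
        Per-action utility intercepts and evidence loadings, in the order
        (flag, skip, like, share). The flag slope enters negatively.
    caution_badge, caution_norm : float
        Extra flag utility — and like/share penalty when evidence is
        negative — under each intervention.
    popularity_weight : float
        Bandwagon weight on log(1 + displayed likes) in the share utility.
    """

    d: float = 0.8
    w_fc: float = 0.5
    w_src: float = 0.6
    sigma: float = 1.0
    g: float = 2.2
    rho: float = 0.7
    delta_norm: float = 0.25
    diligence_badge: float = 0.2
    action_intercepts: tuple[float, float, float, float] = (-1.2, 0.6, 0.3, -0.2)
    action_slopes: tuple[float, float, float, float] = (1.6, 0.0, 1.0, 1.1)
    caution_badge: float = 0.25
    caution_norm: float = 0.15
    popularity_weight: float = 0.15

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.d < 0 or self.diligence_badge < 0:
            raise ValueError("d and diligence_badge must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.caution_badge < 0 or self.caution_norm < 0 or self.delta_norm < 0:
            raise ValueError("caution and norm-shift parameters must be >= 0")
        if len(self.action_intercepts) != 4 or len(self.action_slopes) != 4:
            raise ValueError("four actions: (flag, skip, like, share)")


def net_factcheck_signal(post: Post) -> float:
    """Net fact-check signal f in {-1, -0.5, +0.5, +1} (0 if no fact-check).

    The strongest fact-check in the thread dominates; sign follows its
    direction (+ affirm, - refute). Neutral comments contribute nothing.
    """
    strength = 0.0
    for c in post.comments:
        if c.kind is CommentKind.STRONG_FACTCHECK:
            s = 1.0
        elif c.kind is CommentKind.WEAK_FACTCHECK:
            s = 0.5
        else:
            continue
        if s > strength:
            strength = s
            sign = 1.0 if c.direction is Direction.AFFIRM else -1.0
    return strength * (sign if strength else 1.0)


def evidence_mean(agent: AgentParams, post: Post, condition: Condition) -> float:
    """Deterministic part of the perceived evidence for one post.

    e_bar = d'·v/2 + w_fc'·f + w_src·b·c~   with v = ±1 for true/false,
    c~ = (credibility − 50)/50 (only when the badge is shown), and
    d' = d·(1 + diligence_badge·b), likewise w_fc'.
    """
    v = 1.0 if post.claim.veracity else -1.0
    boost = 1.0 + agent.diligence_badge * condition.badge
    e = agent.d * boost * v / 2.0 + agent.w_fc * boost * net_factcheck_signal(post)
    if condition.badge:
        e += agent.w_src * (post.source.credibility_score - 50.0) / 50.0
    return e


def perceived_evidence(
    agent: AgentParams,
    post: Post,
    condition: Condition,
    rng: np.random.Generator,
) -> float:
    """One noisy evidence draw: evidence_mean plus N(0, sigma^2) noise."""
    if not post.comments:
        raise ValueError("post must carry at least one comment")
    return evidence_mean(agent, post, condition) + agent.sigma * rng.standard_normal()


def rate_belief(
    agent: AgentParams,
    e: float,
    condition: Condition,
    refuted: bool,
) -> int:
    """Map evidence to a 0-10 belief rating.

    r = clamp(round(5 + g·e − delta_norm·[norm]·[refuted]), 0, 10);
    monotone nondecreasing in e.
    """
    raw = 5.0 + agent.g * e
    if condition.norm and refuted:
        raw -= agent.delta_norm
    return int(min(10, max(0, int(np.rint(raw)))))


def _caution(agent: AgentParams, condition: Condition) -> float:
    return agent.caution_badge * condition.badge + agent.caution_norm * condition.norm


def _utilities(
    agent: AgentParams, e: float, post: Post, condition: Condition
) -> tuple[float, float, float, float]:
    a = agent.action_intercepts
    s = agent.action_slopes
    caution = _caution(agent, condition)
    endorse_penalty = caution if e < 0 else 0.0
    return (
        a[0] - s[0] * e + caution,
        a[1],
        a[2] + s[2] * e - endorse_penalty,
        a[3]
        + s[3] * e
        + agent.popularity_weight * math.log1p(post.displayed_likes)
        - endorse_penalty,
    )


def action_utilities(
    agent: AgentParams, e: float, post: Post, condition: Condition
) -> np.ndarray:
    """Utilities in ACTION_ORDER = (flag, skip, like, share)."""
    return np.array(_utilities(agent, e, post, condition))


def action_probabilities(
    agent: AgentParams, e: float, post: Post, condition: Condition
) -> np.ndarray:
    """Softmax choice probabilities over (flag, skip, like, share)."""
    u = action_utilities(agent, e, post, condition)
    u -= u.max()
    w = np.exp(u)
    return w / w.sum()


def choose_action(
    agent: AgentParams,
    e: float,
    post: Post,
    condition: Condition,
    rng: np.random.Generator,
) -> EngagementAction:
    """Sample one engagement action from the softmax policy."""
    u = _utilities(agent, e, post, condition)
    m = max(u)
    w = tuple(math.exp(ui - m) for ui in u)
    target = rng.random() * (w[0] + w[1] + w[2] + w[3])
    c = 0.0
    for action, wi in zip(ACTION_ORDER, w):
        c += wi
        if target < c:
            return action
    return ACTION_ORDER[-1]


@dataclass(frozen=True)
class CohortDistribution:
    """Between-subject heterogeneity: agent parameters are drawn around
    ``mean`` with the given sds; nonnegative parameters are floored at 0
    and sigma at a small positive value."""

    mean: AgentParams = field(default_factory=AgentParams)
    d_sd: float = 0.25
    w_fc_sd: float = 0.15
    w_src_sd: float = 0.2
    g_sd: float = 0.3
    intercept_sd: float = 0.3
    caution_sd: float = 0.1
    delta_norm_sd: float = 0.1
    sigma_sd: float = 0.0


def null_cohort_distribution(mean: AgentParams | None = None) -> CohortDistribution:
    """A cohort in which the four conditions are statistically exchangeable:
    every intervention-sensitive parameter is zeroed."""
    base = mean if mean is not None else AgentParams()
    null_mean = replace(
        base,
        w_src=0.0,
        diligence_badge=0.0,
        delta_norm=0.0,
        caution_badge=0.0,
        caution_norm=0.0,
    )
    return CohortDistribution(
        mean=null_mean, w_src_sd=0.0, caution_sd=0.0, delta_norm_sd=0.0
    )


def _draw_agent(dist: CohortDistribution, rng: np.random.Generator) -> AgentParams:
    m = dist.mean
    intercepts = tuple(
        ai + dist.intercept_sd * rng.standard_normal() for ai in m.action_intercepts
    )
    return replace(
        m,
        d=max(0.0, rng.normal(m.d, dist.d_sd)),
        w_fc=rng.normal(m.w_fc, dist.w_fc_sd),
        w_src=max(0.0, rng.normal(m.w_src, dist.w_src_sd)) if dist.w_src_sd else m.w_src,
        g=max(0.1, rng.normal(m.g, dist.g_sd)),
        sigma=max(0.05, rng.normal(m.sigma, dist.sigma_sd)) if dist.sigma_sd else m.sigma,
        delta_norm=(
            max(0.0, rng.normal(m.delta_norm, dist.delta_norm_sd))
            if dist.delta_norm_sd
            else m.delta_norm
        ),
        caution_badge=(
            max(0.0, rng.normal(m.caution_badge, dist.caution_sd))
            if dist.caution_sd
            else m.caution_badge
        ),
        caution_norm=(
            max(0.0, rng.normal(m.caution_norm, dist.caution_sd))
            if dist.caution_sd
            else m.caution_norm
        ),
        action_intercepts=intercepts,
    )


def make_cohort(
    n_per_cell: int,
    dist: CohortDistribution | None = None,
    conditions: Sequence[Condition] = CONDITIONS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[tuple[AgentParams, Condition]]:
    """Draw a balanced cohort: ``n_per_cell`` heterogeneous agents per cell.

    Assignment is blocked (exactly n_per_cell per condition), mirroring an
    equal-cells version of the between-subjects design. Deterministic under
    a fixed seed.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if dist is None:
        dist = CohortDistribution()
    if rng is None:
        rng = np.random.default_rng(seed)
    cohort = []
    for condition in conditions:
        for _ in range(n_per_cell):
            cohort.append((_draw_agent(dist, rng), condition))
    return cohort


def cohort_to_frame(cohort: Sequence[tuple[AgentParams, Condition]]):
    """Realized per-agent parameters as a tidy DataFrame (for export and
    parameter-recovery checks)."""
    import pandas as pd

    rows = []
    for i, (agent, condition) in enumerate(cohort):
        row = {"agent_index": i, "badge": condition.badge, "norm": condition.norm}
        d = asdict(agent)
        for j, name in enumerate(("flag", "skip", "like", "share")):
            row[f"intercept_{name}"] = d["action_intercepts"][j]
            row[f"slope_{name}"] = d["action_slopes"][j]
        del d["action_intercepts"], d["action_slopes"]
        row.update(d)
        rows.append(row)
    return pd.DataFrame(rows)
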