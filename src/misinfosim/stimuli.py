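"""Stimulus environment: simulated social-media posts.

The simulated feed consists of 80 posts (40 true, 40 false claims by default).
Each post carries a source account (handle, follower count, 0-100 credibility
score), displayed engagement counts (likes / shares / flags drawn from normal
distributions left-truncated at zero), and a comment thread of one to three
comments that always contains a valid fact-check: a refutation for false
claims, an affirmation for true ones.

Sampling conventions
--------------------
* "Truncated" means the normal distribution *conditioned* on the interval
  (inverse-CDF sampling), not clipping: a flag count of 0 is a legitimate
  draw, not a censored negative.
* Comment likes are the one exception: they are *censored* at zero (negative
  draws replaced by 0), matching how the displayed threads were built.
* All displayed quantities are integerized by round-half-to-even.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Claim",
    "Source",
    "Comment",
    "CommentKind",
    "Direction",
    "Post",
    "DisplayCountParams",
    "SourceCredibilityParams",
    "CommentLikesParams",
    "FollowerCountParams",
    "StimulusParams",
    "CommentPattern",
    "sample_truncated_normal",
    "sample_display_counts",
    "assign_source_credibility",
    "build_comment_thread",
    "generate_stimulus_set",
    "stimulus_set_to_json",
    "stimulus_set_from_json",
]


def _round_half_even(x: float) -> int:
    """Banker's rounding to int (platform-stable integerization)."""
    return int(np.rint(x))


def sample_truncated_normal(
    mean: float,
    sd: float,
    lower: float,
    upper: float = math.inf,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw from a normal distribution conditioned on ``[lower, upper]``.

    Uses the inverse-CDF method (uniform draw mapped through the truncated
    normal quantile function), so the result is the renormalized conditional
    distribution — not rejection or clipping. ``sd == 0`` is the degenerate
    point mass at ``mean`` and requires ``mean`` to lie inside the interval.

    Parameters
    ----------
    mean, sd : float
        Location and scale of the parent normal; ``sd >= 0``.
    lower, upper : float
        Truncation interval; ``lower < upper``. ``upper`` may be ``inf``.
    rng : numpy.random.Generator
        Source of randomness.
    size : int, optional
        If given, return an ndarray of that many draws; otherwise a scalar.
    """
    if not lower < upper:
        raise ValueError(f"require lower < upper, got [{lower}, {upper}]")
    if sd < 0:
        raise ValueError(f"sd must be nonnegative, got {sd}")
    if sd == 0:
        if not (lower <= mean <= upper):
            raise ValueError(
                f"degenerate sd=0 requires mean within [{lower}, {upper}]"
            )
        return float(mean) if size is None else np.full(size, float(mean))
    if rng is None:
        raise ValueError("rng is required for stochastic draws")
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    u = rng.random(size=size)
    x = stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    return float(x) if size is None else x


class CommentKind(str, Enum):
    STRONG_FACTCHECK = "strong_factcheck"
    WEAK_FACTCHECK = "weak_factcheck"
    NEUTRAL = "neutral"


class Direction(str, Enum):
    REFUTE = "refute"
    AFFIRM = "affirm"
    NONE = "none"


class CommentPattern(str, Enum):
    """Thread composition: every thread leads with a strong fact-check."""

    ONE = "one"                  # [strong]
    TWO_WEAK = "two_weak"        # [strong, weak]
    TWO_NEUTRAL = "two_neutral"  # [strong, neutral]
    THREE = "three"              # [strong, weak, neutral]


@dataclass(frozen=True)
class Claim:
    claim_id: str
    text: str
    veracity: bool  # True = objectively true claim


@dataclass(frozen=True)
class Source:
    handle: str
    follower_count: int
    credibility_score: int  # integer in [0, 100]; shown only in badge cells

    def __post_init__(self):
        if self.follower_count < 0:
            raise ValueError("follower_count must be >= 0")
        if not 0 <= self.credibility_score <= 100:
            raise ValueError("credibility_score must be in [0, 100]")


@dataclass(frozen=True)
class Comment:
    author_handle: str
    kind: CommentKind
    direction: Direction
    likes: int
    position: int  # 1-based order in the thread

    def __post_init__(self):
        if (self.kind is CommentKind.NEUTRAL) != (self.direction is Direction.NONE):
            raise ValueError("neutral comments and only neutral comments have direction 'none'")
        if self.kind is CommentKind.STRONG_FACTCHECK and self.likes < 1:
            raise ValueError("strong fact-checks must have at least 1 like")
        if self.likes < 0 or self.position < 1:
            raise ValueError("likes >= 0 and position >= 1 required")


@dataclass(frozen=True)
class Post:
    claim: Claim
    source: Source
    displayed_likes: int
    displayed_shares: int
    displayed_flags: int
    comments: tuple[Comment, ...]

    def __post_init__(self):
        if not 1 <= len(self.comments) <= 3:
            raise ValueError("a post carries 1-3 comments")
        positions = [c.position for c in self.comments]
        if positions != list(range(1, len(self.comments) + 1)):
            raise ValueError("comment positions must be consecutive from 1")
        for c in self.comments:
            if c.direction is Direction.NONE:
                continue
            expected = Direction.AFFIRM if self.claim.veracity else Direction.REFUTE
            if c.direction is not expected:
                raise ValueError("fact-checks must be valid: refute false, affirm true claims")
        if min(self.displayed_likes, self.displayed_shares, self.displayed_flags) < 0:
            raise ValueError("displayed counts must be nonnegative")

    @property
    def factcheck_direction(self) -> Direction:
        return Direction.AFFIRM if self.claim.veracity else Direction.REFUTE


@dataclass(frozen=True)
class DisplayCountParams:
    """Normal(mean, sd) left-truncated at 0, per count type and veracity.

    Likes and shares use identical parameters for true and false posts;
    false posts have heavier flag distributions for realism.
    """

    likes_mean: float = 5.0
    likes_sd: float = 10.0
    shares_mean: float = 1.0
    shares_sd: float = 3.0
    flags_true_mean: float = 0.0
    flags_true_sd: float = 0.25
    flags_false_mean: float = 0.5
    flags_false_sd: float = 1.0

    def params_for(self, veracity: bool) -> tuple[tuple[float, float], ...]:
        flags = (
            (self.flags_true_mean, self.flags_true_sd)
            if veracity
            else (self.flags_false_mean, self.flags_false_sd)
        )
        return (
            (self.likes_mean, self.likes_sd),
            (self.shares_mean, self.shares_sd),
            flags,
        )


@dataclass(frozen=True)
class SourceCredibilityParams:
    mean_false: float = 40.0
    sd_false: float = 30.0
    mean_true: float = 60.0
    sd_true: float = 30.0
    lower: float = 0.0
    upper: float = 100.0

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")


@dataclass(frozen=True)
class CommentLikesParams:
    mean: float = 1.0
    sd: float = 1.5
    floor: int = 0


@dataclass(frozen=True)
class FollowerCountParams:
    mean: float = 300.0
    sd: float = 500.0
    lower: float = 0.0


@dataclass(frozen=True)
class StimulusParams:
    """All stimulus-generation parameters in one bundle."""

    n_true: int = 40
    n_false: int = 40
    display: DisplayCountParams = field(default_factory=DisplayCountParams)
    credibility: SourceCredibilityParams = field(default_factory=SourceCredibilityParams)
    comment_likes: CommentLikesParams = field(default_factory=CommentLikesParams)
    followers: FollowerCountParams = field(default_factory=FollowerCountParams)


def sample_display_counts(
    veracity: bool,
    params: DisplayCountParams,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Displayed (likes, shares, flags) for one post.

    Each count is a left-truncated-at-zero normal draw integerized by
    round-half-to-even, so truncation pushes realized means above the
    nominal parameters (e.g. likes mean 5 realizes near 10).
    """
    out = []
    for mean, sd in params.params_for(veracity):
        draw = sample_truncated_normal(mean, sd, 0.0, math.inf, rng)
        out.append(_round_half_even(draw))
    return tuple(out)


def assign_source_credibility(
    veracity: bool,
    params: SourceCredibilityParams,
    rng: np.random.Generator,
) -> int:
    """Integer credibility score in [0, 100] for a post's source."""
    mean, sd = (
        (params.mean_true, params.sd_true)
        if veracity
        else (params.mean_false, params.sd_false)
    )
    draw = sample_truncated_normal(mean, sd, params.lower, params.upper, rng)
    score = _round_half_even(draw)
    return int(min(max(score, int(params.lower)), int(params.upper)))


_PATTERN_KINDS = {
    CommentPattern.ONE: (CommentKind.STRONG_FACTCHECK,),
    CommentPattern.TWO_WEAK: (CommentKind.STRONG_FACTCHECK, CommentKind.WEAK_FACTCHECK),
    CommentPattern.TWO_NEUTRAL: (CommentKind.STRONG_FACTCHECK, CommentKind.NEUTRAL),
    CommentPattern.THREE: (
        CommentKind.STRONG_FACTCHECK,
        CommentKind.WEAK_FACTCHECK,
        CommentKind.NEUTRAL,
    ),
}


def build_comment_thread(
    veracity: bool,
    pattern: CommentPattern,
    likes_params: CommentLikesParams,
    rng: np.random.Generator,
    author_handles: Sequence[str] | None = None,
) -> tuple[Comment, ...]:
    """Build a 1-3 comment thread led by a strong fact-check.

    Fact-check direction follows claim veracity (affirm true, refute false).
    Likes are normal draws censored at the floor, rounded, then sorted
    descending so earlier comments have at least as many likes as later
    ones; the strong fact-check is forced to >= 1 like.
    """
    pattern = CommentPattern(pattern)
    kinds = _PATTERN_KINDS[pattern]
    direction = Direction.AFFIRM if veracity else Direction.REFUTE
    n = len(kinds)
    if author_handles is None:
        author_handles = [f"commenter{i + 1}" for i in range(n)]
    raw = [
        max(likes_params.floor, _round_half_even(rng.normal(likes_params.mean, likes_params.sd)))
        for _ in range(n)
    ]
    raw.sort(reverse=True)  # earlier (higher) comments tend to have more likes
    comments = []
    for pos, (kind, likes, handle) in enumerate(zip(kinds, raw, author_handles), start=1):
        if kind is CommentKind.STRONG_FACTCHECK:
            likes = max(likes, 1)
        comments.append(
            Comment(
                author_handle=handle,
                kind=kind,
                direction=Direction.NONE if kind is CommentKind.NEUTRAL else direction,
                likes=likes,
                position=pos,
            )
        )
    return tuple(comments)


def _pattern_allocation(n: int, rng: np.random.Generator) -> list[CommentPattern]:
    """Allocate comment patterns for one veracity class of n posts.

    Deterministic round-robin over {1, 2, 3}-comment threads (two-comment
    variants alternating weak/neutral) approximates the one-third split as
    closely as n allows; the sequence is then shuffled with the shared rng
    so pattern order is not confounded with claim identity.
    """
    cycle = [CommentPattern.ONE, CommentPattern.TWO_WEAK, CommentPattern.THREE,
             CommentPattern.ONE, CommentPattern.TWO_NEUTRAL, CommentPattern.THREE]
    patterns = [cycle[i % len(cycle)] for i in range(n)]
    rng.shuffle(patterns)
    return patterns


def generate_stimulus_set(
    params: StimulusParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[Post]:
    """Generate the full stimulus set (default 40 true + 40 false posts).

    Source-post pairings are fixed within a set: every simulated participant
    in an experiment sees the same posts with the same sources, counts and
    comment threads. Deterministic under a fixed seed.
    """
    if params is None:
        params = StimulusParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    if params.n_true < 0 or params.n_false < 0:
        raise ValueError("post counts must be nonnegative")

    posts: list[Post] = []
    handle_counter = 0
    comment_counter = 0
    cred = params.credibility
    for veracity, n in ((True, params.n_true), (False, params.n_false)):
        patterns = _pattern_allocation(n, rng)
        if n == 0:
            continue
        # batch the truncated-normal draws for the whole veracity class
        follower_draws = sample_truncated_normal(
            params.followers.mean, params.followers.sd, params.followers.lower,
            math.inf, rng, size=n,
        )
        cm, cs = (cred.mean_true, cred.sd_true) if veracity else (cred.mean_false, cred.sd_false)
        cred_draws = sample_truncated_normal(cm, cs, cred.lower, cred.upper, rng, size=n)
        count_draws = np.column_stack(
            [
                sample_truncated_normal(mean, sd, 0.0, math.inf, rng, size=n)
                if sd > 0
                else np.full(n, float(mean))
                for mean, sd in params.display.params_for(veracity)
            ]
        )
        for i in range(n):
            handle_counter += 1
            label = "true" if veracity else "false"
            claim = Claim(
                claim_id=f"{label}_{i + 1:03d}",
                text=f"[synthetic claim {label} #{i + 1}]",
                veracity=veracity,
            )
            source = Source(
                handle=f"user{handle_counter:04d}",
                follower_count=max(_round_half_even(follower_draws[i]), 0),
                credibility_score=int(
                    min(max(_round_half_even(cred_draws[i]), int(cred.lower)), int(cred.upper))
                ),
            )
            likes, shares, flags = (
                _round_half_even(count_draws[i, 0]),
                _round_half_even(count_draws[i, 1]),
                _round_half_even(count_draws[i, 2]),
            )
            n_comments = len(_PATTERN_KINDS[patterns[i]])
            authors = [f"commenter{comment_counter + j + 1:04d}" for j in range(n_comments)]
            comment_counter += n_comments
            thread = build_comment_thread(
                veracity, patterns[i], params.comment_likes, rng, author_handles=authors
            )
            posts.append(
                Post(
                    claim=claim,
                    source=source,
                    displayed_likes=likes,
                    displayed_shares=shares,
                    displayed_flags=flags,
                    comments=thread,
                )
            )
    return posts


def _post_to_dict(post: Post) -> dict:
    return {
        "claim_id": post.claim.claim_id,
        "text": post.claim.text,
        "veracity": post.claim.veracity,
        "source": {
            "handle": post.source.handle,
            "followers": post.source.follower_count,
            "credibility": post.source.credibility_score,
        },
        "displayed": {
            "likes": post.displayed_likes,
            "shares": post.displayed_shares,
            "flags": post.displayed_flags,
        },
        "comments": [
            {
                "author": c.author_handle,
                "kind": c.kind.value,
                "direction": c.direction.value,
                "likes": c.likes,
                "position": c.position,
            }
            for c in post.comments
        ],
    }


def stimulus_set_to_json(
    posts: Sequence[Post],
    seed: int | None = None,
    params: StimulusParams | None = None,
) -> str:
    """Serialize a stimulus set to JSON with stable key order."""
    payload = {
        "seed": seed,
        "params": asdict(params) if params is not None else None,
        "posts": [_post_to_dict(p) for p in posts],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def stimulus_set_from_json(text: str) -> list[Post]:
    """Inverse of :func:`stimulus_set_to_json` (posts only)."""
    payload = json.loads(text)
    posts = []
    for d in payload["posts"]:
        posts.append(
            Post(
                claim=Claim(d["claim_id"], d["text"], d["veracity"]),
                source=Source(
                    d["source"]["handle"],
                    d["source"]["followers"],
                    d["source"]["credibility"],
                ),
                displayed_likes=d["displayed"]["likes"],
                displayed_shares=d["displayed"]["shares"],
                displayed_flags=d["displayed"]["flags"],
                comments=tuple(
                    Comment(
                        c["author"],
                        CommentKind(c["kind"]),
                        Direction(c["direction"]),
                        c["likes"],
                        c["position"],
                    )
                    for c in d["comments"]
                ),
            )
        )
    return posts
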