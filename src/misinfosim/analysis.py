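"""Discernment and engagement statistics for the 2x2 experiment.

Implements the full analysis pipeline applied to the trial and belief
tables: composite engagement scores (flag = -1, skip = 0, like = +1,
share = +2, summed separately over true and false posts), per-action
counts, per-participant ROC curves built from cumulative belief-rating
cutoffs with trapezoidal AUC, 2x2 between-subjects ANOVAs with partial
eta-squared and noncentral-F confidence intervals, pooled-variance t-tests
with Cohen's d and noncentral-t confidence intervals, and a-priori power
for a two-group comparison specified by Cohen's f.

The ROC construction follows the cumulative-cutoff convention for an
ordinal 0-10 belief scale: for each cutoff c in {10, ..., 1} the hit rate
is the proportion of true claims rated >= c and the false-alarm rate the
analogous proportion for false claims — ten operating points per
participant, anchored by (0,0) and (1,1) for integration. The trapezoidal
AUC over these points equals the pairwise concordance probability
(ties counted half), i.e. the Mann-Whitney statistic scaled to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import EngagementAction

__all__ = [
    "ENGAGEMENT_CODES",
    "ROCCurve",
    "EffectResult",
    "AnovaTable",
    "TTestResult",
    "PowerSpec",
    "composite_engagement",
    "engagement_type_counts",
    "roc_curve",
    "auc_trapezoid",
    "anova_2x2",
    "t_test_pooled",
    "power_n_per_group",
    "participant_summaries",
    "full_report",
]

#: engagement coding used for the composite score
ENGAGEMENT_CODES: Mapping[str, int] = {
    EngagementAction.FLAG.value: -1,
    EngagementAction.SKIP.value: 0,
    EngagementAction.LIKE.value: 1,
    EngagementAction.SHARE.value: 2,
}


def _class_records(records: pd.DataFrame, veracity_class: bool) -> pd.DataFrame:
    sub = records[records["veracity"] == bool(veracity_class)]
    if len(sub) == 0:
        raise ValueError("no records for the requested veracity class")
    if sub["claim_id"].duplicated().any():
        raise ValueError("duplicate claim_ids: records must cover each post once")
    return sub


def composite_engagement(records: pd.DataFrame, veracity_class: bool) -> int:
    """Composite engagement score for one participant and veracity class.

    Sum of action codes over the class's posts; bounded by [-n, 2n] for n
    posts (all-flag to all-share).
    """
    sub = _class_records(records, veracity_class)
    return int(sum(ENGAGEMENT_CODES[a] for a in sub["action"]))


def engagement_type_counts(
    records: pd.DataFrame, veracity_class: bool
) -> dict[str, int]:
    """Counts of (flag, skip, like, share) over the class's posts."""
    sub = _class_records(records, veracity_class)
    counts = {a.value: 0 for a in EngagementAction}
    for a in sub["action"]:
        counts[a] += 1
    return counts


@dataclass(frozen=True)
class ROCCurve:
    """Cumulative-cutoff ROC for one participant's belief ratings."""

    cutoffs: tuple[int, ...]            # 10 down to 1
    hit_rates: tuple[float, ...]
    false_alarm_rates: tuple[float, ...]
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        """(false-alarm, hit) pairs with the (0,0) and (1,1) anchors."""
        pts = [(0.0, 0.0)]
        pts += [
            (fa, hr)
            for fa, hr in sorted(zip(self.false_alarm_rates, self.hit_rates))
        ]
        pts.append((1.0, 1.0))
        return pts


def auc_trapezoid(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a piecewise-linear ROC.

    ``points`` are (false-alarm, hit) pairs that must include the (0,0)
    and (1,1) anchors; they are sorted by x (then y) before integration,
    so vertical segments contribute nothing, as they should.
    """
    pts = sorted((float(x), float(y)) for x, y in points)
    if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
        raise ValueError("ROC points must include the (0,0) and (1,1) anchors")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, x))


def roc_curve(
    true_ratings: Sequence[int],
    false_ratings: Sequence[int],
    scale_max: int = 10,
) -> ROCCurve:
    """Build the cumulative-cutoff ROC from 0-10 belief ratings.

    For each cutoff c in {scale_max, ..., 1}: hit rate = proportion of
    true-claim ratings >= c, false-alarm rate = proportion of false-claim
    ratings >= c. Cutoff 0 would classify everything as true — that is the
    fixed (1,1) anchor. AUC is the trapezoid over the anchored points and
    equals the Mann-Whitney concordance (ties half-weighted).
    """
    t = np.asarray(true_ratings, dtype=float)
    f = np.asarray(false_ratings, dtype=float)
    if t.size == 0 or f.size == 0:
        raise ValueError("both rating vectors must be nonempty")
    for arr in (t, f):
        if np.any((arr < 0) | (arr > scale_max)) or np.any(arr != np.round(arr)):
            raise ValueError(f"ratings must be integers in [0, {scale_max}]")
    cutoffs = tuple(range(scale_max, 0, -1))
    hit = tuple(float(np.mean(t >= c)) for c in cutoffs)
    fa = tuple(float(np.mean(f >= c)) for c in cutoffs)
    pts = [(0.0, 0.0)] + sorted(zip(fa, hit)) + [(1.0, 1.0)]
    return ROCCurve(cutoffs=cutoffs, hit_rates=hit, false_alarm_rates=fa,
                    auc=auc_trapezoid(pts))


# ---------------------------------------------------------------------------
# factorial ANOVA


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta2: float
    eta2_ci: tuple[float, float]


@dataclass(frozen=True)
class AnovaTable:
    effects: dict[str, EffectResult] = field(default_factory=dict)

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]

    def to_dict(self) -> dict:
        return {
            name: {
                "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                "partial_eta2": e.partial_eta2,
                "eta2_ci_lower": e.eta2_ci[0], "eta2_ci_upper": e.eta2_ci[1],
            }
            for name, e in self.effects.items()
        }


def _eta2_from_lambda(lam: float, df1: int, df2: int) -> float:
    return lam / (lam + df1 + df2 + 1)


def _eta2_ci(F: float, df1: int, df2: int, level: float = 0.95) -> tuple[float, float]:
    """CI for partial eta^2 by inverting the noncentral-F distribution.

    Finds noncentrality values at which the observed F sits at the upper /
    lower tail quantiles, then maps lambda to eta^2; the lower bound is
    floored at 0.
    """
    if not math.isfinite(F) or F <= 0:
        return (0.0, 0.0) if F <= 0 else (0.0, 1.0)
    alpha = 1.0 - level

    def cdf(lam: float) -> float:
        v = stats.ncf.cdf(F, df1, df2, lam)
        return 0.0 if math.isnan(v) else float(v)  # cdf -> 0 as lambda -> inf

    hi = 4.0 * (F * df1 + df1 + df2)  # generous bracket for the noncentrality
    while cdf(hi) > alpha / 2 and hi < 1e8:
        hi *= 4.0
    lo_lam = 0.0
    if cdf(0.0) > 1 - alpha / 2:
        lo_lam = optimize.brentq(lambda l: cdf(l) - (1 - alpha / 2), 0.0, hi)
    up_lam = 0.0
    if cdf(0.0) > alpha / 2:
        up_lam = optimize.brentq(lambda l: cdf(l) - alpha / 2, 0.0, hi)
    return (
        max(0.0, _eta2_from_lambda(lo_lam, df1, df2)),
        _eta2_from_lambda(up_lam, df1, df2),
    )


def anova_2x2(
    dv: Sequence[float],
    badge: Sequence[bool],
    norm: Sequence[bool],
    compute_ci: bool = True,
) -> AnovaTable:
    """2x2 between-subjects ANOVA (badge, norm, interaction).

    Type-III sums of squares with sum-to-zero (-1/+1) contrasts — on
    balanced data this coincides with the classical balanced decomposition.
    partial eta^2 = SS_effect / (SS_effect + SS_error); 95% CIs by
    noncentral-F inversion. A dv with zero variance everywhere returns
    F = 0, p = 1 for all effects.
    """
    y = np.asarray(dv, dtype=float)
    a = np.where(np.asarray(badge, dtype=bool), 1.0, -1.0)
    b = np.where(np.asarray(norm, dtype=bool), 1.0, -1.0)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("dv, badge and norm must have equal length")
    cells = {(ai, bi) for ai, bi in zip(a, b)}
    if len(cells) < 4:
        raise ValueError("all four design cells must be present")
    for cell in cells:
        if np.sum((a == cell[0]) & (b == cell[1])) < 2:
            raise ValueError("each cell needs at least 2 observations")

    X = np.column_stack([np.ones_like(y), a, b, a * b])

    def ss_res(cols: list[int]) -> float:
        beta, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        r = y - X[:, cols] @ beta
        return float(r @ r)

    ss_err = ss_res([0, 1, 2, 3])
    df2 = len(y) - 4
    effects = {"badge": 1, "norm": 2, "interaction": 3}
    scale = float(y @ y) + 1.0
    table = {}
    for name, col in effects.items():
        reduced = [c for c in range(4) if c != col]
        ss_eff = max(0.0, ss_res(reduced) - ss_err)
        if ss_err <= 1e-12 * scale:
            if ss_eff <= 1e-12 * scale:
                F, p = 0.0, 1.0
            else:
                F, p = math.inf, 0.0
        else:
            F = (ss_eff / 1.0) / (ss_err / df2)
            p = float(stats.f.sf(F, 1, df2))
        eta2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        ci = _eta2_ci(F, 1, df2) if compute_ci else (math.nan, math.nan)
        table[name] = EffectResult(
            F=float(F), df1=1, df2=df2, p=float(p),
            partial_eta2=float(eta2), eta2_ci=ci,
        )
    return AnovaTable(effects=table)


# ---------------------------------------------------------------------------
# t-tests, effect sizes, power


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    cohens_d: float
    d_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "cohens_d": self.cohens_d,
            "d_ci_lower": self.d_ci[0], "d_ci_upper": self.d_ci[1],
        }


def _d_ci(t_obs: float, df: int, scale: float, level: float = 0.95) -> tuple[float, float]:
    """CI for Cohen's d by inverting the noncentral-t distribution;
    ``scale`` converts a noncentrality into a d (sqrt(1/n1 + 1/n2))."""
    alpha = 1.0 - level

    def cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        if math.isnan(v):  # far tails of the noncentrality
            return 0.0 if nc > t_obs else 1.0
        return float(v)

    def solve(q: float) -> float:
        f = lambda nc: cdf(nc) - q
        lo, hi = t_obs - 50.0, t_obs + 50.0
        while f(lo) < 0:
            lo -= 50.0
        while f(hi) > 0:
            hi += 50.0
        return optimize.brentq(f, lo, hi)

    return solve(1 - alpha / 2) * scale, solve(alpha / 2) * scale


def t_test_pooled(
    group1: Sequence[float],
    group2: Sequence[float],
    welch: bool = False,
    compute_ci: bool = True,
) -> TTestResult:
    """Two-sample t-test with Cohen's d.

    Default is the pooled-variance Student's t (df = n1 + n2 - 2), matching
    integer-df reporting conventions; set ``welch=True`` for the unequal-
    variance variant. Cohen's d uses the pooled sd in both cases; its 95%
    CI comes from noncentral-t inversion.
    """
    x = np.asarray(group1, dtype=float)
    z = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(z)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = x.var(ddof=1), z.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("degenerate input: zero pooled variance")
    scale = math.sqrt(1 / n1 + 1 / n2)
    if welch:
        res = stats.ttest_ind(x, z, equal_var=False)
        t_val, p_val, dfree = float(res.statistic), float(res.pvalue), float(res.df)
    else:
        t_val = float((x.mean() - z.mean()) / (math.sqrt(sp2) * scale))
        dfree = n1 + n2 - 2
        p_val = float(2 * stats.t.sf(abs(t_val), dfree))
    d = float((x.mean() - z.mean()) / math.sqrt(sp2))
    t_for_ci = d / scale  # pooled-form statistic regardless of variant
    ci = _d_ci(t_for_ci, n1 + n2 - 2, scale) if compute_ci else (math.nan, math.nan)
    return TTestResult(t=t_val, df=dfree, p=p_val, cohens_d=d, d_ci=ci)


@dataclass(frozen=True)
class PowerSpec:
    effect_f: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if self.effect_f <= 0:
            raise ValueError("effect_f must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def _t_power(d: float, n: int, alpha: float) -> float:
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    tcrit = stats.t.isf(alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_n_per_group(spec: PowerSpec, n_max: int = 10_000_000) -> int:
    """Smallest per-group n for a two-sided two-sample t-test to reach the
    target power at effect size d = 2f (two-group reading of Cohen's f).

    Exact noncentral-t computation, ceiling to an integer group size.
    """
    d = 2.0 * spec.effect_f
    # normal-approximation starting point, then exact scan
    za = stats.norm.isf(spec.alpha / 2)
    zb = stats.norm.isf(1 - spec.power)
    n = max(2, int(2 * ((za + zb) / d) ** 2) - 2)
    while n <= n_max and _t_power(d, n, spec.alpha) < spec.power:
        n += 1
    if n > n_max:
        raise ValueError("target power unreachable within n_max")
    while n > 2 and _t_power(d, n - 1, spec.alpha) >= spec.power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# full pipeline


def participant_summaries(trials: pd.DataFrame, beliefs: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: composites, action counts, final state,
    belief means and trapezoidal AUC.

    Vectorized across participants; per participant it computes exactly
    what :func:`composite_engagement`, :func:`engagement_type_counts` and
    :func:`roc_curve` compute one participant at a time.
    """
    pids = trials["participant_id"].drop_duplicates().tolist()
    base = (
        trials.groupby("participant_id", sort=False)[["badge", "norm"]]
        .first()
        .astype(bool)
        .reindex(pids)
    )
    codes = trials["action"].map(ENGAGEMENT_CODES)
    comp = (
        trials.assign(code=codes)
        .pivot_table(
            index="participant_id", columns="veracity", values="code", aggfunc="sum"
        )
        .reindex(pids)
    )
    counts = (
        trials.groupby(["participant_id", "veracity", "action"], sort=False)
        .size()
        .unstack(["veracity", "action"], fill_value=0)
        .reindex(pids)
    )
    last = (
        trials.sort_values("trial_index")
        .groupby("participant_id", sort=False)
        .tail(1)
        .set_index("participant_id")
        .reindex(pids)
    )

    out = pd.DataFrame({"participant_id": pids})
    out["badge"] = base["badge"].to_numpy()
    out["norm"] = base["norm"].to_numpy()
    for label, cls in (("true", True), ("false", False)):
        out[f"composite_{label}"] = comp[cls].to_numpy(dtype=int)
        for action in ENGAGEMENT_CODES:
            col = (cls, action)
            out[f"n_{action}_{label}"] = (
                counts[col].to_numpy(dtype=int) if col in counts else 0
            )
    out["final_followers"] = last["follower_count_after"].to_numpy(dtype=int)
    out["final_credibility"] = np.where(
        out["badge"], last["credibility_after"].to_numpy(dtype=float), np.nan
    )

    # belief means and AUC from per-participant rating histograms
    scale_max = 10
    hist = (
        beliefs.groupby(["participant_id", "veracity", "rating"], sort=False)
        .size()
        .unstack(["veracity", "rating"], fill_value=0)
    )
    full_cols = pd.MultiIndex.from_product([[True, False], range(scale_max + 1)])
    hist = hist.reindex(columns=full_cols, fill_value=0).reindex(pids)
    ht = hist[True].to_numpy(dtype=float)   # (n_participants, 11) rating counts
    hf = hist[False].to_numpy(dtype=float)
    nt, nf = ht.sum(axis=1), hf.sum(axis=1)
    ratings = np.arange(scale_max + 1)
    out["belief_true"] = (ht * ratings).sum(axis=1) / nt
    out["belief_false"] = (hf * ratings).sum(axis=1) / nf
    # cumulative-cutoff rates: P(rating >= c) for c = scale_max..1, anchored
    cum_t = np.cumsum(ht[:, ::-1], axis=1)[:, :-1] / nt[:, None]
    cum_f = np.cumsum(hf[:, ::-1], axis=1)[:, :-1] / nf[:, None]
    x = np.concatenate(
        [np.zeros((len(pids), 1)), cum_f, np.ones((len(pids), 1))], axis=1
    )
    y = np.concatenate(
        [np.zeros((len(pids), 1)), cum_t, np.ones((len(pids), 1))], axis=1
    )
    out["auc"] = np.trapezoid(y, x, axis=1)
    return out


ANOVA_DVS = (
    "composite_true",
    "composite_false",
    "final_followers",
    "belief_true",
    "belief_false",
    "auc",
)


def full_report(
    trials: pd.DataFrame,
    beliefs: pd.DataFrame,
    compute_ci: bool = True,
) -> dict:
    """Run the complete analysis pipeline on tidy record tables.

    Returns a JSON-serializable dict: per-cell descriptives, a 2x2 ANOVA
    for each dependent variable (engagement composites, final followers,
    belief means, AUC), and the norm-effect t-test on final credibility
    within the badge cells.
    """
    summ = participant_summaries(trials, beliefs)
    report: dict = {"n_participants": int(len(summ)), "cells": {}, "anova": {}}
    for (badge, norm), sub in summ.groupby(["badge", "norm"]):
        key = ("badge" if badge else "nobadge") + "_" + ("norm" if norm else "nonorm")
        report["cells"][key] = {
            "n": int(len(sub)),
            **{
                dv: {"mean": float(sub[dv].mean()), "sd": float(sub[dv].std(ddof=1))}
                for dv in ANOVA_DVS
                if not sub[dv].isna().all()
            },
        }
    for dv in ANOVA_DVS:
        sub = summ.dropna(subset=[dv])
        table = anova_2x2(sub[dv], sub["badge"], sub["norm"], compute_ci=compute_ci)
        report["anova"][dv] = table.to_dict()
    badge_cells = summ[summ["badge"]]
    if badge_cells["norm"].nunique() == 2:
        g_norm = badge_cells.loc[badge_cells["norm"], "final_credibility"]
        g_nonorm = badge_cells.loc[~badge_cells["norm"].astype(bool), "final_credibility"]
        report["credibility_t_test"] = t_test_pooled(
            g_norm, g_nonorm, compute_ci=compute_ci
        ).to_dict()
    return report


def report_markdown(report: dict) -> str:
    """Render a full_report dict as readable markdown tables."""
    lines = [
        "# Simulated experiment report",
        "",
        f"Participants: {report['n_participants']}",
        "",
        "## Cell descriptives (mean ± sd)",
        "",
    ]
    dvs = [dv for dv in ANOVA_DVS if any(dv in c for c in report["cells"].values())]
    lines.append("| cell | n | " + " | ".join(dvs) + " |")
    lines.append("|---" * (len(dvs) + 2) + "|")
    for cell, desc in report["cells"].items():
        vals = [
            f"{desc[dv]['mean']:.3g} ± {desc[dv]['sd']:.3g}" if dv in desc else "—"
            for dv in dvs
        ]
        lines.append(f"| {cell} | {desc['n']} | " + " | ".join(vals) + " |")
    lines += ["", "## 2×2 ANOVAs", ""]
    lines.append("| dv | effect | F | df | p | partial η² | 95% CI |")
    lines.append("|---|---|---|---|---|---|---|")
    for dv, table in report["anova"].items():
        for eff, r in table.items():
            ci = (
                f"[{r['eta2_ci_lower']:.3f}, {r['eta2_ci_upper']:.3f}]"
                if not math.isnan(r.get("eta2_ci_lower", math.nan))
                else "—"
            )
            lines.append(
                f"| {dv} | {eff} | {r['F']:.2f} | ({r['df1']}, {r['df2']}) "
                f"| {r['p']:.4g} | {r['partial_eta2']:.3f} | {ci} |"
            )
    if "credibility_t_test" in report:
        t = report["credibility_t_test"]
        lines += [
            "",
            "## Norm effect on final credibility (badge cells)",
            "",
            f"t({t['df']:.0f}) = {t['t']:.2f}, p = {t['p']:.4g}, "
            f"d = {t['cohens_d']:.2f}",
        ]
    return "\n".join(lines) + "\n"
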