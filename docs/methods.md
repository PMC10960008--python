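# Methods

This note documents the generative model, its calibration, the numerical
conventions, and what the simulation can and cannot show.

## Stimulus environment

The feed is 80 posts: 40 true and 40 false claims, each paired once with a
unique source. Quantities and their defaults:

| quantity | distribution | notes |
|---|---|---|
| source followers | *N*(300, 500) truncated at 0 | rounded half-to-even |
| source credibility, false posts | *N*(40, 30) truncated [0, 100] | integer scores |
| source credibility, true posts | *N*(60, 30) truncated [0, 100] | integer scores |
| displayed likes | *N*(5, 10) truncated at 0 | same for both classes |
| displayed shares | *N*(1, 3) truncated at 0 | same for both classes |
| displayed flags, true | *N*(0, 0.25) truncated at 0 | |
| displayed flags, false | *N*(0.5, 1) truncated at 0 | false posts flagged more |
| comment likes | *N*(1, 1.5) **censored** at 0 | see below |

"Truncated" means conditioning: draws use the inverse-CDF of the truncated
normal, never clip-and-keep, so a displayed flag count of 0 is a genuine
draw and realized means sit above the nominal parameters (a likes parameter
of 5 realizes near 10.09; false-post credibility near 43.7, true near 56.3).
Comment likes are the one deliberate exception — negative draws are
*replaced* by 0 (censoring), matching how displayed threads behave.

Comment threads: a deterministic round-robin assigns one-, two- and
three-comment patterns as close to thirds as 40 allows (overall 28/26/26),
with the two-comment variants alternating between strong+weak and
strong+neutral; the assignment order is then shuffled under the run seed.
Every thread leads with a strong fact-check whose direction follows the
claim (refute false, affirm true); likes are sorted non-increasing in
thread position and strong fact-checks are forced to ≥ 1 like so the
fact-check never appears unendorsed.

All integerization in displayed quantities uses round-half-to-even, chosen
for platform stability since the rounding rule is otherwise a free choice.

## Reputation dynamics

Non-skip engagements trigger integer follower and credibility changes drawn
from normals and rounded half-to-even. Follower changes reward activity:
like (1, 0.75) and share (2, 1) for both classes; flagging gains followers
only for false posts (0.5 vs 0 mean, sd 0.25). Credibility changes are
antisymmetric in veracity: like ±0.5, share ±1, flag ∓1.5 (sd 0.5), positive
for truth-aligned behaviour. Skips are exactly (0, 0).

Participant credibility is clamped to [0, 100] — the badge scale — and
followers to ≥ 0 (a negative audience is meaningless). Pre-clamp deltas are
retained in the history and the trial records, so trajectories replay
exactly. Without a badge the participant has no credibility score; the
simulator records those fields as missing and never updates the state.
Commenting and comment-liking carry no feedback and are not modeled as
actions.

## The agent model

The agent is the package's synthetic-data contract: the study design
constrains only the emergent statistics, so the behavioural model is a
deliberately simple latent-evidence + softmax architecture.

Perceived evidence for a post, per encounter:

    e = d'·v/2 + w_fc'·f + w_src·b·c̃ + ε,   ε ~ N(0, σ²)

with v = ±1 the claim's veracity; f the net fact-check signal (the
strongest fact-check dominates: strong = ±1, weak alone = ±0.5, neutral
comments contribute 0); b = 1 iff the badge is shown; c̃ = (credibility −
50)/50; and d' = d·(1 + diligence_badge·b), likewise w_fc'. The
`diligence_badge` term models badges acting as an implicit accuracy prompt
(more careful reading), which is the mechanism required for badges to
improve discrimination: the credibility signal alone cannot do it, because
w_src adds within-class variance along with its small mean separation
(credibility is only weakly diagnostic), and past moderate weights it
*lowers* AUC.

Actions are a softmax over utilities (flag, skip, like, share):

    U_flag  = a₁ − s₁·e + caution
    U_skip  = a₂
    U_like  = a₃ + s₃·e − caution·1[e<0]
    U_share = a₄ + s₄·e + w_pop·log(1 + displayed likes) − caution·1[e<0]

with caution = caution_badge·b + caution_norm·n. Belief ratings are
r = clamp(round(5 + g·e_b − delta_norm·n·1[refuted]), 0, 10), where the
belief-phase evidence e_b reuses the engagement-phase noise with
correlation ρ (default 0.7): belief is a memory readout of the encounter,
not an independent second judgement. The norm downshift applies only to
refuted (false) claims, so norms lower false belief and raise AUC without
touching true belief, matching the observed asymmetry.

Cohorts draw per-agent parameters around the configured means (sds for d,
w_fc, w_src, g, the intercepts, the caution terms and delta_norm;
nonnegative parameters floored at zero). Assignment to the four cells is
blocked, giving exactly n_per_cell agents per cell. Agents do not condition
on their running credibility score — only on badge presence; a trial-level
hook could be added but the two mechanisms are not distinguishable from the
cell-level statistics this package targets.

### Calibrated defaults

d = 0.8, w_fc = 0.5, w_src = 0.6, σ = 1, g = 2.2, ρ = 0.7,
delta_norm = 0.25, diligence_badge = 0.2, caution_badge = 0.25,
caution_norm = 0.15, w_pop = 0.15, intercepts (−1.2, 0.6, 0.3, −0.2),
slopes (1.6, 0, 1.0, 1.1). Calibration targeted the qualitative pattern
(signs of all badge and norm effects) and put the discrimination effects in
a realistic band: at 104 participants per cell the defaults yield AUC
partial η² near 0.07 for the badge and 0.02–0.03 for the norm, with the
engagement and belief effects in the same direction but stronger than their
human counterparts — the agents are more homogeneous and more rule-driven
than people. Anyone needing a specific effect size should tune
`diligence_badge`/`w_src` (badge) and `delta_norm`/`caution_norm` (norm)
against a replicate bank, as done in `tests/conftest.py`.

## Experiment orchestration

One stimulus set per run, shared by all participants (fixed source–post
pairings, so the credibility–veracity relationship is a between-replicate
random factor, as it is in a fixed-materials study). Each participant sees
the posts in a private uniform random order, then rates all claims in a
fresh order. All randomness descends from the run seed through a
SeedSequence spawn per participant; outputs (tidy `trials.csv`,
`beliefs.csv`, `run_meta.json` with seed and config hash) are
byte-identical across runs with the same seed. Cells are exactly balanced;
display timing (the 3-second minimum) and comment-visibility checks are not
modeled.

## Analysis conventions

* **ROC.** Ten cutoffs (10 down to 1) plus fixed anchors (0,0) and (1,1);
  cutoff 0 is the trivial all-positive point, i.e. the (1,1) anchor. The
  trapezoidal AUC over these anchored points equals pairwise concordance
  with ties counted half (verified to 1e-12 in the tests), so the anchored
  convention is not a free parameter of the result.
* **ANOVA.** Type-III sums of squares with sum-to-zero contrasts (equal to
  the classical decomposition on balanced data); partial η² =
  SS_effect/(SS_effect + SS_error); 95% CIs by noncentral-F inversion with
  η² = λ/(λ + df₁ + df₂ + 1), lower bound floored at 0. A dv with zero
  variance yields F = 0, p = 1 rather than NaN.
* **t-tests.** Pooled-variance Student's t (df = n₁ + n₂ − 2) by default,
  matching integer-df reporting; Welch available behind a flag. Cohen's d
  uses the pooled sd; its CI inverts the noncentral t.
* **Power.** Cohen's f maps to d = 2f for two groups; exact noncentral-t
  power, smallest integer n per group (f = 0.20, α = 0.05, power 0.80
  gives 100).
* Far-tail noncentral distribution CDFs that underflow to NaN in scipy are
  treated as their limiting value (0 or 1) during CI root-finding.

## Problem sizes in the shipped tests

The replicate bank used by the direction-reproduction and power-contract
tests runs 200 full experiments at 104 participants per cell (the first 100
serve the direction checks). Type-I calibration resamples per-participant
AUCs from a 600-participant null cohort into exchangeable 4×26 cells,
10 000 times. These sizes make the Monte-Carlo error small relative to the
contracted bands while keeping the default suite in the low minutes.

## Limitations

* The agent model is a stand-in: it reproduces cell-level statistical
  structure, not psychological process. Effect-size magnitudes for
  engagement and belief run higher than human data at the default
  parameters; only directions and the discrimination effect sizes were
  calibration targets.
* Claim texts, images and handles are synthetic placeholders; nothing about
  content (topic, emotional valence, plausibility) varies between posts
  beyond veracity and the sampled quantities.
* No within-session learning: agents do not update on the dynamic feedback
  they receive, so the simulation cannot address whether trial-by-trial
  credibility changes (vs mere badge presence) drive the effects.
* Exclusion pipelines, attention checks, unequal cells, and the
  supplementary cumulative-link mixed-model analyses are out of scope.
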