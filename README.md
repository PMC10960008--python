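# misinfosim

Simulated social-media misinformation experiments with synthetic
participants, and the statistical pipeline to analyze them.

`misinfosim` is for researchers studying interventions against online
misinformation — credibility badges and social norms in particular — who
want a fully generative, seeded re-creation of a 2×2 between-subjects
social-media simulation experiment: it builds the stimulus environment,
simulates cohorts of participants engaging with true and false posts under
dynamic reputation feedback, and runs the complete truth-discernment
analysis. Because every stage is parameterized and reproducible, it is
useful for power planning, analysis-pipeline validation, and exploring how
intervention mechanisms translate into observable effect sizes.

## What it simulates

**Environment.** A feed of 80 posts (40 objectively true, 40 false claims).
Each post has a source with follower count *N*(300, 500) truncated at 0 and
an integer credibility score drawn from *N*(40, 30) for false posts and
*N*(60, 30) for true posts, truncated to [0, 100] — so source credibility
is only weakly diagnostic of truth. Displayed like/share/flag counts come
from zero-truncated normals (false posts are flagged more). Every post
carries a 1–3 comment thread led by a valid fact-check (refuting false,
affirming true claims).

**Interventions (2×2 between subjects).** A *credibility badge* condition
displays 0–100 credibility scores (color-coded by decile, dark red →
gold | turquoise → dark blue) for every source and for the participant,
whose own score starts at 50 and updates trial by trial: endorsing true
content or flagging false content raises it, and vice versa (changes are
antisymmetric in veracity). A *social norm* condition tells participants
that most people do not share misinformation and that doing so is wrong.

**Participants.** Synthetic agents form noisy latent evidence for each
claim,

&nbsp;&nbsp;&nbsp;&nbsp;*e* = *d*·*v*/2 + *w*₍fc₎·*f* + *w*₍src₎·*b*·*c̃* + ε,&nbsp;&nbsp;ε ~ *N*(0, σ²),

with *v* = ±1 the claim's veracity, *f* the net fact-check signal, *c̃* the
standardized source credibility (badge conditions only), choose
flag/skip/like/share through a softmax policy over evidence-dependent
utilities, and later rate belief in each claim on a 0–10 scale as a noisy
memory readout of the same evidence. Intervention effects emerge from the
model structure (credibility signal, attention boost, caution terms, norm
downshift for refuted claims); the shipped defaults are calibrated so cohort
statistics reproduce the qualitative human pattern: badges raise true-claim
belief, lower false-claim belief and false-post engagement, and improve
discrimination; norms lower false-claim belief and improve discrimination.

**Analysis.** Per participant: composite engagement scores (flag = −1,
skip = 0, like = +1, share = +2, summed over the 40 posts of each class,
range −40…80), per-action counts, belief means, and a cumulative-cutoff ROC
— for each belief level *c* ∈ {10, …, 1} the hit rate is the proportion of
true claims rated ≥ *c* and the false-alarm rate the same for false claims —
integrated by the trapezoidal rule (with (0,0)/(1,1) anchors) into an AUC
that equals the Mann–Whitney concordance. Across participants: 2×2
between-subjects ANOVAs (Type-III, sum-to-zero contrasts) with partial η²
and noncentral-*F* confidence intervals, pooled-variance *t*-tests with
Cohen's *d* and noncentral-*t* intervals, and exact noncentral-*t* a-priori
power (*d* = 2*f* for two groups).

## Worked example

```bash
python examples/04_full_experiment.py
```

runs a reduced experiment (30 participants per cell, seed 1) and prints:

```
120 participants x 80 posts

cell             engage(false) belief(false)     AUC
nobadge_nonorm            -2.1          2.85   0.905
nobadge_norm              -1.5          2.80   0.898
badge_nonorm              -7.2          2.61   0.926
badge_norm               -10.2          2.57   0.936

2x2 ANOVAs (F, p, partial eta^2):
  composite_false  badge: F= 17.40 p=0.0001 np2=0.130 | norm: F=  0.54 p=0.4625 np2=0.005 | ...
  belief_false     badge: F=  5.40 p=0.0219 np2=0.044 | norm: F=  0.22 p=0.6384 np2=0.002 | ...
  auc              badge: F=  8.21 p=0.0049 np2=0.066 | norm: F=  0.02 p=0.8967 np2=0.000 | ...
```

Badge cells engage less positively with false posts (−7 to −10 vs ~−2),
believe false claims less, and discriminate better (higher AUC); at this
reduced size the badge main effects are already significant while the
smaller norm effects are not. The other examples cover stimulus generation,
the reputation dynamics, a single participant's session, and power/ROC
anchors.

The same pipeline is available from the shell:

```bash
misinfosim simulate --seed 1 --n-per-cell 104 --outdir runs/demo
misinfosim analyze --indir runs/demo
misinfosim report --indir runs/demo
misinfosim power --f 0.20        # -> 100
```

## Layout

- `src/misinfosim/stimuli.py` — posts, sources, comment threads, truncated sampling
- `src/misinfosim/dynamics.py` — follower/credibility feedback rules
- `src/misinfosim/agents.py` — the synthetic-participant generative model
- `src/misinfosim/experiment.py` — the 2×2 experiment orchestration, tidy outputs
- `src/misinfosim/analysis.py` — composites, ROC/AUC, ANOVA, t-tests, power
- `src/misinfosim/config.py`, `cli.py` — config files, badge colors, shell interface
- `docs/methods.md` — model assumptions, calibration, and limitations
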