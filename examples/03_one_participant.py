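"""Simulate a single synthetic participant in the badge condition.

The agent forms noisy evidence for each claim (own discrimination +
fact-checks + credibility badge), engages via a softmax policy, then
rates belief in every claim; we score its engagement and discrimination.
"""

import numpy as np
import pandas as pd

from misinfosim import (
    AgentParams,
    Condition,
    DynamicsParams,
    composite_engagement,
    engagement_type_counts,
    generate_stimulus_set,
    roc_curve,
    run_participant,
)

posts = generate_stimulus_set(seed=1)
agent = AgentParams()  # calibrated defaults
condition = Condition(badge=True, norm=False)
trials, beliefs, state = run_participant(
    agent, condition, posts, DynamicsParams(), np.random.default_rng(5)
)

tdf, bdf = pd.DataFrame(trials), pd.DataFrame(beliefs)
for label, cls in (("true", True), ("false", False)):
    comp = composite_engagement(tdf, cls)
    counts = engagement_type_counts(tdf, cls)
    print(f"{label:5s} posts: composite engagement {comp:+4d}  counts {counts}")
print("-> composite = -flags + likes + 2*shares per class (range -40..80 for 40 posts)")

tr = bdf.loc[bdf.veracity, "rating"]
fr = bdf.loc[~bdf.veracity.astype(bool), "rating"]
auc = roc_curve(tr, fr).auc
print(f"belief means  true {tr.mean():.2f}  false {fr.mean():.2f};  AUC = {auc:.3f} "
      "(0.5 = chance, 1 = perfect discrimination)")
print(f"final state: {state.follower_count} followers, credibility {state.credibility}")
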