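"""Follower/credibility feedback for different engagement policies.

Sharing true posts and flagging false ones raises credibility; the
reverse policy destroys it. Skips change nothing.
"""

import numpy as np

from misinfosim import (
    DynamicsParams,
    EngagementAction as A,
    ParticipantState,
    apply_engagement,
    expected_credibility_drift,
)

params = DynamicsParams()

virtuous = {True: {A.SHARE: 1.0}, False: {A.FLAG: 1.0}}
vicious = {True: {A.FLAG: 1.0}, False: {A.SHARE: 1.0}}
print(f"expected credibility drift per post  virtuous: {expected_credibility_drift(virtuous, params):+.2f}"
      f"   vicious: {expected_credibility_drift(vicious, params):+.2f}")

rng = np.random.default_rng(0)
for label, policy in (("virtuous", virtuous), ("vicious", vicious)):
    state = ParticipantState()  # 0 followers, credibility 50
    for _ in range(40):  # alternate true/false posts
        for veracity, mix in policy.items():
            action = next(iter(mix))
            apply_engagement(state, veracity, action, params, rng)
    print(f"{label:8s} after 80 engagements: {state.follower_count:3d} followers, "
          f"credibility {state.credibility:3d}")
print("-> credibility is clamped to [0, 100]; followers never drop below 0")
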