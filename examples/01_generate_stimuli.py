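"""Generate the simulated social-media feed: 80 posts, 40 true / 40 false.

Each post gets a source (handle, followers, 0-100 credibility), displayed
like/share/flag counts from zero-truncated normals, and a 1-3 comment
thread led by a valid fact-check.
"""

import numpy as np

from misinfosim import generate_stimulus_set
from misinfosim.config import badge_color

posts = generate_stimulus_set(seed=1)

true_cred = [p.source.credibility_score for p in posts if p.claim.veracity]
false_cred = [p.source.credibility_score for p in posts if not p.claim.veracity]
print(f"posts: {len(posts)} ({len(true_cred)} true, {len(false_cred)} false)")
print(f"mean source credibility  true: {np.mean(true_cred):5.1f}   false: {np.mean(false_cred):5.1f}")
print("-> truth and source credibility are only weakly related, as in a real feed\n")

p = posts[0]
print(f"example post: {p.claim.claim_id} by @{p.source.handle}")
print(f"  credibility {p.source.credibility_score} ({badge_color(p.source.credibility_score)} badge), "
      f"{p.source.follower_count} followers")
print(f"  displayed: {p.displayed_likes} likes, {p.displayed_shares} shares, {p.displayed_flags} flags")
for c in p.comments:
    print(f"  comment {c.position}: {c.kind.value} ({c.direction.value}), {c.likes} likes")
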