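"""Estimate the imitative anchor and score deviation from imitation.

Labelled imitative-pull segments are pooled (frame-weighted) into one global
anchor — the "zero" of exploration.  Per-frame absolute deviations in each
axis give the axis difference score (dev_x - dev_y) and the additive
imitative-similarity score -(dev_x + dev_y): 0 means perfect imitation,
more negative means more exploration.
"""

import numpy as np

from microexplore import deviation_series, estimate_anchor, px_to_cm
from microexplore.baseline import ImitativeSegment

rng = np.random.default_rng(1)

# three infants' imitative pulls, jittered around the true pull-back point
true_xy = np.array([458.29, 347.79])
segments = [
    ImitativeSegment(f"p{i:03d}", true_xy + rng.normal(0, 8, size=(n, 2)))
    for i, n in enumerate((40, 25, 90))
]
anchor = estimate_anchor(segments)
print(f"anchor: ({anchor.x_anchor:.2f}, {anchor.y_anchor:.2f}) px "
      f"from {anchor.n_frames} frames / {anchor.n_contributors} infants")
print(f"anchor in cm from frame edges: ({px_to_cm(anchor.x_anchor):.2f}, "
      f"{px_to_cm(anchor.y_anchor):.2f})")

# one exploratory trial: the infant pulls right of and below the anchor
import pandas as pd
coords = pd.DataFrame({
    "time_s": np.arange(5) / 30,
    "x": anchor.x_anchor + np.array([0.0, 50, 120, -30, 200]),
    "y": anchor.y_anchor + np.array([0.0, -20, 40, 10, -60]),
})
dev = deviation_series(coords, anchor)
print(dev.round(2).to_string(index=False))
# similarity = 0 only at the anchor; |diff_score| <= -similarity always.
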