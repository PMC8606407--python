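"""Write, read and clip a pose track in the standard three-header CSV layout.

A trial track is 30 fps image coordinates (origin: top-left of the camera
view) for each tracked handle point, plus a tracking likelihood.  Analyses
use only the first 20 s of each trial so every trial contributes the same
amount of data.
"""

import tempfile
from pathlib import Path

import numpy as np

from microexplore import clip_trial, make_track, read_pose_csv, select_point, write_pose_csv

rng = np.random.default_rng(0)
n = 900  # 30 s at 30 fps
track = make_track(
    {"handle_base": np.column_stack([rng.uniform(0, 600, n),
                                     rng.uniform(0, 450, n),
                                     rng.uniform(0.9, 1.0, n)])},
    fps=30, participant_id="p000", trial_number=1)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "p000_trial1.csv"
    write_pose_csv(track, path)
    back = read_pose_csv(path)
    identical = bool((track.data.to_numpy() == back.data.to_numpy()).all())
    print(f"round-trip identical: {identical}")

clipped = clip_trial(track, duration=20)
coords = select_point(clipped, "handle_base")
print(f"clip: {track.n_frames} frames -> {clipped.n_frames} frames "
      f"({clipped.duration_s:.0f} s)")
print(f"first frames of the analysis point:\n{coords.head(3)}")
# 600 frames = 20 s x 30 fps; the (time_s, x, y) series feeds every metric.
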