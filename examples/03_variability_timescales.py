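"""Local vs global spatial variability and why they dissociate.

Per-second variability responds to the previous second's own mean; overall
variability responds to the trial-global mean.  An infant who dwells ~2 s on
each candidate location but hops between distant locations shows LOW
per-second and HIGH overall variability — persistence within attempts,
breadth across them.
"""

import numpy as np

from microexplore import (SimParams, generate_trial, overall_variability,
                          per_second_variability, select_point)

params = SimParams(seed=4)  # bout dispersion 150 px, jitter 10 px, dwell 2 s
track, _ = generate_trial(params, participant_index=0, trial_number=2)
coords = select_point(track, "handle_base").iloc[:600]  # 20 s clip

persec = per_second_variability(coords)
overall = overall_variability(coords)
print(f"per-second variability, first 5 windows (px): "
      f"{np.round(persec.head(5).to_numpy(), 1)}")
print(f"mean per-second variability: {np.nanmean(persec):6.1f} px")
print(f"overall variability:         {overall:6.1f} px")
print(f"dissociation (local < global): {np.nanmean(persec) < overall}")
# sqrt-transformed versions of both are what the mixed models analyse.
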