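"""Why exclude the first trials after an entropy change?

A Dirichlet-count observer tracks next-stimulus probabilities per current
stimulus. Simulating many ordered (75% forward) segments shows how many
trials it takes until the posterior predictive of the forward successor
first exceeds 0.5 - the rationale for the per-segment burn-in exclusion.
"""

import numpy as np
import pandas as pd

from predtend.sequence import ORDERED, generate_sequence, ideal_observer

rng = np.random.default_rng(8)
schedule = pd.DataFrame({"block": [0], "segment": [0], "entropy": [ORDERED]})

crossings = []
for _ in range(500):
    seq = generate_sequence(schedule, 200, seed=int(rng.integers(2**31)))
    _, first = ideal_observer(seq.stimulus, prior_strength=1.0)
    if first is not None:
        crossings.append(first)

q = np.percentile(crossings, [25, 50, 75])
print(f"replicate segments: 500 (converged: {len(crossings)})")
print(f"first trial with P(forward) > 0.5: median {q[1]:.0f}, IQR {q[0]:.0f}-{q[2]:.0f}")

# Deterministic check: in a pure forward cycle the predictive is
# (n+1)/(n+4) after n observations of the current stimulus, so it first
# exceeds 0.5 at the third observation.
seq = np.array([1, 2, 3, 4] * 5)
traj, first = ideal_observer(seq)
print(f"pure forward cycle: first crossing at trial {first} "
      f"(3rd observation of stimulus 1)")

# The median of a few tens of trials is consistent with dropping the first
# 20 trials of every segment before training the classifier.
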