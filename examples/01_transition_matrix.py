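"""Lag-1 transition matrix of a simulated ASD behavior stream.

Simulates one long coded-behavior session from the empirical ASD-group
kernel, counts lag-1 transitions and prints the row-normalized conditional
probabilities P(next | current).  The dominant entry of the
nonverbal-initiation row (-> avoidance, planted at 0.62) shows how often a
social bid is followed by withdrawal in this group.
"""

import numpy as np

import playseq as ps
from playseq.behavior import default_alphabet
from playseq.cohort import asd_group_kernel, simulate_event_log

alphabet = default_alphabet(6)
rng = np.random.default_rng(0)

log = simulate_event_log(asd_group_kernel(6), alphabet, 5000, rng)
tm = ps.transition_probabilities(ps.transition_counts(log))

print("estimated P(next | current), 5000 events:")
print(tm.probs_frame().round(3))
i, j = alphabet.index("nonverbal_initiation"), alphabet.index("avoidance")
print(f"\nP(avoidance | nonverbal initiation) = {tm.probs[i, j]:.3f} (planted 0.62)")
print("Each row conditions on the current behavior; rows sum to 1.")
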