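"""Run the 3-level binary HGF filter on a hand-made input sequence.

Feeds the filter twenty trials in which "go is correct" (u = 1)
dominates, and prints the belief trajectory: the contingency belief
mu2 climbs, its uncertainty sigma2 shrinks as evidence accumulates,
and the precision-weighted prediction errors eps2 spike whenever the
input contradicts the current prediction.
"""

import numpy as np

from escalearn import HGFParams, filter_sequence

u = np.array([1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1])
params = HGFParams(omega2=-3.0, omega3=-6.0, beta=1.0)
traj = filter_sequence(u, params)

frame = traj.to_frame()[["trial", "u", "muhat1", "mu2", "sigma2", "mu3", "psi3", "eps2"]]
print(frame.to_string(index=False, float_format=lambda v: f"{v:+.4f}"))
print(
    "\nmuhat1 is the predicted probability that 'go' is correct before each\n"
    "trial; mu2 is the same belief on the log-odds scale after the update.\n"
    "Note eps2 turning negative exactly on the u=0 trials (surprise), and\n"
    "sigma2 = psi2 shrinking: the belief update slows as certainty grows."
)
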