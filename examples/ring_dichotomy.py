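"""The aggregation dichotomy on the one-dimensional ring reduction.

A small cosine bump on the membrane density either decays back to uniform
(weak coupling) or aggregates into a spike in finite time (strong
coupling) - the two-state, Keller-Segel-like behaviour behind the
polarized/unpolarized dichotomy of the full model.
"""

import math

import numpy as np

from shmoo import ModelParams
from shmoo.ring1d import RingState, aggregation_threshold, run_reduced

params = ModelParams()
L = 2 * math.pi * params.R
theta = (np.arange(64) + 0.5) * 2 * math.pi / 64
mu0 = (130.0 / L) * (1 + 0.2 * np.cos(theta))  # resting membrane pool + bump

for chi in (0.05, 50.0):
    state = RingState(t=0.0, mu=mu0.copy(), length=L)
    traj, times, aggregated = run_reduced(
        state, params.kappa_mean, 1.0, params.with_(chi=chi), t_max=2000.0, dt=2000.0
    )
    peak = traj[-1].max() / traj[-1].mean()
    print(f"chi = {chi:5.2f}: aggregated={aggregated!s:5}  "
          f"final peak/mean = {peak:6.1f}  (t = {times[-1]:.0f} s)")

chi_c = aggregation_threshold(params, mass=130.0, n=48, t_max=800.0, iters=8)
print(f"\nbisected critical chi at ring mass 130: {chi_c:.2f} um^2/s")
# Doubling the ring mass halves the critical chi: the dichotomy is
# controlled by the product chi * mass.
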