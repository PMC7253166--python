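"""Capacity and rate of a single leaky node.

The simplest channel: one node with decay rate a, impulse inputs every
T time units, readout noise variance sigma2.  The closed form

    C_T = 1/2 log2[(2 a sigma2 + 1) / (2 a sigma2 + e^{-2aT})]

is reproduced here by the full Gramian + log-det pipeline, and the rate
R_T = C_T / T is shown to decrease with T: a single node is best used
with the shortest window its application allows.
"""

import numpy as np

from netcap import NetworkChannel, capacity_given_input, scalar_capacity

a, sigma2 = 1.0, 1.0
print(f"single node, a={a}, sigma2={sigma2}")
print(f"{'T':>6} {'C_T closed form':>16} {'C_T pipeline':>14} {'R_T':>8}")
for T in (0.1, 0.5, 1.0, 2.0, 5.0):
    closed = scalar_capacity(a, sigma2, T)
    piped = capacity_given_input(NetworkChannel(A=[[-a]], T=T, sigma2=sigma2), [[1.0]])
    print(f"{T:6.1f} {closed:16.6f} {piped:14.6f} {piped / T:8.4f}")

print()
print("C_T grows with T but saturates near", round(0.5 * np.log2(1 + 1 / (2 * a * sigma2)), 4),
      "bits, so the rate C_T/T keeps falling: short windows win for one node.")
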