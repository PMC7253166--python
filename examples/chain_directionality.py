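"""Non-normality rescues the information rate of a noisy chain.

An 8-node chain with decay gamma = -2.5 and coupling beta = 1 has the
same eigenvalues for every directionality alpha (the forward weight is
alpha*beta, the backward one beta/alpha).  Yet at readout noise
sigma2 = 1 its peak information rate grows dramatically with alpha:
directed (non-normal) wiring transiently amplifies select input
patterns above the noise floor, something no symmetric network can do.
"""

import numpy as np

from netcap import (
    ChainSpec, NetworkChannel, OptimizerOptions, build_chain, capacity,
    low_noise_rate, max_rate_over_T, nonnormality_index,
)

T_grid = np.geomspace(0.05, 8.0, 10)
opts = OptimizerOptions(n_restarts=3, seed=0)
limit = low_noise_rate(build_chain(ChainSpec(8, 1.0)))

print("8-node chain, gamma=-2.5, beta=1, sigma2=1, B=C=I")
print(f"noiseless ceiling -tr(A)/ln2 = {limit:.3f} bits/time\n")
print(f"{'alpha':>6} {'non-normality':>14} {'R_max':>8} {'T_opt':>7} {'boundary':>9}")
for alpha in (1.0, 3.0, 7.0, 20.0, 100.0):
    A = build_chain(ChainSpec(8, alpha))
    mr = max_rate_over_T(A, T_grid, sigma2=1.0, opts=opts, refine=False)
    print(f"{alpha:6.0f} {nonnormality_index(A):14.3f} {mr.R_max:8.3f} "
          f"{mr.T_opt:7.2f} {str(mr.boundary):>9}")

print("\nalpha=1 (symmetric, normal): the best rate sits at the smallest window.")
print("Large alpha: an interior optimal window appears and R_max climbs toward")
print("the noiseless ceiling - strong non-normality cancels the readout noise.")

res = capacity(NetworkChannel(A=build_chain(ChainSpec(8, 7.0)), T=3.0, sigma2=1.0), opts)
print(f"\nAt alpha=7, T=3: optimal input covariance uses "
      f"{res.input_dimensionality:.2f} effective dimensions "
      f"(power concentrates on the chain's source nodes).")
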