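"""Simulate the benchmark systems and take noiseless snapshots.

Draws one exact trajectory of the predator-prey model and of the closed
SIR epidemic, then reads the state at a handful of times — the kind of
data the inference algorithms consume.
"""

import numpy as np

from pmjp import fixtures
from pmjp.simulate import gillespie_simulate, observe_at_times

lv, s0 = fixtures.lotka_volterra()
traj = gillespie_simulate(lv, s0, t_end=4.0, seed=1)
obs = observe_at_times(traj, np.linspace(0.0, 4.0, 9))
print(f"Lotka-Volterra from {tuple(int(x) for x in s0)}: {traj.n_jumps} reaction events in 4 time units")
print(obs.to_dataframe(species=lv.species).to_string(index=False))
print("-> (time, predator count X, prey count Y); counts stay nonnegative and small\n")

sir, s0 = fixtures.sir_finite()
traj = gillespie_simulate(sir, s0, t_end=3.0, seed=2)
obs = observe_at_times(traj, np.linspace(0.0, 3.0, 7))
print(f"closed SIR from {tuple(int(x) for x in s0)}: S+I+R is conserved at {int(s0.sum())}")
print(obs.to_dataframe(species=sir.species).to_string(index=False))
print("-> infections move mass S->I, recoveries I->R; rows always sum to 15")
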