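"""Simulate one silencing experiment: 20 nM complex, 6 h exposure, 24 h readout.

Prints the internalized-siRNA count at the end of exposure, the active-RISC
level and the normalized reporter expression at readout, and the mass-balance
residual showing that every siRNA molecule is accounted for.
"""

import numpy as np

from sirnatraffic import (
    Protocol, TraffickingParams, mass_balance_residual,
    silencing_readout, simulate, uptake_timecourse,
)

params = TraffickingParams()
protocol = Protocol(dose=20e-9)

traj = simulate(protocol, params)
control = simulate(protocol.with_(dose=0.0), params)

i6 = np.searchsorted(traj.times, protocol.t_transfect)
print(f"internalized siRNA at 6 h:   {uptake_timecourse(traj)[i6]:.3g} molecules/cell")
print(f"active RISC at 24 h:         {traj['risc_a'][-1]:.3g} of {params.RISC_tot:.0g}")
print(f"normalized expression:       {silencing_readout(traj, control):.3f}")
print(f"mass-balance residual:       {mass_balance_residual(traj):.2e}")
print()
print("A 20 nM dose saturates uptake and RISC loading, knocking the")
print("destabilized reporter down to a few percent of control; the")
print("residual confirms the degradation/wash-out bookkeeping closes.")
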