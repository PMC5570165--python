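"""Titrate a soluble receptor competitor against a fixed 20 nM complex dose.

A monovalent receptor binder blocks complex uptake without touching the
intracellular machinery, so sweeping it from 0 to 4 uM titrates the number
of internalized siRNA at constant extracellular dose. Pairing internalized
counts with silencing gives the per-siRNA potency curve.
"""

import numpy as np

from sirnatraffic import Protocol, TraffickingParams, competition_curve

curve = competition_curve(
    TraffickingParams(), Protocol(dose=20e-9),
    np.concatenate([[0.0], np.geomspace(4e-9, 4e-6, 7)]),
)

print("competitor (M)   internalized/cell   normalized expression")
for c, n, e in zip(curve.competitor_concs, curve.internalized_6h,
                   curve.expression):
    print(f"{c:12.2e} {n:18.3g} {e:18.3f}")

counts, expr = curve.per_sirna_potency()
print()
print("The competitor suppresses uptake >100-fold at saturating")
print("concentration. Silencing stays maximal here because even the")
print("blocked residual (~1e5 molecules/cell) dwarfs the RISC pool (1e4):")
print("at this dose the assay titrates uptake, and the sorted (count,")
print("expression) pairs - the per-siRNA potency curve - only bend upward")
print("once delivery falls below the RISC-saturating level.")
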