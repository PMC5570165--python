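# sirnatraffic

Kinetic modeling and assay analysis for receptor-targeted siRNA delivery
by high-affinity protein carriers.

A protein carrier (a p19-dimer fusion targeted to EGFR) binds one siRNA
duplex non-covalently and ferries it into cells; a separately dosed
pore-forming agent lets endosomal cargo escape to the cytoplasm, where
free siRNA loads RISC and silences a destabilized GFP reporter. How
strongly should the carrier hold its siRNA? Tighter binding improves
complexation and uptake, but siRNA that never leaves its carrier cannot
load RISC. This package provides the quantitative machinery to ask that
question: a compartmental mass-action model of the whole delivery chain,
the fitting routines for the affinity and potency assays that
parameterize it, and model-based inference over the carrier off-rate.

It is a library for systems-biology and delivery-engineering work in
Python: import it, or start from the scripts in `examples/`.

## The model

States are tracked separately for free siRNA `S`, free carrier `C` and
the 1:1 complex `X` in the medium (molar), on the cell surface bound to
receptor, in the endosomal compartment and in the cytoplasm
(molecules/cell). The core processes, all mass action:

- extracellular loading `S + C <-> X` (`kon_s`, `koff_s`);
- receptor binding of carrier-containing species (`kon_r`, `koff_r`) and
  net internalization at `k_int` (receptor recycles, surface total
  `R_tot` constant);
- first-order endosomal escape `k_esc` applied to `S_e`, `C_e`, `X_e`
  alike (the pore passes intact complexes), endo/lysosomal degradation
  `k_deg_endo`;
- cytoplasmic re-equilibration of `S_c + C_c <-> X_c`, per-species
  degradation, RISC loading from **free** siRNA only:
  `d RISC*/dt = k_load * S_c * (RISC_tot - RISC*)`;
- RNAi module: `dM/dt = k_txn - k_deg_m*M - k_slice*RISC**M`,
  `dP/dt = k_tln*M - k_deg_p*P`; the readout is
  `P_treated(t_obs) / P_control(t_obs)`.

Degraded and washed-out siRNA accumulate in explicit sinks, so total
siRNA equivalents balance to solver precision at every time — the
package's primary self-check.

Assay math implemented alongside: 1:1 biosensor kinetics with global
multi-concentration fitting (`kon`, `koff`, `KD = koff/kon`), the
quadratic solution-equilibrium titration (exact free fraction
`1 - B/A0` with `B` the depletion-aware root), four-parameter-logistic
EC50 fitting (`y = bottom + (top-bottom)/(1 + (d/EC50)^h)`),
comparative-Ct fold change (`2^-ddCt`) and MESF bead calibration of
fluorescence to molecules per cell.

## Worked example

```python
import numpy as np
from sirnatraffic import Protocol, TraffickingParams, affinity_sweep

sweep = affinity_sweep(
    TraffickingParams(), kon_fixed=1e5,
    koff_grid=np.geomspace(1e-7, 1e0, 13),
    protocol=Protocol(), doses=np.geomspace(1e-12, 3e-7, 8),
)
print(f"optimum koff {sweep.optimum_koff:.2e} s^-1, "
      f"EC50 {sweep.optimum_ec50*1e12:.1f} pM")
```

prints

```
optimum koff 7.38e-06 s^-1, EC50 8.6 pM
```

i.e. at a fixed on-rate of 1e5 M^-1 s^-1 the model predicts silencing
potency is maximized near KD ~ 74 pM. The full grid (see
`examples/affinity_optimum.py`) shows EC50 rising from 8.6 pM to
1.8 nM at the weak-binding end (complexation and uptake limited) and to
58 pM at the tight-binding end, where the regime label flips to
`sequestration-limited`: most cytoplasmic siRNA is still carrier-bound
at readout. Potency first gains ~200-fold with affinity, then reverses —
an interior affinity optimum.

Each example in `examples/` is a self-contained narrative script:
delivery simulation with mass-balance audit, binding-assay fitting,
escape-rate estimation from linked uptake + silencing data, the affinity
sweep, and the receptor-competitor titration.

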