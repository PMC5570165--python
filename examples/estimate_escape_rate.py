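"""Estimate the endosomal escape rate from linked uptake + silencing data.

The escape step sits between what the two assays see: uptake timecourses
count every intact intracellular siRNA, while silencing only responds to
molecules that reached the cytoplasm and loaded RISC. Fitting both jointly
pins down the first-order escape rate.
"""

import numpy as np

from sirnatraffic import (
    DoseResponse, NoiseSpec, Protocol, TraffickingParams, TruthBundle,
    fit_escape_rate, fit_mesf, gen_cell_assays, uptake_series_from_frame,
)

truth_params = TraffickingParams(k_esc=1e-4)
bundle = TruthBundle(params=truth_params, protocol=Protocol())
datasets, sidecar = gen_cell_assays(
    bundle, noise=NoiseSpec(cv=0.05, replicates=3, seed=2))

cal = fit_mesf(datasets["beads"]["intensity_au"], datasets["beads"]["mesf"])
uptake = uptake_series_from_frame(datasets["uptake"], cal)
mean = datasets["silencing"].groupby("dose_M")["response"].mean()
dr = DoseResponse(doses=mean.index.to_numpy(float),
                  responses=mean.to_numpy())

fit = fit_escape_rate(uptake, dr, truth_params.with_(k_esc=0.0), Protocol())
print(f"true escape rate:      {sidecar['k_esc']:.3g} s^-1")
print(f"fitted escape rate:    {fit.k_esc:.3g} s^-1 "
      f"(+/- {fit.stderr_log10:.2f} log10 units)")
print(f"residuals  uptake: {fit.residual_uptake:.3g} (log-molecules)  "
      f"silencing: {fit.residual_silencing:.3g} (normalized)")
print()
print("At 5% assay noise with triplicates the joint fit recovers the")
print("escape rate to within ~10%; uptake alone could not (the intact")
print("total hardly changes when molecules move endosome -> cytoplasm).")
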