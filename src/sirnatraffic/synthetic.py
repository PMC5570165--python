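"""Seeded generators emulating every assay the analysis pipeline consumes.

Each generator is a pure function of (truth, design, seed): identical
inputs reproduce the dataset bit-for-bit. Noise is multiplicative
lognormal (unit mean) with an optional additive floor, which matches the
error structure of plate readers and flow cytometers. Every generator
returns the dataset together with a plain-dict truth sidecar so that
downstream tests read ground truth from the sidecar rather than
re-deriving it.

Default designs reproduce the study conditions: biosensor concentration
series in 2-fold dilutions from 10 nM, equilibrium titrations of 100 pM
labeled siRNA against 3-fold titrant dilutions from 200 nM down to ~2 pM,
0-6 h uptake timecourses at several complex concentrations, a
6 h-transfection / 24 h-readout silencing dose-response, and a competitor
titration from 0 to 4 uM at fixed 20 nM complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BliTrace, SetTitration, bli_signal, set_free_fraction
from .inference import UptakeSeries, predict_dose_response
from .model import simulate, uptake_timecourse
from .params import Protocol, TraffickingParams
from .quantify import DoseResponse, MesfCalibration, fit_mesf

__all__ = [
    "NoiseSpec",
    "TruthBundle",
    "default_set_series",
    "gen_bli_traces",
    "gen_set_titration",
    "gen_cell_assays",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for one assay: lognormal CV, additive sigma, replicates."""

    cv: float = 0.0              # multiplicative coefficient of variation
    sigma_add: float = 0.0       # additive noise, assay units
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0 or self.sigma_add < 0 or self.replicates < 1:
            raise ValueError("cv, sigma_add >= 0 and replicates >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Unit-mean lognormal multiplicative noise plus additive floor."""
        values = np.asarray(values, float)
        out = values.copy()
        if self.cv > 0:
            sigma = np.sqrt(np.log1p(self.cv**2))
            out = out * rng.lognormal(-0.5 * sigma**2, sigma, size=out.shape)
        if self.sigma_add > 0:
            out = out + rng.normal(0.0, self.sigma_add, size=out.shape)
        return out


# per-assay default noise levels (CV): cell-based 5%, biosensor 2%,
# equilibrium titration 3%
CELL_CV = 0.05
BLI_CV = 0.02
SET_CV = 0.03


@dataclass(frozen=True)
class TruthBundle:
    """Ground truth for a full cell-assay generation run."""

    params: TraffickingParams = field(default_factory=TraffickingParams)
    protocol: Protocol = field(default_factory=Protocol)
    mesf_slope: float = 10.0         # fluorophores per a.u.
    mesf_intercept: float = 0.0
    dyes_per_sirna: float = 1.0
    ct_ref: float = 18.0             # housekeeping-gene Ct
    ct_target_control: float = 24.0  # target-gene Ct, untreated
    amplification_noise_ct: float = 0.0
    gfp_background: float = 150.0    # plate background, a.u.
    gfp_control: float = 1200.0      # untreated-well signal, a.u.


def default_set_series(top: float = 200e-9, bottom: float = 2e-12,
                       fold: float = 3.0) -> np.ndarray:
    """Serial-dilution titrant series (descending), e.g. 200 nM -> ~2 pM."""
    n = int(np.floor(np.log(top / bottom) / np.log(fold))) + 1
    return top / fold ** np.arange(n)


def gen_bli_traces(
    kon: float = 1e5,
    koff: float = 1e-4,
    rmax: float = 1.0,
    concs=None,
    t_assoc: float = 600.0,
    t_dissoc: float = 2400.0,
    dt: float = 5.0,
    noise: NoiseSpec = NoiseSpec(cv=BLI_CV),
) -> tuple[list[BliTrace], dict]:
    """Generate a multi-concentration biosensor association/dissociation set.

    Default concentration series: six 2-fold dilutions from 10 nM.
    Returns the traces and a truth sidecar.
    """
    if concs is None:
        concs = 10e-9 / 2.0 ** np.arange(6)
    concs = np.asarray(concs, float)
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    times = times[times > 0]
    rng = noise.rng()
    traces = []
    for _ in range(noise.replicates):
        for c in concs:
            clean = bli_signal(kon, koff, rmax, float(c), times, t_assoc)
            traces.append(BliTrace(
                conc=float(c), times=times,
                signal=noise.apply(clean, rng), t_assoc_end=t_assoc,
            ))
    truth = {"kon": kon, "koff": koff, "KD": koff / kon, "rmax": rmax,
             "concs": concs.tolist(), "t_assoc": t_assoc,
             "noise_cv": noise.cv, "seed": noise.seed}
    return traces, truth


def gen_set_titration(
    kd: float = 170e-12,
    a0: float = 100e-12,
    titrant_concs=None,
    scale: float = 1e14,
    offset: float = 50.0,
    noise: NoiseSpec = NoiseSpec(cv=SET_CV),
) -> tuple[SetTitration, dict]:
    """Generate a solution-equilibrium titration of labeled antigen.

    Signal is ``offset + scale * A0 * free_fraction`` with seeded noise
    (``scale`` in response units per molar free antigen, matching the
    parameterization of :func:`~sirnatraffic.binding.fit_set`).
    """
    if titrant_concs is None:
        titrant_concs = default_set_series()
    t = np.asarray(titrant_concs, float)
    clean = offset + scale * a0 * np.array(
        [set_free_fraction(a0, float(ti), kd) for ti in t])
    rng = noise.rng()
    titration = SetTitration(a0=a0, titrant_concs=t,
                             signal=noise.apply(clean, rng))
    truth = {"KD": kd, "a0": a0, "scale": scale, "offset": offset,
             "noise_cv": noise.cv, "seed": noise.seed}
    return titration, truth


def _beads_table(truth: TruthBundle, rng, cv: float) -> pd.DataFrame:
    intensities = np.array([1e2, 1e3, 1e4, 1e5, 1e6])
    mesf = truth.mesf_slope * intensities + truth.mesf_intercept
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mesf = mesf * rng.lognormal(-0.5 * sigma**2, sigma, mesf.shape)
    return pd.DataFrame({"intensity_au": intensities, "mesf": mesf})


def gen_cell_assays(
    truth: TruthBundle,
    uptake_doses=(20e-9, 6.7e-9, 2.2e-9),
    uptake_times=None,
    silencing_doses=None,
    noise: NoiseSpec = NoiseSpec(cv=CELL_CV),
) -> tuple[dict, dict]:
    """Generate linked uptake, silencing, qPCR and bead-calibration data.

    Simulates the trafficking model at the truth parameters, then applies
    the measurement chain *in reverse*: molecule counts become
    fluorescence intensities through the inverse MESF line, knockdown
    becomes target-gene Ct values through the inverse comparative-Ct
    transform, and each observable receives seeded noise.

    Returns ``(datasets, sidecar)`` where datasets holds

    * ``uptake``: DataFrame ``time_s, dose_M, intensity_au, replicate``
    * ``silencing``: DataFrame ``dose_M, response, replicate``
    * ``ct``: DataFrame ``sample, target, ct`` (target + reference genes)
    * ``beads``: DataFrame ``intensity_au, mesf``
    """
    p, proto = truth.params, truth.protocol
    if uptake_times is None:
        uptake_times = np.linspace(0.5, 6.0, 8) * 3600.0
    uptake_times = np.asarray(uptake_times, float)
    if silencing_doses is None:
        silencing_doses = np.geomspace(3e-12, 1e-7, 9)
    silencing_doses = np.asarray(silencing_doses, float)
    rng = noise.rng()

    # uptake: simulate each dose over the exposure window, counts -> a.u.
    uptake_rows = []
    clean_uptake = {}
    for dose in uptake_doses:
        proto_u = proto.with_(dose=float(dose), media_swap=False,
                              t_transfect=float(uptake_times[-1]),
                              t_obs=float(uptake_times[-1]))
        grid = np.concatenate([[0.0], uptake_times])
        counts = uptake_timecourse(simulate(proto_u, p, grid))[1:]
        clean_uptake[float(dose)] = counts
        intensity = counts * truth.dyes_per_sirna / truth.mesf_slope
        for rep in range(noise.replicates):
            noisy = noise.apply(intensity, rng)
            for t, val in zip(uptake_times, noisy):
                uptake_rows.append((t, float(dose), max(val, 0.0), rep))
    uptake_df = pd.DataFrame(
        uptake_rows, columns=["time_s", "dose_M", "intensity_au", "replicate"])

    # silencing dose-response; raw plate fluorescence encodes the
    # normalized expression through the background/control levels
    dr = predict_dose_response(p, proto, silencing_doses)
    span = truth.gfp_control - truth.gfp_background
    sil_rows = []
    for rep in range(noise.replicates):
        noisy = np.clip(noise.apply(dr.responses, rng), 0.0, None)
        for d, r in zip(silencing_doses, noisy):
            raw = truth.gfp_background + r * span
            sil_rows.append((float(d), float(raw), float(r), rep))
    silencing_df = pd.DataFrame(
        sil_rows, columns=["dose_M", "raw_au", "response", "replicate"])

    # qPCR: mRNA fold change at the highest silencing dose -> Ct values
    traj = simulate(proto.with_(dose=float(silencing_doses[-1])), p)
    m_control = p.k_txn / p.k_deg_m
    fold = traj["mrna"][-1] / m_control
    ct_target_treated = truth.ct_target_control - np.log2(max(fold, 1e-12))
    ct_rows = []
    for sample, tgt_ct in (("control", truth.ct_target_control),
                           ("treated", ct_target_treated)):
        for gene, ct in (("target", tgt_ct), ("reference", truth.ct_ref)):
            jitter = (rng.normal(0.0, truth.amplification_noise_ct)
                      if truth.amplification_noise_ct > 0 else 0.0)
            ct_rows.append((sample, gene, float(ct + jitter)))
    ct_df = pd.DataFrame(ct_rows, columns=["sample", "target", "ct"])

    beads_df = _beads_table(truth, rng, noise.cv if noise.cv > 0 else 0.0)

    # 4PL truth: fit the clean model curve once so the sidecar records the
    # EC50 the measurement chain should recover
    from .quantify import fit_four_pl
    fit = fit_four_pl(dr)
    sidecar = {
        "k_esc": p.k_esc,
        "koff_s": p.koff_s,
        "kon_s": p.kon_s,
        "mesf_slope": truth.mesf_slope,
        "dyes_per_sirna": truth.dyes_per_sirna,
        "mrna_fold_change": float(fold),
        "ec50": float(fit.ec50) if not fit.unidentifiable else None,
        "hill": float(fit.hill) if not fit.unidentifiable else None,
        "top": float(fit.top) if not fit.unidentifiable else None,
        "bottom": float(fit.bottom) if not fit.unidentifiable else None,
        "uptake_doses": [float(d) for d in uptake_doses],
        "uptake_times_s": uptake_times.tolist(),
        "silencing_doses": silencing_doses.tolist(),
        "gfp_background": truth.gfp_background,
        "gfp_control": truth.gfp_control,
        "noise_cv": noise.cv,
        "replicates": noise.replicates,
        "seed": noise.seed,
    }
    datasets = {
        "uptake": uptake_df,
        "silencing": silencing_df,
        "ct": ct_df,
        "beads": beads_df,
        "clean_uptake_counts": clean_uptake,
        "clean_dose_response": dr,
    }
    return datasets, sidecar


def uptake_series_from_frame(
    df: pd.DataFrame, cal: MesfCalibration
) -> list[UptakeSeries]:
    """Convert a generated/loaded uptake table into fit-ready count series.

    Replicates are averaged per (dose, time); intensities are converted to
    molecules through the calibration line.
    """
    from .quantify import mesf_convert
    series = []
    for dose, sub in df.groupby("dose_M"):
        mean = sub.groupby("time_s")["intensity_au"].mean()
        counts = mesf_convert(cal, mean.to_numpy(), 0.0)
        series.append(UptakeSeries(
            dose=float(dose), times=mean.index.to_numpy(float),
            counts=np.asarray(counts, float)))
    return series
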