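"""Reading and writing the package's tabular and configuration formats.

CSV dialects
------------
* trajectory: ``t_s`` plus one column per state species, one row per
  output-grid point; solver/protocol metadata go in a JSON sidecar.
* biosensor traces: ``time_s, signal, conc_M, phase`` with
  ``phase in {assoc, dissoc}``.
* equilibrium titration: ``titrant_M, signal``.
* dose-response: ``dose_M, response, replicate``.
* Ct table: ``sample, target, ct``; bead table: ``intensity_au, mesf``.

Configuration is YAML with keys matching the dataclass field names of
:class:`~sirnatraffic.params.TraffickingParams` and
:class:`~sirnatraffic.params.Protocol`, all in SI units.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .binding import BliTrace, SetTitration
from .model import SPECIES, Trajectory
from .params import Protocol, TraffickingParams
from .quantify import DoseResponse

__all__ = [
    "load_config",
    "save_config",
    "trajectory_to_frame",
    "write_trajectory",
    "read_bli_csv",
    "write_bli_csv",
    "read_set_csv",
    "write_set_csv",
    "read_dose_response_csv",
    "write_dose_response_csv",
]


def load_config(path) -> tuple[TraffickingParams, Protocol]:
    """Load model parameters and protocol from a YAML file.

    Top-level keys ``params`` and ``protocol`` each hold a mapping of
    field names; missing fields keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = TraffickingParams(**(raw.get("params") or {}))
    protocol = Protocol(**(raw.get("protocol") or {}))
    return params, protocol


def save_config(path, params: TraffickingParams, protocol: Protocol) -> None:
    payload = {
        "params": dataclasses.asdict(params),
        "protocol": dataclasses.asdict(protocol),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    frame = pd.DataFrame(traj.states, columns=list(SPECIES))
    frame.insert(0, "t_s", traj.times)
    return frame


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory CSV plus a JSON metadata sidecar (``.meta.json``)."""
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False)
    meta = {
        "params": dataclasses.asdict(traj.params),
        "protocol": dataclasses.asdict(traj.protocol),
        "solver": {"method": "LSODA", "rtol": 1e-8,
                   "atol_molar": 1e-15, "atol_molecules": 1e-3},
        "package_version": _pkg_version,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def write_bli_csv(path, traces: list[BliTrace]) -> None:
    rows = []
    for tr in traces:
        phase = np.where(tr.times <= tr.t_assoc_end, "assoc", "dissoc")
        rows.append(pd.DataFrame({
            "time_s": tr.times, "signal": tr.signal,
            "conc_M": tr.conc, "phase": phase,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_bli_csv(path) -> list[BliTrace]:
    df = pd.read_csv(path)
    traces = []
    for conc, sub in df.groupby("conc_M", sort=True):
        sub = sub.sort_values("time_s")
        assoc = sub[sub["phase"] == "assoc"]
        if assoc.empty:
            raise ValueError(f"trace at {conc} M has no association phase")
        traces.append(BliTrace(
            conc=float(conc),
            times=sub["time_s"].to_numpy(float),
            signal=sub["signal"].to_numpy(float),
            t_assoc_end=float(assoc["time_s"].max()),
        ))
    return traces


def write_set_csv(path, titration: SetTitration) -> None:
    pd.DataFrame({
        "titrant_M": titration.titrant_concs, "signal": titration.signal,
    }).to_csv(path, index=False)


def read_set_csv(path, a0: float) -> SetTitration:
    df = pd.read_csv(path)
    return SetTitration(a0=a0,
                        titrant_concs=df["titrant_M"].to_numpy(float),
                        signal=df["signal"].to_numpy(float))


def write_dose_response_csv(path, dr: DoseResponse) -> None:
    pd.DataFrame({
        "dose_M": dr.doses, "response": dr.responses,
        "replicate": dr.replicate,
    }).to_csv(path, index=False)


def read_dose_response_csv(path) -> DoseResponse:
    """Read a dose-response CSV, averaging replicates per dose."""
    df = pd.read_csv(path)
    mean = df.groupby("dose_M")["response"].mean().sort_index()
    return DoseResponse(doses=mean.index.to_numpy(float),
                        responses=mean.to_numpy(float))
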