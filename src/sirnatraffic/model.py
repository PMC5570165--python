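"""Mass-action ODE model of receptor-targeted siRNA delivery.

Free siRNA (S), free carrier (C) and the 1:1 siRNA-carrier complex (X) are
tracked separately in the extracellular medium (molar), on the cell surface
bound to receptor (molecules/cell), in the endosomal compartment and in the
cytoplasm (molecules/cell). Receptor-mediated uptake follows a net
internalization scheme: bound receptor internalizes at ``k_int``, delivers
its cargo to the endosome and returns to the surface, so the total surface
receptor pool is constant. Endosomal escape is first order and moves free
siRNA, free carrier and the intact complex alike (the pore-based escape
route passes whole complexes). Only *free* cytoplasmic siRNA loads RISC;
carrier-bound cytoplasmic siRNA is sequestered until it dissociates, which
is the mechanism that penalizes extreme carrier affinity. Active RISC
cleaves target mRNA catalytically and the reporter protein follows by
translation/turnover.

Degraded siRNA equivalents accumulate in ``d_sink`` and siRNA removed by
the media swap in ``w_sink``, so that total siRNA is exactly accounted for
at all times (see :func:`mass_balance_residual`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import N_AVOGADRO, Protocol, TraffickingParams
from .binding import set_free_fraction

__all__ = [
    "SPECIES",
    "SystemState",
    "Trajectory",
    "derivatives",
    "initial_state",
    "simulate",
    "uptake_timecourse",
    "silencing_readout",
    "mass_balance_residual",
]

#: State-vector layout. Extracellular entries (and cmp_x) are molar; all
#: others are molecules per cell.
SPECIES = (
    "s_x", "c_x", "x_x",          # extracellular, M
    "r", "rc", "rx",              # surface receptor species, molecules
    "s_e", "c_e", "x_e",          # endosomal, molecules
    "s_c", "c_c", "x_c",          # cytoplasmic, molecules
    "risc_a", "mrna", "protein",  # RNAi module, molecules
    "d_sink",                     # degraded siRNA equivalents, molecules
    "cmp_x", "r_cmp",             # competitor: medium (M), on receptor
    "w_sink",                     # siRNA washed out at media swap
)

_IDX = {name: i for i, name in enumerate(SPECIES)}
_MOLAR = np.array([name in ("s_x", "c_x", "x_x", "cmp_x") for name in SPECIES])


@dataclass(frozen=True)
class SystemState:
    """One snapshot of the delivery system; see :data:`SPECIES` for units."""

    s_x: float
    c_x: float
    x_x: float
    r: float
    rc: float
    rx: float
    s_e: float
    c_e: float
    x_e: float
    s_c: float
    c_c: float
    x_c: float
    risc_a: float
    mrna: float
    protein: float
    d_sink: float
    cmp_x: float = 0.0
    r_cmp: float = 0.0
    w_sink: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, y: Sequence[float]) -> "SystemState":
        return cls(**{name: float(v) for name, v in zip(SPECIES, y)})

    def validate(self, params: TraffickingParams, tol: float = 1e-9) -> None:
        """Check non-negativity, receptor conservation and the RISC cap."""
        y = self.to_vector()
        scale = max(1.0, float(np.max(np.abs(y))))
        if np.any(y < -tol * scale):
            bad = SPECIES[int(np.argmin(y))]
            raise ValueError(f"negative species {bad} = {np.min(y):g}")
        r_sum = self.r + self.rc + self.rx + self.r_cmp
        if abs(r_sum - params.R_tot) > 1e-6 * params.R_tot:
            raise ValueError(
                f"receptor conservation violated: {r_sum:g} != {params.R_tot:g}"
            )
        if self.risc_a > params.RISC_tot * (1 + 1e-9):
            raise ValueError("risc_a exceeds RISC_tot")


def _rhs(t: float, y: np.ndarray, p: TraffickingParams) -> np.ndarray:
    """Right-hand side; `t` is unused (the system is autonomous between events)."""
    (s_x, c_x, x_x, r, rc, rx, s_e, c_e, x_e, s_c, c_c, x_c,
     risc_a, mrna, prot, _d, cmp_x, r_cmp, _w) = y

    f = p.percell_to_molar                  # molecules/cell -> M
    kon_e = p.kon_s / (N_AVOGADRO * p.V_endo)
    kon_c = p.kon_s / (N_AVOGADRO * p.V_cyt)

    # extracellular siRNA-carrier binding (molar)
    v_x = p.kon_s * s_x * c_x - p.koff_s * x_x
    # receptor binding fluxes (molecules/cell/s)
    b_c = p.kon_r * c_x * r
    u_c = p.koff_r * rc
    b_x = p.kon_r * x_x * r
    u_x = p.koff_r * rx
    b_g = p.kon_cmp * cmp_x * r
    u_g = p.koff_cmp * r_cmp
    # fluid-phase uptake (molecules/cell/s)
    p_s = p.k_pino * N_AVOGADRO * s_x
    p_c = p.k_pino * N_AVOGADRO * c_x
    p_x = p.k_pino * N_AVOGADRO * x_x
    # intracellular binding (molecules/cell/s)
    v_e = kon_e * s_e * c_e - p.koff_s * x_e
    v_c = kon_c * s_c * c_c - p.koff_s * x_c
    load = p.k_load * s_c * (p.RISC_tot - risc_a)
    leak = p.k_esc + p.k_deg_endo + p.k_dil

    dy = np.empty_like(y)
    dy[_IDX["s_x"]] = -v_x - f * p_s
    dy[_IDX["c_x"]] = -v_x + f * (u_c - b_c) - f * p_c
    dy[_IDX["x_x"]] = v_x + f * (u_x - b_x) - f * p_x
    dy[_IDX["cmp_x"]] = f * (u_g - b_g)
    dy[_IDX["rc"]] = b_c - u_c - p.k_int * rc
    dy[_IDX["rx"]] = b_x - u_x - p.k_int * rx
    dy[_IDX["r_cmp"]] = b_g - u_g - p.k_int * r_cmp
    dy[_IDX["r"]] = (
        -(b_c + b_x + b_g) + (u_c + u_x + u_g)
        + p.k_int * (rc + rx + r_cmp)
    )
    dy[_IDX["s_e"]] = p_s - v_e - leak * s_e
    dy[_IDX["c_e"]] = p.k_int * rc + p_c - v_e - leak * c_e
    dy[_IDX["x_e"]] = p.k_int * rx + p_x + v_e - leak * x_e
    dy[_IDX["s_c"]] = (
        p.k_esc * s_e - v_c - (p.k_deg_s_cyt + p.k_dil) * s_c - load
    )
    dy[_IDX["c_c"]] = p.k_esc * c_e - v_c - (p.k_deg_c_cyt + p.k_dil) * c_c
    dy[_IDX["x_c"]] = p.k_esc * x_e + v_c - (p.k_deg_x_cyt + p.k_dil) * x_c
    dy[_IDX["risc_a"]] = load - (p.k_risc_decay + p.k_dil) * risc_a
    dy[_IDX["mrna"]] = (
        p.k_txn - (p.k_deg_m + p.k_dil) * mrna - p.k_slice * risc_a * mrna
    )
    dy[_IDX["protein"]] = p.k_tln * mrna - (p.k_deg_p + p.k_dil) * prot
    dy[_IDX["d_sink"]] = (
        (p.k_deg_endo + p.k_dil) * (s_e + x_e)
        + (p.k_deg_s_cyt + p.k_dil) * s_c
        + (p.k_deg_x_cyt + p.k_dil) * x_c
        + (p.k_risc_decay + p.k_dil) * risc_a
    )
    dy[_IDX["w_sink"]] = 0.0
    return dy


def derivatives(
    state: SystemState,
    params: TraffickingParams,
    protocol: Protocol | None = None,
    t: float = 0.0,
) -> SystemState:
    """Time derivative of every species at the given state.

    The protocol argument is accepted for interface symmetry; the vector
    field itself is autonomous (protocol events act between integration
    segments, not inside the right-hand side).
    """
    state.validate(params)
    return SystemState.from_vector(_rhs(t, state.to_vector(), params))


def initial_state(protocol: Protocol, params: TraffickingParams) -> SystemState:
    """Initial condition: dosed medium, naive cell at reporter steady state.

    The siRNA/carrier mixture is pre-equilibrated at the stated loading
    ratio using the quadratic binding equilibrium (free fraction of siRNA
    against total carrier), unless ``protocol.preequilibrate`` is False,
    in which case the full dose starts as complex.
    """
    s_tot = protocol.dose
    c_tot = protocol.dose * protocol.loading_ratio
    if s_tot > 0 and protocol.preequilibrate and params.kon_s > 0:
        free = set_free_fraction(s_tot, c_tot, params.KD_s)
        x0 = s_tot * (1.0 - free)
        s0 = s_tot - x0
        c0 = c_tot - x0
    else:
        x0, s0, c0 = s_tot, 0.0, max(c_tot - s_tot, 0.0)
    m0 = params.k_txn / params.k_deg_m if params.k_deg_m > 0 else 0.0
    p0 = params.k_tln * m0 / params.k_deg_p if params.k_deg_p > 0 else 0.0
    return SystemState(
        s_x=s0, c_x=c0, x_x=x0,
        r=params.R_tot, rc=0.0, rx=0.0,
        s_e=0.0, c_e=0.0, x_e=0.0,
        s_c=0.0, c_c=0.0, x_c=0.0,
        risc_a=0.0, mrna=m0, protein=p0, d_sink=0.0,
        cmp_x=protocol.competitor_conc, r_cmp=0.0, w_sink=0.0,
    )


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course on a fixed output grid.

    ``states`` has shape (len(times), len(SPECIES)); column order follows
    :data:`SPECIES`.
    """

    times: np.ndarray
    states: np.ndarray
    params: TraffickingParams
    protocol: Protocol

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_vector(self.states[i])

    def interpolate(self, species: str, t: float) -> float:
        return float(np.interp(t, self.times, self[species]))


# solver settings: stiff-capable, tight relative tolerance, per-species
# absolute floors (1e-15 M for molar entries, 1e-3 molecules otherwise)
_RTOL = 1e-8
_ATOL_MOLAR = 1e-15
_ATOL_AMOUNT = 1e-3
_CLIP_WARN_FRACTION = 1e-12


def _integrate(y0, t0, t1, params):
    atol = np.where(_MOLAR, _ATOL_MOLAR, _ATOL_AMOUNT)
    sol = solve_ivp(
        _rhs, (t0, t1), y0, args=(params,),
        method="LSODA", rtol=_RTOL, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed on [{t0:g}, {t1:g}] s: {sol.message}; "
            f"params={params!r}"
        )
    return sol


def simulate(
    protocol: Protocol,
    params: TraffickingParams,
    output_grid: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the delivery system over one protocol.

    The integration is split at the media-swap event (``t_transfect``):
    extracellular species (and competitor) are zeroed there when
    ``protocol.media_swap`` is set, the removed siRNA equivalents are
    booked into ``w_sink``, and the solver restarts from the post-event
    state. Tiny negative values produced by the solver are clipped to
    zero (warning if they exceed 1e-12 of the species scale).
    """
    if output_grid is None:
        output_grid = np.linspace(0.0, protocol.t_obs, 241)
    grid = np.asarray(output_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("output_grid must be 1-D and strictly increasing")
    if grid[0] < 0 or grid[-1] > protocol.t_obs:
        raise ValueError("output_grid must lie within [0, t_obs]")

    y0 = initial_state(protocol, params).to_vector()
    t_swap = protocol.t_transfect
    pre_grid = grid[grid <= t_swap]
    post_grid = grid[grid > t_swap]

    # integrate up to the event so the swap applies to the exact state at
    # t_transfect even when the grid skips it
    sol = _integrate(y0, 0.0, t_swap, params)
    rows = [sol.sol(pre_grid).T] if pre_grid.size else []
    y_swap = sol.y[:, -1].copy()

    if protocol.media_swap:
        f = params.percell_to_molar
        washed = (y_swap[_IDX["s_x"]] + y_swap[_IDX["x_x"]]) / f
        y_swap[_IDX["w_sink"]] += max(washed, 0.0)
        for name in ("s_x", "c_x", "x_x", "cmp_x"):
            y_swap[_IDX[name]] = 0.0

    if post_grid.size:
        sol2 = _integrate(y_swap, t_swap, protocol.t_obs, params)
        rows.append(sol2.sol(post_grid).T)

    states = np.vstack(rows) if rows else np.empty((0, len(SPECIES)))

    scale = np.maximum(np.max(np.abs(states), axis=0, initial=0.0), 1.0)
    atol = np.where(_MOLAR, _ATOL_MOLAR, _ATOL_AMOUNT)
    warn_floor = np.maximum(_CLIP_WARN_FRACTION * scale, 10.0 * atol)
    neg = states < 0
    if np.any(states < -warn_floor):
        worst = np.min(states / scale)
        warnings.warn(
            f"clipping negative species values (worst {worst:.2e} of scale)",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.any(neg):
        states = np.where(neg, 0.0, states)
    return Trajectory(times=grid, states=states, params=params, protocol=protocol)


def uptake_timecourse(traj: Trajectory) -> np.ndarray:
    """Intact intracellular siRNA per cell at each output time.

    Counts endosomal and cytoplasmic free siRNA and complex plus loaded
    RISC. Degraded siRNA is excluded: the fluorophore is assumed lost on
    degradation. Surface-bound complex is not counted (washed off in the
    assay this mirrors).
    """
    return (
        traj["s_e"] + traj["x_e"] + traj["s_c"] + traj["x_c"] + traj["risc_a"]
    )


def silencing_readout(
    traj: Trajectory, control: Trajectory, t_obs: float | None = None
) -> float:
    """Normalized reporter expression: treated / zero-dose control protein.

    Mirrors the plate assay normalization against carrier-free control
    wells read at the same time.
    """
    if t_obs is None:
        t_obs = traj.protocol.t_obs
    for tr in (traj, control):
        if not (tr.times[0] <= t_obs <= tr.times[-1]):
            raise ValueError("t_obs outside trajectory grid")
    p_ctrl = control.interpolate("protein", t_obs)
    if p_ctrl <= 0:
        raise ValueError("degenerate control: protein <= 0 at t_obs")
    return traj.interpolate("protein", t_obs) / p_ctrl


def _total_sirna(traj: Trajectory) -> np.ndarray:
    """siRNA equivalents per cell at every grid time (excluding sinks)."""
    f = traj.params.percell_to_molar
    extracellular = (traj["s_x"] + traj["x_x"]) / f
    return (
        extracellular
        + traj["rx"]
        + traj["s_e"] + traj["x_e"]
        + traj["s_c"] + traj["x_c"]
        + traj["risc_a"]
    )


def mass_balance_residual(traj: Trajectory) -> float:
    """Worst-case relative error of the siRNA bookkeeping over the grid.

    Total intact siRNA plus the degradation and wash-out sinks must equal
    the initial total at every time; returns the max relative deviation
    (0.0 for a zero-dose run by convention).
    """
    total = _total_sirna(traj) + traj["d_sink"] + traj["w_sink"]
    t0 = total[0]
    if t0 <= 0:
        return 0.0
    return float(np.max(np.abs(total - t0)) / t0)
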