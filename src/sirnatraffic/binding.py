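"""Closed-form binding models and fitters for the two affinity assays.

Biosensor (biolayer-interferometry style) traces follow pseudo-first-order
1:1 kinetics: during association at analyte concentration ``c`` the
response relaxes toward the concentration-dependent plateau with observed
rate ``kon*c + koff``; during dissociation it decays mono-exponentially at
``koff``. Multiple concentrations are fitted globally with shared rate
constants.

Solution-equilibrium titrations (fixed labeled antigen A0, varying titrant
T0) follow the exact quadratic 1:1 equilibrium, which accounts for antigen
depletion; the readout is proportional to the *free* antigen fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BliTrace",
    "KineticFit",
    "SetTitration",
    "EquilibriumFit",
    "bli_signal",
    "fit_bli_global",
    "set_free_fraction",
    "fit_set",
]


@dataclass(frozen=True)
class BliTrace:
    """One baseline-subtracted biosensor trace at a single analyte conc."""

    conc: float                 # analyte concentration, M
    times: np.ndarray           # s, strictly increasing, from 0
    signal: np.ndarray          # response units
    t_assoc_end: float          # association/dissociation boundary, s

    def __post_init__(self):
        t = np.asarray(self.times, float)
        s = np.asarray(self.signal, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)
        if self.conc < 0:
            raise ValueError("conc must be >= 0")
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if s.shape != t.shape:
            raise ValueError("signal/times shape mismatch")
        if not 0 < self.t_assoc_end <= t[-1] + 1e-12:
            raise ValueError("t_assoc_end must fall inside the trace")


@dataclass(frozen=True)
class KineticFit:
    """Globally fitted 1:1 kinetic parameters."""

    kon: float                  # M^-1 s^-1
    koff: float                 # s^-1
    rmax: np.ndarray            # response units, one per trace (may be tied)
    residual_norm: float
    stderr: dict = field(default_factory=dict)
    per_trace_rss: np.ndarray | None = None
    converged: bool = True

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant koff/kon, M."""
        return self.koff / self.kon


def bli_signal(
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    times: np.ndarray,
    t_assoc_end: float,
) -> np.ndarray:
    """Predicted 1:1 biosensor response over an association/dissociation cycle.

    Association (t <= t_assoc_end)::

        R(t) = Rmax * c / (c + KD) * (1 - exp(-(kon*c + koff) * t))

    Dissociation: exponential decay at ``koff`` from the response reached
    at the end of association.
    """
    if kon <= 0 or koff < 0 or rmax <= 0:
        raise ValueError("kon, rmax must be > 0 and koff >= 0")
    if conc < 0:
        raise ValueError("conc must be >= 0")
    t = np.asarray(times, float)
    if conc == 0:
        return np.zeros_like(t)
    kd = koff / kon
    kobs = kon * conc + koff
    plateau = rmax * conc / (conc + kd)
    r_assoc = plateau * -np.expm1(-kobs * np.minimum(t, t_assoc_end))
    r_end = plateau * -np.expm1(-kobs * t_assoc_end)
    r_dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, r_assoc, r_dissoc)


def _bli_residuals(theta, traces, shared_rmax):
    # exponents clipped so wild optimizer steps overflow gracefully
    theta = np.clip(theta, -30.0, 30.0)
    log_kon, log_koff = theta[0], theta[1]
    kon, koff = 10.0 ** log_kon, 10.0 ** log_koff
    rmaxes = 10.0 ** np.asarray(theta[2:])
    res = []
    for i, tr in enumerate(traces):
        rm = rmaxes[0] if shared_rmax else rmaxes[i]
        pred = bli_signal(kon, koff, rm, tr.conc, tr.times, tr.t_assoc_end)
        res.append(pred - tr.signal)
    return np.concatenate(res)


# D10-style multi-start grids (log10 space)
_KOFF_STARTS = np.arange(-6.0, 0.0, 1.0)           # 1e-6 .. 1e-1 s^-1
_KD_GRID_BOUNDS = (-12.0, -6.0)                    # 1 pM .. 1 uM


def fit_bli_global(
    traces: list[BliTrace],
    shared_rmax: bool = True,
    kon_init: float = 1e5,
) -> KineticFit:
    """Global least-squares fit of a 1:1 kinetic model to multiple traces.

    Rate constants are shared across all traces; ``Rmax`` is shared by
    default (same sensor batch) or per-trace otherwise. Fitting runs in
    log10 parameter space from a grid of ``koff`` starting values and the
    lowest-residual solution wins. Raises if fewer than two distinct
    analyte concentrations are supplied (kon and koff would not be
    separable from a single curve in practice).
    """
    concs = {tr.conc for tr in traces}
    if len([c for c in concs if c > 0]) < 2:
        raise ValueError("global kinetic fit needs >= 2 analyte concentrations")
    n_rmax = 1 if shared_rmax else len(traces)
    sig_scale = max(float(np.max(np.abs(tr.signal))) for tr in traces)
    sig_scale = max(sig_scale, 1e-12)

    best = None
    for log_koff0 in _KOFF_STARTS:
        theta0 = np.concatenate(
            [[math.log10(kon_init), log_koff0],
             np.full(n_rmax, math.log10(sig_scale))]
        )
        try:
            sol = least_squares(
                _bli_residuals, theta0, args=(traces, shared_rmax),
                method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("BLI global fit failed from every start")

    kon = 10.0 ** best.x[0]
    koff = 10.0 ** best.x[1]
    rmaxes = 10.0 ** best.x[2:]
    if shared_rmax:
        rmaxes = np.full(len(traces), rmaxes[0])
    per_rss = []
    i0 = 0
    res = _bli_residuals(best.x, traces, shared_rmax)
    for tr in traces:
        n = tr.times.size
        per_rss.append(float(np.sum(res[i0:i0 + n] ** 2)))
        i0 += n
    stderr = _stderr_from_jacobian(best, ("log10_kon", "log10_koff"))
    converged = bool(best.status > 0)
    return KineticFit(
        kon=kon, koff=koff, rmax=rmaxes,
        residual_norm=float(np.sqrt(2 * best.cost)),
        stderr=stderr, per_trace_rss=np.asarray(per_rss),
        converged=converged,
    )


def _stderr_from_jacobian(sol, names):
    """Asymptotic standard errors of the first len(names) parameters."""
    try:
        m, n = sol.jac.shape
        dof = max(m - n, 1)
        s2 = 2 * sol.cost / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        return {nm: float(np.sqrt(cov[i, i])) for i, nm in enumerate(names)}
    except Exception:
        return {}


def set_free_fraction(a0: float, t0: float, kd: float) -> float:
    """Free fraction of antigen in a 1:1 equilibrium with depletion.

    For total antigen ``a0``, total titrant ``t0`` and dissociation
    constant ``kd``, the bound concentration solves the quadratic mass
    balance; the returned free fraction is ``1 - bound/a0``. Uses the
    cancellation-free root form, accurate down to a0 << kd.
    """
    if a0 <= 0 or t0 < 0 or kd <= 0:
        raise ValueError("need a0 > 0, t0 >= 0, kd > 0")
    if t0 == 0.0:
        return 1.0
    s = a0 + t0 + kd
    disc = s * s - 4.0 * a0 * t0
    # disc >= (a0 - t0)^2 + kd^2 > 0 always
    bound = 2.0 * a0 * t0 / (s + math.sqrt(disc))
    return min(max(1.0 - bound / a0, 0.0), 1.0)


@dataclass(frozen=True)
class SetTitration:
    """Solution-equilibrium titration: free-antigen signal vs titrant."""

    a0: float                       # total labeled antigen, M
    titrant_concs: np.ndarray       # M
    signal: np.ndarray              # free-antigen readout, a.u.

    def __post_init__(self):
        t = np.asarray(self.titrant_concs, float)
        s = np.asarray(self.signal, float)
        object.__setattr__(self, "titrant_concs", t)
        object.__setattr__(self, "signal", s)
        if self.a0 <= 0:
            raise ValueError("a0 must be > 0")
        if np.any(t < 0) or len(np.unique(t)) != t.size:
            raise ValueError("titrant concs must be non-negative and distinct")
        if s.shape != t.shape:
            raise ValueError("signal/concs shape mismatch")


@dataclass(frozen=True)
class EquilibriumFit:
    """Fitted quadratic equilibrium titration parameters."""

    kd: float                   # M
    scale: float                # signal per unit free-antigen concentration
    offset: float               # background signal
    residual_norm: float
    stderr: dict = field(default_factory=dict)
    unidentifiable: bool = False


_SET_LOG_KD_STARTS = np.arange(*_KD_GRID_BOUNDS, 1.0)


def fit_set(titration: SetTitration) -> EquilibriumFit:
    """Fit KD from a solution-equilibrium titration.

    Model: ``signal = offset + scale * A0 * free_fraction(A0, T, KD)``.
    Residuals are weighted by the predicted signal (plate-reader noise is
    multiplicative, so relative error is the right loss). For each
    log-spaced KD start the linear pair (scale, offset) is profiled out by
    weighted least squares, then all three parameters are polished
    jointly. A fit whose KD lands within one grid step of the multi-start
    boundary, or a titration carrying no information (flat signal), is
    flagged unidentifiable.
    """
    if titration.titrant_concs.size < 6:
        raise ValueError("need >= 6 titrant points")
    t, y = titration.titrant_concs, titration.signal
    a0 = titration.a0
    span = float(np.max(y) - np.min(y))
    scale0 = max(float(np.max(np.abs(y))), 1e-12)
    if span <= 1e-12 * scale0:
        return EquilibriumFit(
            kd=float("nan"), scale=0.0, offset=float(np.mean(y)),
            residual_norm=0.0, unidentifiable=True,
        )

    w = 1.0 / np.maximum(np.abs(y), 1e-3 * scale0)

    def model_free(log_kd):
        kd = 10.0 ** float(np.clip(log_kd, -30, 0))
        return np.array([a0 * set_free_fraction(a0, ti, kd) for ti in t])

    def residuals(theta):
        log_kd, scale, offset = theta
        return w * (offset + scale * model_free(log_kd) - y)

    best = None
    for log_kd0 in _SET_LOG_KD_STARTS:
        ff = model_free(log_kd0)
        design = np.column_stack([ff, np.ones_like(ff)]) * w[:, None]
        coef, *_ = np.linalg.lstsq(design, y * w, rcond=None)
        theta0 = np.array([log_kd0, coef[0], coef[1]])
        sol = least_squares(
            residuals, theta0, method="lm",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    log_kd, scale, offset = best.x
    # within one grid step (one decade) of the multi-start boundary ->
    # the data place KD at or beyond the scanned range
    lo, hi = _KD_GRID_BOUNDS
    unident = not (lo + 1.0 < log_kd < hi - 1.0)
    stderr = _stderr_from_jacobian(best, ("log10_kd", "scale", "offset"))
    return EquilibriumFit(
        kd=10.0 ** log_kd, scale=float(scale), offset=float(offset),
        residual_norm=float(np.sqrt(2 * best.cost)),
        stderr=stderr, unidentifiable=bool(unident),
    )
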