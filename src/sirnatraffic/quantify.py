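"""Readout transformations: normalization, 4PL dose-response, ddCt, MESF.

These are the standard plate/flow-cytometry reductions applied between raw
instrument output and the quantities the kinetic model works with:
background-subtracted normalized reporter expression, EC50 from a
four-parameter logistic (4PL) fit, relative mRNA fold change by the
comparative-Ct method, and fluorescence-to-molecule conversion against a
MESF bead calibration line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponse",
    "FourPLFit",
    "MesfCalibration",
    "normalize_expression",
    "fit_four_pl",
    "four_pl",
    "ddct_fold_change",
    "fit_mesf",
    "mesf_convert",
]


def normalize_expression(raw, background, control):
    """Background-subtract and normalize a reporter signal.

    Returns ``(raw - background) / (control - background)``; negative
    results are clipped to zero with a warning. Raises if the control does
    not exceed background. Accepts scalars or arrays for ``raw``.
    """
    span = control - background
    if span <= 0:
        raise ValueError("degenerate control: control - background <= 0")
    value = (np.asarray(raw, float) - background) / span
    if np.any(value < 0):
        warnings.warn("negative normalized expression clipped to 0",
                      RuntimeWarning, stacklevel=2)
        value = np.clip(value, 0.0, None)
    if value.ndim == 0:
        return float(value)
    return value


@dataclass(frozen=True)
class DoseResponse:
    """A silencing dose-response: normalized expression vs complex dose."""

    doses: np.ndarray            # M
    responses: np.ndarray        # dimensionless, >= 0
    replicate: int = 0

    def __post_init__(self):
        d = np.asarray(self.doses, float)
        r = np.asarray(self.responses, float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)
        if np.any(d < 0) or np.any(r < 0):
            raise ValueError("doses and responses must be >= 0")
        if d.shape != r.shape:
            raise ValueError("doses/responses shape mismatch")


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of a (decreasing) dose-response."""

    top: float
    bottom: float
    ec50: float                  # M (same units as the input doses)
    hill: float
    residual_norm: float
    stderr: dict = field(default_factory=dict)
    unidentifiable: bool = False

    def __post_init__(self):
        if not self.unidentifiable:
            if self.ec50 <= 0:
                raise ValueError("ec50 must be > 0")
            if self.top < self.bottom:
                raise ValueError("top must be >= bottom")

    def predict(self, doses) -> np.ndarray:
        return four_pl(np.asarray(doses, float), self.top, self.bottom,
                       self.ec50, self.hill)


def four_pl(dose, top, bottom, ec50, hill):
    """Decreasing four-parameter logistic:
    ``bottom + (top - bottom) / (1 + (dose/ec50)**hill)``.

    At ``dose == ec50`` the value is exactly ``(top + bottom) / 2``.
    """
    dose = np.asarray(dose, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
        term = np.where(dose > 0, ratio ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + term)


def fit_four_pl(dr: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit with log-dose multi-start on EC50.

    Uses the decreasing-response convention (``hill > 0``): silencing
    curves fall with dose. Data that are flat to within noise of machine
    precision are returned flagged unidentifiable rather than fitted.
    """
    d, y = dr.doses, dr.responses
    if len(np.unique(d)) < 5:
        raise ValueError("need >= 5 distinct doses")
    span = float(np.max(y) - np.min(y))
    if span <= 1e-9 * max(float(np.max(np.abs(y))), 1e-30):
        return FourPLFit(
            top=float(np.mean(y)), bottom=float(np.mean(y)),
            ec50=float("nan"), hill=float("nan"),
            residual_norm=0.0, unidentifiable=True,
        )
    pos = d[d > 0]

    def residuals(theta):
        top, bottom, log_ec50, log_hill = theta
        return four_pl(d, top, bottom, 10.0 ** log_ec50, 10.0 ** log_hill) - y

    top0 = float(np.max(y))
    bot0 = float(np.min(y))
    starts = np.linspace(math.log10(pos.min()), math.log10(pos.max()), 7)
    best = None
    for log_ec0 in starts:
        sol = least_squares(
            residuals, np.array([top0, bot0, log_ec0, 0.0]),
            method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    top, bottom, log_ec50, log_hill = best.x
    if bottom > top:   # decreasing convention: reflect a flipped solution
        top, bottom = bottom, top
    from .binding import _stderr_from_jacobian
    stderr = _stderr_from_jacobian(
        best, ("top", "bottom", "log10_ec50", "log10_hill"))
    # EC50 far outside the dosed range -> the transition was not sampled
    lo = math.log10(pos.min()) - 2.0
    hi = math.log10(pos.max()) + 2.0
    unident = not (lo < log_ec50 < hi)
    return FourPLFit(
        top=float(top), bottom=float(bottom),
        ec50=10.0 ** log_ec50, hill=10.0 ** log_hill,
        residual_norm=float(np.sqrt(2 * best.cost)),
        stderr=stderr, unidentifiable=bool(unident),
    )


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the comparative-Ct method: ``2**(-ddCt)``.

    ``ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control``
    with the reference (housekeeping) gene measured in the same samples.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control,
           ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)


@dataclass
class MesfCalibration:
    """Linear fluorescence-to-molecule calibration from MESF beads.

    Fit ``mesf = slope * intensity + intercept`` over >= 3 bead
    populations; ``dyes_per_molecule`` converts fluorophore counts to
    siRNA molecules (labeling stoichiometry, default one dye per duplex).
    """

    bead_intensity: np.ndarray       # a.u.
    bead_mesf: np.ndarray            # fluorophores per bead
    dyes_per_molecule: float = 1.0
    zero_intercept: bool = False
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self):
        x = np.asarray(self.bead_intensity, float)
        m = np.asarray(self.bead_mesf, float)
        self.bead_intensity, self.bead_mesf = x, m
        if x.size < 3:
            raise ValueError("need >= 3 bead populations")
        if x.shape != m.shape:
            raise ValueError("bead table shape mismatch")
        if self.dyes_per_molecule <= 0:
            raise ValueError("dyes_per_molecule must be > 0")

    def fit(self) -> "MesfCalibration":
        x, m = self.bead_intensity, self.bead_mesf
        if self.zero_intercept:
            slope = float(np.dot(x, m) / np.dot(x, x))
            intercept = 0.0
        else:
            design = np.column_stack([x, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(design, m, rcond=None)
            slope, intercept = float(coef[0]), float(coef[1])
        if slope <= 0:
            raise ValueError("calibration slope must be > 0")
        self.slope, self.intercept = slope, intercept
        return self

    @property
    def fitted(self) -> bool:
        return self.slope is not None


def fit_mesf(
    bead_intensity,
    bead_mesf,
    dyes_per_molecule: float = 1.0,
    zero_intercept: bool = False,
) -> MesfCalibration:
    """Convenience constructor: build and fit a bead calibration line."""
    return MesfCalibration(
        np.asarray(bead_intensity, float), np.asarray(bead_mesf, float),
        dyes_per_molecule=dyes_per_molecule, zero_intercept=zero_intercept,
    ).fit()


def mesf_convert(cal: MesfCalibration, intensity, background=0.0):
    """Convert background-subtracted fluorescence to siRNA molecules/cell.

    The calibration slope maps the background-subtracted intensity to
    fluorophore counts (the fitted intercept absorbs instrument/bead
    baseline and is not re-applied to a difference of intensities, so a
    cell at exactly background converts to zero molecules); division by
    the labeling stoichiometry yields siRNA molecules. Negative results
    are clipped to zero with a warning.
    """
    if not cal.fitted:
        raise RuntimeError("calibration must be fitted before conversion")
    if np.any(np.asarray(intensity, float) < 0):
        raise ValueError("intensity must be >= 0")
    x = np.asarray(intensity, float) - background
    molecules = cal.slope * x / cal.dyes_per_molecule
    if np.any(molecules < 0):
        warnings.warn("negative molecule counts clipped to 0",
                      RuntimeWarning, stacklevel=2)
        molecules = np.clip(molecules, 0.0, None)
    if molecules.ndim == 0:
        return float(molecules)
    return molecules
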