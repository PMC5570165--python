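"""Parameter and protocol containers for the siRNA delivery trafficking model.

Units are SI throughout: concentrations in molar (M), amounts in molecules
per cell, times in seconds, volumes in litres. Bimolecular rate constants
are given in M^-1 s^-1 and converted to amount-space (molecule^-1 s^-1)
inside intracellular compartments via division by N_A * V_compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

N_AVOGADRO = 6.02214076e23

HOUR = 3600.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class TraffickingParams:
    """Rate constants, pool sizes and volumes of the delivery ODE system.

    The defaults describe an EGFR-targeted p19-dimer carrier delivering a
    21-bp siRNA to adherent epidermoid carcinoma cells expressing a
    destabilized GFP reporter. They are literature-scale magnitudes chosen
    by this package, exposed for configuration, and not measurements.

    Attributes
    ----------
    kon_s, koff_s:
        siRNA-carrier association (M^-1 s^-1) and dissociation (s^-1)
        rates. ``koff_s`` is the natural sweep variable when exploring
        affinity at fixed on-rate.
    kon_r, koff_r:
        Apparent carrier-receptor rates under the monovalent-binder
        simplification.
    k_int:
        Net internalization rate of receptor-bound species (s^-1); the
        receptor returns to the surface so the surface pool is constant.
    k_pino:
        Fluid-phase (pinocytic) uptake volume rate, L cell^-1 s^-1.
        Zero by default; relevant only for untargeted carriers.
    k_esc:
        First-order endosomal escape rate (s^-1), applied equally to
        endosomal free siRNA, free carrier and complex.
    k_deg_endo, k_deg_s_cyt, k_deg_x_cyt, k_deg_c_cyt:
        Degradation rates (s^-1) of endosomal species (all), cytoplasmic
        free siRNA, cytoplasmic complex (destroys both partners) and
        cytoplasmic free carrier.
    R_tot, RISC_tot:
        Surface receptors and total RISC per cell, molecules.
    k_load:
        RISC loading rate from cytoplasmic free siRNA,
        molecule^-1 s^-1 (per-cell second order against free RISC).
    k_risc_decay:
        Active-RISC decay rate (s^-1); the guide strand is lost.
    k_txn, k_deg_m, k_slice:
        Target mRNA synthesis (molecules s^-1), basal degradation (s^-1)
        and RISC-mediated cleavage (molecule^-1 s^-1) rates.
    k_tln, k_deg_p:
        Translation rate per mRNA (s^-1) and reporter-protein degradation
        rate (s^-1; destabilized reporter, ~2 h half-life).
    k_dil:
        Growth-dilution rate applied to all intracellular species
        (s^-1, default 0).
    kon_cmp, koff_cmp:
        Rates of the monovalent soluble receptor competitor (used in
        competition protocols; it occupies receptor, internalizes and
        returns the receptor, carrying no measurable cargo).
    V_media, N_cells, V_endo, V_cyt:
        Medium volume (L), cells per well, endosomal and cytoplasmic
        compartment volumes (L per cell).
    """

    # siRNA-carrier binding
    kon_s: float = 1e5
    koff_s: float = 1e-4
    # carrier-receptor binding (apparent, monovalent)
    kon_r: float = 1e5
    koff_r: float = 1e-4          # KD_r = 1 nM
    k_int: float = 1e-3
    k_pino: float = 0.0
    # endosome
    k_esc: float = 5e-4
    k_deg_endo: float = 5e-5
    # cytoplasm
    k_deg_s_cyt: float = 1e-4
    k_deg_x_cyt: float = 1e-6
    k_deg_c_cyt: float = 2e-5
    # receptor / RISC pools
    R_tot: float = 2e6
    RISC_tot: float = 1e4
    k_load: float = 1e-4
    k_risc_decay: float = 1e-5
    # RNAi / reporter
    k_txn: float = 500.0 * math.log(2) / (4 * HOUR)   # M_ss = 500
    k_deg_m: float = math.log(2) / (4 * HOUR)         # 4 h mRNA half-life
    k_slice: float = 1e-7
    k_tln: float = 0.05
    k_deg_p: float = math.log(2) / (2 * HOUR)         # 2 h d2EGFP half-life
    k_dil: float = 0.0
    # competitor
    kon_cmp: float = 1e5
    koff_cmp: float = 1e-4        # KD ~ 1 nM, high-affinity EGFR binder
    # geometry
    V_media: float = 100e-6
    N_cells: float = 1.5e4
    V_endo: float = 0.05e-12
    V_cyt: float = 1e-12

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(math.isfinite(v), f"{f.name} must be finite, got {v!r}")
            _require(v >= 0, f"{f.name} must be >= 0, got {v!r}")
        for name in ("V_media", "N_cells", "V_endo", "V_cyt", "R_tot", "RISC_tot"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    @property
    def KD_s(self) -> float:
        """siRNA-carrier dissociation constant, M."""
        return self.koff_s / self.kon_s

    @property
    def KD_r(self) -> float:
        """Carrier-receptor apparent dissociation constant, M."""
        return self.koff_r / self.kon_r

    @property
    def percell_to_molar(self) -> float:
        """Conversion factor: molecules/cell -> M in the shared medium."""
        return self.N_cells / (N_AVOGADRO * self.V_media)

    def with_(self, **changes: float) -> "TraffickingParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Protocol:
    """Experimental protocol for one delivery simulation.

    ``dose`` is the nominal complex concentration (equal to total siRNA);
    total carrier is ``dose * loading_ratio``. With ``preequilibrate``
    (default) the extracellular pools start at the quadratic 1:1 loading
    equilibrium; otherwise everything starts as complex.
    """

    dose: float = 20e-9
    loading_ratio: float = 1.0
    t_transfect: float = 6 * HOUR
    t_obs: float = 24 * HOUR
    media_swap: bool = True
    competitor_conc: float = 0.0
    preequilibrate: bool = True

    def __post_init__(self) -> None:
        _require(self.dose >= 0, "dose must be >= 0")
        _require(self.competitor_conc >= 0, "competitor_conc must be >= 0")
        _require(self.loading_ratio > 0, "loading_ratio must be > 0")
        _require(
            0 < self.t_transfect <= self.t_obs,
            "need 0 < t_transfect <= t_obs",
        )

    def with_(self, **changes) -> "Protocol":
        return replace(self, **changes)
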