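"""Domain types for the empagliflozin population-PK bridging pipeline.

All structural parameters are apparent (oral) parameters, i.e. divided by the
bioavailability F, so dose enters the model in amount units without a separate
F term.  Concentrations are in nmol/L throughout; dose is given in mg and
converted internally via the molar mass of empagliflozin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

#: Molar mass of empagliflozin, g/mol.  Converts tablet strength (mg) into the
#: nmol amount units used for exposure (AUC in nmol*h/L).
EMPAGLIFLOZIN_MOLAR_MASS = 450.91

#: Names of the structural parameters, in canonical order.
PARAM_NAMES = ("cl_f", "vc_f", "vp_f", "q_f", "ka", "d1", "alag1")

#: Parameters carrying a lognormal inter-individual random effect.  The central
#: volume has no random effect in the adult reference model.
IIV_NAMES = ("cl_f", "vp_f", "q_f", "d1", "ka", "alag1")


def mg_to_nmol(dose_mg: float) -> float:
    """Convert a dose in mg to nmol (1 mg = 1e6/M nmol for molar mass M)."""
    return dose_mg * 1.0e6 / EMPAGLIFLOZIN_MOLAR_MASS


class ValidationError(ValueError):
    """A domain object failed its invariants."""


@dataclass(frozen=True)
class PKParameters:
    """Typical (or individual) values of the two-compartment oral model.

    Attributes
    ----------
    cl_f : float
        Apparent clearance CL/F, L/h.
    vc_f : float
        Apparent central volume of distribution Vc/F, L.
    vp_f : float
        Apparent peripheral volume of distribution Vp/F, L.
    q_f : float
        Apparent intercompartmental clearance Q/F, L/h.
    ka : float
        First-order absorption rate constant, 1/h.
    d1 : float
        Duration of the zero-order drug release into the depot, h.
    alag1 : float
        Absorption lag time, h.
    """

    cl_f: float
    vc_f: float
    vp_f: float
    q_f: float
    ka: float
    d1: float
    alag1: float

    def __post_init__(self) -> None:
        for name in ("cl_f", "vc_f", "vp_f", "q_f", "ka"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("d1", "alag1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        """Parameters as a float array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PKParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValidationError(f"expected {len(PARAM_NAMES)} parameters, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def replace(self, **kw) -> "PKParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated once-daily oral dosing.

    dose_mg: dose per administration (10 and 25 mg are the commercial
    tablets; any positive dose is accepted for testing), tau: dosing interval
    in h (24 for once daily), n_doses: number of administrations.
    """

    dose_mg: float
    tau: float = 24.0
    n_doses: int = 1

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dose_mg) and self.dose_mg > 0):
            raise ValidationError(f"dose_mg must be > 0, got {self.dose_mg!r}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValidationError(f"tau must be > 0, got {self.tau!r}")
        if int(self.n_doses) != self.n_doses or self.n_doses < 1:
            raise ValidationError(f"n_doses must be an integer >= 1, got {self.n_doses!r}")

    @property
    def dose_nmol(self) -> float:
        return mg_to_nmol(self.dose_mg)


@dataclass(frozen=True)
class ConcentrationProfile:
    """Central-compartment concentration (nmol/L) on a time grid (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValidationError("times and concentrations must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < -1e-9):
            raise ValidationError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", np.maximum(c, 0.0))

    def to_csv(self, path) -> None:
        """Write the profile as 2-column CSV (time_h, conc_nmol_per_L)."""
        import pandas as pd

        pd.DataFrame(
            {"time_h": self.times, "conc_nmol_per_L": self.concentrations}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ExposureMetrics:
    """Secondary steady-state exposure metrics over one dosing interval."""

    auc_0_24: float  # nmol*h/L
    cmax: float      # nmol/L
    tmax: float      # h after dose
    css: float       # nmol/L, auc/tau by construction


@dataclass(frozen=True)
class AllometricSpec:
    """Power-law body-weight scaling of clearances and volumes.

    Flow parameters (CL/F, Q/F) scale with exponent ``exp_flow`` (theory-based
    default 0.75) and volumes (Vc/F, Vp/F) with ``exp_volume`` (default 1.0),
    relative to ``ref_weight`` kg.  Absorption parameters are not scaled.
    """

    ref_weight: float = 70.0
    exp_flow: float = 0.75
    exp_volume: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ref_weight) and self.ref_weight > 0):
            raise ValidationError(f"ref_weight must be > 0, got {self.ref_weight!r}")
        if not (np.isfinite(self.exp_flow) and np.isfinite(self.exp_volume)):
            raise ValidationError("allometric exponents must be finite")


@dataclass(frozen=True)
class OmegaSpec:
    """Diagonal lognormal IIV variances (omega^2) per parameter."""

    cl_f: float = 0.0
    vp_f: float = 0.0
    q_f: float = 0.0
    d1: float = 0.0
    ka: float = 0.0
    alag1: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v >= 0):
                raise ValidationError(f"omega^2 for {f.name} must be >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        """Variances in :data:`IIV_NAMES` order."""
        return np.array([getattr(self, n) for n in IIV_NAMES], dtype=float)


@dataclass(frozen=True)
class ResidualSpec:
    """Proportional residual error: y = f * (1 + eps), eps ~ N(0, sigma_prop^2)."""

    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_prop) and self.sigma_prop >= 0):
            raise ValidationError(f"sigma_prop must be >= 0, got {self.sigma_prop!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Bundle describing a simulated population: typical parameters at the
    reference weight, the allometric rule, IIV and residual error."""

    reference: PKParameters
    allometry: AllometricSpec = field(default_factory=AllometricSpec)
    omega: OmegaSpec = field(default_factory=OmegaSpec)
    residual: ResidualSpec = field(default_factory=ResidualSpec)


@dataclass(frozen=True)
class Subject:
    """One virtual subject: body weight plus individual PK parameters."""

    id: int
    weight: float
    individual_params: PKParameters


def half_life_to_kel(t_half: float) -> float:
    """ln2 / t_half convenience used in fixtures and tests."""
    return math.log(2.0) / t_half
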