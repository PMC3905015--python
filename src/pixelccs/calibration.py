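"""Travelling-wave ion mobility (TWIMS) drift-time → CCS calibration.

TWIMS drift times relate nonlinearly to collision cross section, so
experimental CCS values are obtained by calibration against standards with
published cross sections (classically denatured ubiquitin, cytochrome c and
myoglobin charge states).  The procedure:

1. Each calibrant's published CCS Ω is reduced for charge and reduced mass
   with the buffer gas:  Ω′ = Ω / (z · sqrt(1/μ)),  μ = m·M/(m+M),
   where z is the charge state, m the analyte mass and M the buffer-gas
   mass (nitrogen, 28.0134 Da, by default).
2. Reduced cross sections are fitted against measured drift times t_D with
   an allometric power law Ω′ = A · t_D^B (ordinary least squares on
   (ln t_D, ln Ω′)).
3. An analyte's CCS follows from its drift time by applying the power law
   and undoing the reduction:  Ω = A · t_D^B · z · sqrt(1/μ).

An optional linear drift-time correction (per-sqrt(m/z) flight-time term) is
accepted but defaults to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Buffer-gas molecular masses (Da).
GAS_MASSES = {"N2": 28.0134, "HE": 4.002602, "AR": 39.948}
DEFAULT_GAS_MASS = GAS_MASSES["N2"]


class CalibrationError(ValueError):
    """Raised for unusable calibrant sets or an unfitted calibration."""


@dataclass(frozen=True)
class CalibrantRecord:
    """One calibration standard: published CCS plus measured drift time."""

    name: str
    mass: float  # Da
    charge: int
    published_ccs: float  # Å²
    drift_time: float  # ms

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.published_ccs <= 0 or self.drift_time <= 0:
            raise ValueError(
                f"calibrant {self.name!r}: mass, CCS and drift time must be > 0")
        if self.charge < 1:
            raise ValueError(f"calibrant {self.name!r}: charge must be >= 1")


@dataclass(frozen=True)
class AnalyteMeasurement:
    """A drift-time measurement awaiting CCS assignment."""

    name: str
    mass: float  # Da
    charge: int
    drift_time: float  # ms
    estimated_ccs: float | None = None  # Å², set by ccs_from_drift

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.drift_time <= 0 or self.charge < 1:
            raise ValueError(
                f"analyte {self.name!r}: mass, drift time > 0 and charge >= 1 required")
        if self.estimated_ccs is not None and self.estimated_ccs <= 0:
            raise ValueError(f"analyte {self.name!r}: estimated CCS must be > 0")


@dataclass(frozen=True)
class AllometricFit:
    """Power-law calibration Ω′ = A · t_D^B with per-calibrant residuals."""

    A: float
    B: float
    residuals: tuple[float, ...]  # relative: (fit - obs) / obs per calibrant
    buffer_gas_mass: float
    n_calibrants: int

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be > 0")
        if self.n_calibrants < 2:
            raise ValueError("fit requires >= 2 calibrants")
        if not all(np.isfinite(self.residuals)):
            raise ValueError("non-finite residuals")

    def reduced_ccs_at(self, drift_time: float) -> float:
        return self.A * drift_time ** self.B

    def to_dict(self) -> dict:
        return {"A": self.A, "B": self.B,
                "buffer_gas_mass_da": self.buffer_gas_mass,
                "n_calibrants": self.n_calibrants,
                "relative_residuals": list(self.residuals)}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricFit":
        d = json.loads(Path(path).read_text())
        return cls(A=d["A"], B=d["B"],
                   residuals=tuple(d.get("relative_residuals", (0.0, 0.0))),
                   buffer_gas_mass=d["buffer_gas_mass_da"],
                   n_calibrants=d["n_calibrants"])


def reduced_mass(analyte_mass: float, gas_mass: float) -> float:
    """μ = m·M/(m+M) (Da)."""
    if analyte_mass <= 0 or gas_mass <= 0:
        raise ValueError("masses must be > 0")
    return analyte_mass * gas_mass / (analyte_mass + gas_mass)


def reduced_ccs(ccs: float, charge: int, analyte_mass: float,
                gas_mass: float = DEFAULT_GAS_MASS) -> float:
    """Reduce a CCS for charge and reduced mass: Ω′ = Ω / (z · sqrt(1/μ)).

    In the heavy-analyte limit μ → M, so Ω′ → Ω · sqrt(M) / z.
    """
    if ccs <= 0:
        raise ValueError("ccs must be > 0")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mu = reduced_mass(analyte_mass, gas_mass)
    return float(ccs / (charge * np.sqrt(1.0 / mu)))


def invert_reduced(reduced: float, charge: int, analyte_mass: float,
                   gas_mass: float = DEFAULT_GAS_MASS) -> float:
    """Undo the reduction: Ω = Ω′ · z · sqrt(1/μ)."""
    if reduced <= 0:
        raise ValueError("reduced CCS must be > 0")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mu = reduced_mass(analyte_mass, gas_mass)
    return float(reduced * charge * np.sqrt(1.0 / mu))


def fit_allometric(calibrants: Sequence[CalibrantRecord],
                   gas_mass: float = DEFAULT_GAS_MASS,
                   drift_correction: float = 0.0) -> AllometricFit:
    """Fit Ω′ = A·t_D^B by unweighted OLS on (ln t_D, ln Ω′).

    ``drift_correction`` (ms per sqrt(Da/e)) subtracts an optional
    mass-to-charge-dependent post-cell flight time, c·sqrt(m/z), from each
    drift time before fitting; default zero (no correction).
    """
    if len(calibrants) < 2:
        raise CalibrationError("allometric fit requires >= 2 calibrants")
    td = np.array([_corrected_drift(c.drift_time, c.mass, c.charge,
                                    drift_correction) for c in calibrants])
    if np.any(td <= 0):
        raise CalibrationError("drift-time correction produced non-positive times")
    if np.unique(td).size < 2:
        raise CalibrationError("calibrants have coincident drift times")
    omega_r = np.array([reduced_ccs(c.published_ccs, c.charge, c.mass, gas_mass)
                        for c in calibrants])
    lnB, lnA = np.polyfit(np.log(td), np.log(omega_r), 1)
    A = float(np.exp(lnA))
    B = float(lnB)
    fitted = A * td ** B
    residuals = tuple(float(r) for r in (fitted - omega_r) / omega_r)
    return AllometricFit(A=A, B=B, residuals=residuals,
                         buffer_gas_mass=gas_mass, n_calibrants=len(calibrants))


def _corrected_drift(drift_time: float, mass: float, charge: int,
                     coefficient: float) -> float:
    return drift_time - coefficient * np.sqrt(mass / charge)


def ccs_from_drift(analyte: AnalyteMeasurement, fit: AllometricFit,
                   drift_correction: float = 0.0) -> AnalyteMeasurement:
    """Assign a CCS from a drift time: Ω = A·t_D^B · z · sqrt(1/μ)."""
    if fit is None:
        raise CalibrationError("no calibration fit supplied")
    td = _corrected_drift(analyte.drift_time, analyte.mass, analyte.charge,
                          drift_correction)
    if td <= 0:
        raise CalibrationError("drift-time correction produced a non-positive time")
    omega = invert_reduced(fit.reduced_ccs_at(td), analyte.charge,
                           analyte.mass, fit.buffer_gas_mass)
    return replace(analyte, estimated_ccs=float(omega))


def read_calibrants_csv(path: str | Path) -> list[CalibrantRecord]:
    """Read calibrants from CSV: name, mass_da, charge, ccs_A2, drift_ms."""
    df = pd.read_csv(path)
    _require(df, path, ["name", "mass_da", "charge", "ccs_A2", "drift_ms"])
    return [CalibrantRecord(str(r.name), float(r.mass_da), int(r.charge),
                            float(r.ccs_A2), float(r.drift_ms))
            for r in df.itertuples(index=False)]


def read_analytes_csv(path: str | Path) -> list[AnalyteMeasurement]:
    """Read analytes from CSV: name, mass_da, charge, drift_ms."""
    df = pd.read_csv(path)
    _require(df, path, ["name", "mass_da", "charge", "drift_ms"])
    return [AnalyteMeasurement(str(r.name), float(r.mass_da), int(r.charge),
                               float(r.drift_ms))
            for r in df.itertuples(index=False)]


def analytes_to_frame(analytes: Sequence[AnalyteMeasurement]) -> pd.DataFrame:
    return pd.DataFrame({
        "name": [a.name for a in analytes],
        "mass_da": [a.mass for a in analytes],
        "charge": [a.charge for a in analytes],
        "drift_ms": [a.drift_time for a in analytes],
        "ccs_A2": [a.estimated_ccs for a in analytes],
    })


def _require(df: pd.DataFrame, path, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CalibrationError(f"{path}: missing column(s) {missing}")
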