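"""Maternal-blood menthol exposure model for electronic-cigarette vaping.

A three-step linear chain estimates how much menthol reaches maternal blood
during a vaping session:

1. mass retained in the lung (mg) =
       retention × (n_puffs × liquid mass consumed per puff / liquid density)
       × menthol concentration in the EC liquid,
2. blood concentration (mg/mL) = transfer fraction × mass retained / plasma volume,
3. per-puff concentration = blood concentration / n_puffs.

Concentrations are converted to nanomolar with the compound's molar mass.
Repeated vaping sessions are modelled as instantaneous boluses with
first-order elimination between sessions (one-compartment kinetics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ECLiquid",
    "PuffSession",
    "Subject",
    "Compound",
    "DosingSchedule",
    "ExposureScenario",
    "MENTHOL",
    "mass_retained",
    "blood_concentration",
    "per_puff_concentration",
    "to_molar_nm",
    "from_molar_nm",
    "scenario_blood_nm",
    "calibrate_liquid_mass_per_puff",
    "simulate_time_course",
]


def _require_finite_nonneg(value: float, name: str) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


def _require_fraction(value: float, name: str) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ECLiquid:
    """Electronic-cigarette refill liquid.

    menthol_mg_per_ml : menthol content of the liquid (mg/mL).
    density_mg_per_ml : liquid density (mg/mL); dividing a consumed liquid
        mass (mg) by it yields the consumed volume (mL).
    """

    menthol_mg_per_ml: float
    density_mg_per_ml: float = 1000.0

    def __post_init__(self) -> None:
        _require_finite_nonneg(self.menthol_mg_per_ml, "menthol_mg_per_ml")
        if not math.isfinite(self.density_mg_per_ml) or self.density_mg_per_ml <= 0:
            raise ValueError(
                f"density_mg_per_ml must be positive, got {self.density_mg_per_ml!r}"
            )


@dataclass(frozen=True)
class PuffSession:
    """Puff topography of one vaping session.

    liquid_mass_per_puff_mg is the average mass of liquid consumed per puff;
    retention_fraction is the fraction of inhaled menthol kept in the lung.
    """

    n_puffs: int
    liquid_mass_per_puff_mg: float
    retention_fraction: float = 0.96

    def __post_init__(self) -> None:
        if self.n_puffs < 0 or int(self.n_puffs) != self.n_puffs:
            raise ValueError(f"n_puffs must be a non-negative integer, got {self.n_puffs!r}")
        _require_finite_nonneg(self.liquid_mass_per_puff_mg, "liquid_mass_per_puff_mg")
        _require_fraction(self.retention_fraction, "retention_fraction")


@dataclass(frozen=True)
class Subject:
    """Physiological constants of the exposed subject.

    Defaults describe a pregnant woman at week 2 of gestation: plasma volume
    ~2650 mL, with 50% of lung-retained menthol transferring to blood.
    """

    plasma_volume_ml: float = 2650.0
    transfer_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not math.isfinite(self.plasma_volume_ml) or self.plasma_volume_ml <= 0:
            raise ValueError(
                f"plasma_volume_ml must be positive, got {self.plasma_volume_ml!r}"
            )
        _require_fraction(self.transfer_fraction, "transfer_fraction")


@dataclass(frozen=True)
class Compound:
    name: str
    molecular_weight: float  # g/mol

    def __post_init__(self) -> None:
        if not math.isfinite(self.molecular_weight) or self.molecular_weight <= 0:
            raise ValueError(
                f"molecular_weight must be positive, got {self.molecular_weight!r}"
            )


#: L-menthol, C10H20O.
MENTHOL = Compound("menthol", 156.27)


@dataclass(frozen=True)
class DosingSchedule:
    """Times of repeated vaping sessions and elimination kinetics.

    session_times_h : hours from the start of observation, ascending.
    half_life_h     : blood elimination half-life; math.inf disables decay.
    duration_h      : total simulated span.
    time_step_h     : output grid resolution.
    """

    session_times_h: Sequence[float]
    half_life_h: float = 1.0
    duration_h: float = 12.0
    time_step_h: float = 0.01

    def __post_init__(self) -> None:
        times = list(self.session_times_h)
        if any(t != s for t, s in zip(times, sorted(times))):
            raise ValueError("session_times_h must be sorted ascending")
        if not self.half_life_h > 0:
            raise ValueError(f"half_life_h must be positive, got {self.half_life_h!r}")
        if not (math.isfinite(self.time_step_h) and self.time_step_h > 0):
            raise ValueError(f"time_step_h must be positive, got {self.time_step_h!r}")
        if not (math.isfinite(self.duration_h) and self.duration_h > 0):
            raise ValueError(f"duration_h must be positive, got {self.duration_h!r}")


@dataclass(frozen=True)
class ExposureScenario:
    """Bundle of liquid, puff topography, subject and compound."""

    liquid: ECLiquid
    session: PuffSession
    subject: Subject = field(default_factory=Subject)
    compound: Compound = MENTHOL


def mass_retained(liquid: ECLiquid, session: PuffSession) -> float:
    """Menthol mass (mg) retained in the lung during one session.

    retention × (n_puffs × liquid mass per puff / density) × liquid menthol
    concentration. Linear in every factor.
    """
    consumed_ml = session.n_puffs * session.liquid_mass_per_puff_mg / liquid.density_mg_per_ml
    return session.retention_fraction * consumed_ml * liquid.menthol_mg_per_ml


def blood_concentration(retained_mg: float, subject: Subject) -> float:
    """Maternal blood concentration (mg/mL) from a retained mass (mg)."""
    _require_finite_nonneg(retained_mg, "retained_mg")
    return subject.transfer_fraction * retained_mg / subject.plasma_volume_ml


def per_puff_concentration(total_mg_per_ml: float, session: PuffSession) -> float:
    """Blood concentration attributable to a single puff."""
    if session.n_puffs < 1:
        raise ValueError("per-puff concentration requires n_puffs >= 1")
    return total_mg_per_ml / session.n_puffs


def to_molar_nm(conc_mg_per_ml: float, compound: Compound = MENTHOL) -> float:
    """Convert mg/mL to nM.

    mg/mL equals g/L; dividing by the molar mass (g/mol) gives mol/L, and
    1 mol/L = 1e9 nM.
    """
    _require_finite_nonneg(conc_mg_per_ml, "conc_mg_per_ml")
    return conc_mg_per_ml / compound.molecular_weight * 1e9


def from_molar_nm(conc_nm: float, compound: Compound = MENTHOL) -> float:
    """Inverse of :func:`to_molar_nm` (nM back to mg/mL)."""
    _require_finite_nonneg(conc_nm, "conc_nm")
    return conc_nm * compound.molecular_weight / 1e9


def scenario_blood_nm(scenario: ExposureScenario) -> float:
    """Blood concentration (nM) for a full session under a scenario."""
    retained = mass_retained(scenario.liquid, scenario.session)
    conc = blood_concentration(retained, scenario.subject)
    return to_molar_nm(conc, scenario.compound)


def calibrate_liquid_mass_per_puff(
    target_blood_nm: float,
    liquid: ECLiquid,
    subject: Subject = Subject(),
    compound: Compound = MENTHOL,
    n_puffs: int = 1,
    retention_fraction: float = 0.96,
) -> float:
    """Per-puff consumed-liquid mass (mg) reproducing a known blood level.

    Inverts the linear exposure chain: given a published blood concentration
    for a stated liquid, puff count and physiology, solve for the one
    unmeasured topography parameter. With the defaults, a single puff of a
    3 mg/mL liquid producing 11.62 nM implies ~3.34 mg of liquid per puff.
    """
    _require_finite_nonneg(target_blood_nm, "target_blood_nm")
    if liquid.menthol_mg_per_ml <= 0:
        raise ValueError("calibration requires a liquid with menthol_mg_per_ml > 0")
    if retention_fraction <= 0:
        raise ValueError("calibration requires retention_fraction > 0")
    target_mg_per_ml = from_molar_nm(target_blood_nm, compound)
    retained = target_mg_per_ml * subject.plasma_volume_ml / subject.transfer_fraction
    consumed_ml = retained / (retention_fraction * liquid.menthol_mg_per_ml)
    return consumed_ml * liquid.density_mg_per_ml / n_puffs


def simulate_time_course(
    scenario: ExposureScenario, schedule: DosingSchedule
) -> pd.DataFrame:
    """Blood concentration (nM) over time under repeated vaping sessions.

    Each session is an instantaneous bolus of the full session amount;
    between boluses the concentration decays first-order with the given
    half-life. Computed by exact superposition of decaying boluses, so the
    value at any grid time equals the closed-form geometric series
    regardless of the grid resolution.

    Returns a DataFrame with columns ``time_h`` and ``conc_nM``.
    """
    bolus_nm = scenario_blood_nm(scenario)
    n_steps = int(round(schedule.duration_h / schedule.time_step_h))
    t = np.arange(n_steps + 1) * schedule.time_step_h
    conc = np.zeros_like(t)
    sessions = np.asarray(list(schedule.session_times_h), dtype=float)
    for s in sessions:
        active = t >= s
        if math.isinf(schedule.half_life_h):
            conc[active] += bolus_nm
        else:
            conc[active] += bolus_nm * np.exp2(-(t[active] - s) / schedule.half_life_h)
    return pd.DataFrame({"time_h": t, "conc_nM": conc})
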