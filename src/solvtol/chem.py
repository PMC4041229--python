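"""Closed-vial solvent partitioning via a Henry's-law mass balance.

A dose of a volatile chlorinated solvent added to a sealed anaerobic
culture tube distributes between the aqueous medium, the headspace gas
and (above the aqueous solubility limit) a separate free phase.  At
equilibrium the dissolved concentration follows from the mass balance

    n_total = C_aq * V_aq + H_cc * C_aq * V_gas            (below solubility)

where ``H_cc`` is the dimensionless gas/aqueous concentration ratio at
the incubation temperature.  The *nominal* concentration, total amount
over liquid volume, is what a dose series is labelled with once a free
phase forms.

Units throughout: amounts in µmol, concentrations in mmol L⁻¹ (µmol/mL),
volumes in mL, temperatures in °C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "SolventSpec",
    "VialSetup",
    "SolventDose",
    "PartitionResult",
    "henry_at_temperature",
    "moles_added",
    "partition_dose",
    "partition_amount",
    "amount_for_aqueous_concentration",
    "dose_for_aqueous_concentration",
]

_KELVIN = 273.15


@dataclass(frozen=True)
class SolventSpec:
    """Physicochemical constants of one solvent.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"CT"`` for carbon tetrachloride.
    molar_mass:
        g mol⁻¹.
    liquid_density:
        g mL⁻¹ of the neat liquid, used when dosing as free phase.
    log_pow:
        log10 octanol–water partition coefficient (hydrophobicity index).
    aqueous_solubility:
        Maximum dissolved concentration, mmol L⁻¹.
    henry_points:
        Ordered ``(temperature_C, H_cc)`` pairs, strictly increasing in
        temperature; ``H_cc`` is the dimensionless gas/aqueous ratio.
    """

    name: str
    molar_mass: float
    liquid_density: float
    log_pow: float
    aqueous_solubility: float
    henry_points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.liquid_density <= 0:
            raise ValueError(f"{self.name}: liquid_density must be > 0")
        if self.aqueous_solubility <= 0:
            raise ValueError(f"{self.name}: aqueous_solubility must be > 0")
        pts = tuple((float(t), float(h)) for t, h in self.henry_points)
        if not pts:
            raise ValueError(f"{self.name}: henry_points must be non-empty")
        temps = [t for t, _ in pts]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError(f"{self.name}: henry_points temperatures must be strictly increasing")
        if any(h <= 0 for _, h in pts):
            raise ValueError(f"{self.name}: all H_cc values must be > 0")
        object.__setattr__(self, "henry_points", pts)


@dataclass(frozen=True)
class VialSetup:
    """Sealed-vial geometry and incubation temperature.

    Defaults to the 25 mL Hungate tube with 10 mL medium (15 mL
    headspace) used in anaerobic tube assays.
    """

    liquid_volume: float = 10.0
    headspace_volume: float = 15.0
    temperature: float = 30.0

    def __post_init__(self) -> None:
        if self.liquid_volume <= 0:
            raise ValueError("liquid_volume must be > 0")
        if self.headspace_volume < 0:
            raise ValueError("headspace_volume must be >= 0")
        if not (0.0 <= self.temperature <= 60.0):
            raise ValueError("temperature outside the sane assay range 0-60 °C")


@dataclass(frozen=True)
class SolventDose:
    """A solvent addition, either neat liquid or a dilute ethanolic stock.

    ``stock_concentration`` (mol L⁻¹) is required for ``ethanolic_stock``
    mode; the ethanol carrier itself is ignored (ethanol-only controls
    show no growth effect, and its partitioning is negligible at µL
    volumes).
    """

    mode: Literal["neat", "ethanolic_stock"]
    volume_added: float  # µL
    stock_concentration: float | None = None  # mol L⁻¹

    def __post_init__(self) -> None:
        if self.mode not in ("neat", "ethanolic_stock"):
            raise ValueError(f"unknown dose mode {self.mode!r}")
        if self.volume_added <= 0:
            raise ValueError("volume_added must be > 0")
        if self.mode == "ethanolic_stock":
            if self.stock_concentration is None or self.stock_concentration <= 0:
                raise ValueError("ethanolic_stock dose requires stock_concentration > 0")


@dataclass(frozen=True)
class PartitionResult:
    """Equilibrium fate of a dose in a sealed vial.

    ``nominal_concentration`` is total amount over liquid volume; it
    exceeds ``aqueous_concentration`` whenever headspace or free phase
    holds part of the dose, and is the reporting scale used above the
    solubility limit.
    """

    total_amount: float  # µmol
    aqueous_concentration: float  # mmol L⁻¹
    headspace_concentration: float  # mmol L⁻¹
    nominal_concentration: float  # mmol L⁻¹
    free_phase: bool
    free_phase_amount: float  # µmol


def henry_at_temperature(solvent: SolventSpec, temperature: float) -> float:
    """Dimensionless Henry constant ``H_cc`` at ``temperature`` (°C).

    Exact table values are returned as-is; between listed temperatures,
    ln(H_cc) is interpolated linearly against 1/T(K) (van't Hoff form).
    Outside the tabulated range the nearest endpoint is used and a
    ``UserWarning`` is emitted, because assay temperatures vary per
    species and refusing would be unhelpful.
    """
    pts = solvent.henry_points
    for t, h in pts:
        if temperature == t:
            return h
    if temperature < pts[0][0]:
        warnings.warn(
            f"{solvent.name}: {temperature} °C below Henry table range "
            f"({pts[0][0]}-{pts[-1][0]} °C); clamping to {pts[0][0]} °C",
            stacklevel=2,
        )
        return pts[0][1]
    if temperature > pts[-1][0]:
        warnings.warn(
            f"{solvent.name}: {temperature} °C above Henry table range "
            f"({pts[0][0]}-{pts[-1][0]} °C); clamping to {pts[-1][0]} °C",
            stacklevel=2,
        )
        return pts[-1][1]
    # bracketing pair
    for (t1, h1), (t2, h2) in zip(pts, pts[1:]):
        if t1 < temperature < t2:
            x1, x2 = 1.0 / (t1 + _KELVIN), 1.0 / (t2 + _KELVIN)
            x = 1.0 / (temperature + _KELVIN)
            lnh = math.log(h1) + (math.log(h2) - math.log(h1)) * (x - x1) / (x2 - x1)
            return math.exp(lnh)
    raise AssertionError("unreachable")  # pragma: no cover


def moles_added(dose: SolventDose, solvent: SolventSpec) -> float:
    """Amount of solvent in a dose, µmol.

    Neat liquid: volume × density / molar mass.  Ethanolic stock:
    volume × stock molarity.
    """
    if dose.mode == "neat":
        # µL * g/mL / (g/mol): 1 µL = 1e-3 mL, 1 mol = 1e6 µmol
        return dose.volume_added * solvent.liquid_density / solvent.molar_mass * 1e3
    assert dose.stock_concentration is not None
    # µL * mol/L = µmol
    return dose.volume_added * dose.stock_concentration


def partition_amount(solvent: SolventSpec, vial: VialSetup, total_umol: float) -> PartitionResult:
    """Partition a known total amount (µmol) across aqueous phase,
    headspace and free phase at equilibrium."""
    if total_umol < 0:
        raise ValueError("total amount must be >= 0")
    h = henry_at_temperature(solvent, vial.temperature)
    v_aq, v_gas = vial.liquid_volume, vial.headspace_volume
    nominal = total_umol / v_aq
    c_aq = total_umol / (v_aq + h * v_gas)
    if c_aq > solvent.aqueous_solubility:
        c_aq = solvent.aqueous_solubility
        c_gas = h * c_aq
        free = total_umol - c_aq * v_aq - c_gas * v_gas
        return PartitionResult(total_umol, c_aq, c_gas, nominal, True, free)
    return PartitionResult(total_umol, c_aq, h * c_aq, nominal, False, 0.0)


def partition_dose(solvent: SolventSpec, vial: VialSetup, dose: SolventDose) -> PartitionResult:
    """Equilibrium partitioning of a dose added to a sealed vial."""
    return partition_amount(solvent, vial, moles_added(dose, solvent))


def amount_for_aqueous_concentration(
    solvent: SolventSpec, vial: VialSetup, target_mM: float
) -> float:
    """Inverse solve: total µmol needed for a dissolved target (mmol L⁻¹).

    The target must not exceed the aqueous solubility; above it no finite
    dose raises the dissolved concentration further.
    """
    if target_mM < 0:
        raise ValueError("target concentration must be >= 0")
    if target_mM > solvent.aqueous_solubility:
        raise ValueError(
            f"{solvent.name}: target {target_mM} mM exceeds aqueous solubility "
            f"{solvent.aqueous_solubility} mM"
        )
    h = henry_at_temperature(solvent, vial.temperature)
    return target_mM * (vial.liquid_volume + h * vial.headspace_volume)


def dose_for_aqueous_concentration(
    solvent: SolventSpec,
    vial: VialSetup,
    target_mM: float,
    mode: Literal["neat", "ethanolic_stock"] = "neat",
    stock_concentration: float | None = None,
) -> SolventDose:
    """Plan the dose volume achieving a dissolved target concentration."""
    n = amount_for_aqueous_concentration(solvent, vial, target_mM)
    if mode == "neat":
        vol = n * solvent.molar_mass / solvent.liquid_density / 1e3
        return SolventDose("neat", vol)
    if stock_concentration is None or stock_concentration <= 0:
        raise ValueError("stock_concentration required for ethanolic_stock planning")
    return SolventDose("ethanolic_stock", n / stock_concentration, stock_concentration)
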